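"""Deterministic synthetic MAVE datasets for download-free testing.

The generator emulates the core MAVE pipeline on a synthetic target: a
saturation variant library, a latent per-variant effect, separation of
variants into sorting bins, and sequencing-count quantification, summarized
into per-variant scores.  The effect model and the logistic bin-sorting
model are non-normative conveniences — a reporting standard prescribes what
to record about an experiment, not how to simulate one — but their
parameters are surfaced on :class:`FixtureSpec` so tests can reason about
what the generator should recover.

Everything is keyed by a single integer seed; per-stage substreams are
derived from it so adding stages never perturbs earlier outputs, and
identical seeds give byte-identical files.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MavekitError, UnknownRuleError
from . import mavehgvs
from .mavehgvs import EditKind, MaveHgvsVariant, SequenceEdit, format_variant
from .seqid import AMINO_ACIDS, MoleculeType, TargetSequence, write_fasta
from .tables import CountSet, ScoreKind, ScoreRecord, ScoreSet, write_counts, write_scores
from .vocabulary import (
    AnalysisDescriptor,
    AssayDescriptor,
    CalibrationVariant,
    ControlledTerm,
    DataType,
    DepositionRecord,
    DiseaseAnnotation,
    GenerationMode,
    LibraryDescriptor,
    MetadataDocument,
    ModelSystem,
    RULE_TABLE,
    SequencingDescriptor,
    TermRegistry,
    load_registry,
)
from .seqid import ReferenceLink, Strand, parse_accession


@dataclass(frozen=True)
class EffectModel:
    """Latent effect mixture: a null class at zero and a shifted class."""

    null_fraction: float = 0.5
    deleterious_mean_shift: float = -2.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.null_fraction <= 1.0:
            raise MavekitError("nullFraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise MavekitError("noiseSd must be positive")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    target_length: int = 30
    molecule_type: MoleculeType = MoleculeType.dna
    n_bins: int = 4
    depth_per_variant: int = 2000
    effect_model: EffectModel = field(default_factory=EffectModel)

    def __post_init__(self) -> None:
        if self.target_length < 1:
            raise MavekitError("targetLength must be positive")
        if self.n_bins < 2:
            raise MavekitError("nBins must be at least 2")
        if self.depth_per_variant < 1:
            raise MavekitError("depthPerVariant must be positive")
        object.__setattr__(self, "molecule_type", MoleculeType(self.molecule_type))


def _stage_rng(spec_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, stage]))


def generate_target(spec: FixtureSpec) -> TargetSequence:
    """Pseudo-random target sequence; same seed, same sequence."""
    rng = _stage_rng(spec.seed, 0)
    if spec.molecule_type is MoleculeType.dna:
        alphabet = "ACGT"
    else:
        alphabet = AMINO_ACIDS
    residues = "".join(rng.choice(list(alphabet), size=spec.target_length))
    return TargetSequence(
        label=f"synthetic_target_{spec.seed}",
        residues=residues,
        molecule_type=spec.molecule_type,
    )


def compliant_preset(
    target: TargetSequence, registry: TermRegistry | None = None
) -> MetadataDocument:
    """A metadata document built to satisfy every reporting rule.

    Illustrative, not a replica of any published record: identifiers such as
    the RefSeq accession and SRA run are synthetic placeholders.
    """
    if registry is None:
        registry = load_registry()

    def term(category: str, label: str) -> ControlledTerm:
        match = [t for t in registry.terms_in(category) if t.label == label]
        return match[0]

    first_variant = format_variant(mavehgvs.enumerate_saturation(target)[0])
    link = ReferenceLink(
        target_digest=target.digest,
        accession=parse_accession("NM_900001.2"),
        anchor_position=101,
        strand=Strand.plus,
        reference_context=target.residues,
    )
    return MetadataDocument.build(
        title="Synthetic saturation mutagenesis fixture",
        project_scope_term=term("projectScope", "protein coding element"),
        targets=[target],
        reference_links=[link],
        model_system=ModelSystem(
            taxon_curie="NCBITaxon:9606",
            cell_line_curie="CLO:0009454",
            description="synthetic human cell line model",
        ),
        library=LibraryDescriptor(
            generation_mode=GenerationMode.in_vitro,
            generation_method_term=term("libraryGeneration", "doped oligonucleotide synthesis"),
            delivery_method_term=term("libraryIntegrationExpression", "landing pad recombination"),
        ),
        assay=AssayDescriptor(
            readout_terms=(term("assayType", "flow cytometry assay"),),
            environmental_variables=(("temperature", "37", "C"),),
            protocol_uri="https://example.org/protocols/synthetic-mave",
            calibration_variants=(
                CalibrationVariant(
                    variant=first_variant,
                    known_effect="functionally normal",
                    evidence_source="doi:10.0000/synthetic-calibration-set",
                ),
            ),
        ),
        sequencing=SequencingDescriptor(
            method_term=term("sequencingMethod", "targeted amplicon sequencing"),
            raw_read_depositions=(
                (
                    "Sequence Read Archive",
                    "SRR000000",
                    ("per-bin amplicon reads; bins 1..K, single time point",),
                ),
            ),
        ),
        analysis=AnalysisDescriptor(
            pipeline_description=(
                "variant counting from amplicon reads followed by log-ratio "
                "scoring across sorting bins"
            ),
            software=(("mavekit", "0.1.0"),),
            code_repository_uri="https://example.org/code/synthetic-mave",
            archive_doi="10.5281/zenodo.0000000",
        ),
        depositions=[
            DepositionRecord(DataType.processed_scores, "MaveDB", "urn:synthetic:scores"),
            DepositionRecord(DataType.unprocessed_scores, "MaveDB", "urn:synthetic:raw-scores"),
            DepositionRecord(DataType.raw_counts, "MaveDB", "urn:synthetic:counts"),
            DepositionRecord(DataType.raw_sequence_reads, "Sequence Read Archive", "SRR000000"),
            DepositionRecord(DataType.target_sequence, "MaveDB", "urn:synthetic:target"),
            DepositionRecord(DataType.analysis_code, "Zenodo", "10.5281/zenodo.0000000"),
        ],
        disease=DiseaseAnnotation(
            disease_curie="MONDO:0000001",
            gene_disease_mechanism="loss of function of the synthetic target",
            assay_mechanism_relevance=(
                "readout tracks the molecular function whose loss drives the condition"
            ),
        ),
    )


def generate_dataset(
    spec: FixtureSpec, registry: TermRegistry | None = None
) -> tuple[ScoreSet, CountSet, MetadataDocument]:
    """Simulate one MAVE dataset: scores, per-bin counts, and metadata.

    The library is the full saturation library of the generated target.
    Each variant draws a latent effect from the two-component mixture; a
    read's bin follows Binomial(nBins-1, sigmoid(effect)), so the logistic
    of the mean bin recovers the effect.  The observed score is the
    empirical logit of the mean normalized bin, which is approximately the
    latent effect; per-variant totals are Poisson around depthPerVariant.
    """
    target = generate_target(spec)
    variants = mavehgvs.enumerate_saturation(target)
    n = len(variants)
    em = spec.effect_model

    rng_eff = _stage_rng(spec.seed, 1)
    is_null = rng_eff.random(n) < em.null_fraction
    base = np.where(is_null, 0.0, em.deleterious_mean_shift)
    effects = base + rng_eff.normal(0.0, em.noise_sd, size=n)

    rng_counts = _stage_rng(spec.seed, 2)
    m = spec.n_bins - 1
    p = 1.0 / (1.0 + np.exp(-effects))
    totals = rng_counts.poisson(spec.depth_per_variant, size=n)
    from scipy.stats import binom

    bin_probs = binom.pmf(np.arange(spec.n_bins)[None, :], m, p[:, None])
    counts = np.vstack(
        [rng_counts.multinomial(totals[i], bin_probs[i]) for i in range(n)]
    )

    bins = np.arange(spec.n_bins)
    weighted = counts @ bins
    phat = (weighted + 0.5) / (m * totals + 1.0)
    scores = np.log(phat / (1.0 - phat))

    variant_col = "hgvs_pro" if spec.molecule_type is MoleculeType.protein else "hgvs_nt"
    records = []
    for i, v in enumerate(variants):
        text = format_variant(v)
        records.append(
            ScoreRecord(
                hgvs_nt=text if variant_col == "hgvs_nt" else None,
                hgvs_pro=text if variant_col == "hgvs_pro" else None,
                score=float(scores[i]),
                extras={
                    "latentClass": "null" if is_null[i] else "deleterious",
                    "latentEffect": repr(float(effects[i])),
                },
            )
        )
    score_set = ScoreSet(records=records, score_kind=ScoreKind.raw, target_digest=target.digest)
    count_set = CountSet(
        samples=[f"bin{b + 1}" for b in range(spec.n_bins)],
        records=[
            (format_variant(v), [int(c) for c in counts[i]])
            for i, v in enumerate(variants)
        ],
        target_digest=target.digest,
    )
    doc = compliant_preset(target, registry)
    return score_set, count_set, doc


def write_fixture_files(
    spec: FixtureSpec, out_dir: str | Path, registry: TermRegistry | None = None
) -> dict[str, Path]:
    """Write the four on-disk artifacts: FASTA, scores CSV, counts CSV, JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    score_set, count_set, doc = generate_dataset(spec, registry)
    target = generate_target(spec)
    paths = {
        "target": out / "target.fasta",
        "scores": out / "scores.csv",
        "counts": out / "counts.csv",
        "metadata": out / "metadata.json",
    }
    write_fasta([target], paths["target"])
    write_scores(score_set, paths["scores"])
    write_counts(count_set, paths["counts"])
    paths["metadata"].write_text(doc.to_json() + "\n")
    return paths


# --- ablation ----------------------------------------------------------------

def _drop_deposition(doc: dict, data_type: str) -> None:
    doc["depositions"] = [
        d for d in doc.get("depositions", []) if d.get("dataType") != data_type
    ]


def _mutate_context(doc: dict) -> None:
    ctx = doc["referenceLinks"][0]["referenceContext"]
    flipped = {"A": "C", "C": "A", "G": "T", "T": "G"}.get(ctx[0], "A")
    doc["referenceLinks"][0]["referenceContext"] = flipped + ctx[1:]


_ABLATIONS = {
    "TARGET_SEQUENCE_REQUIRED": lambda d: d["targets"][0].__setitem__("residues", ""),
    "VERSIONED_ACCESSION_REQUIRED": lambda d: d["referenceLinks"][0].__setitem__(
        "accession", d["referenceLinks"][0]["accession"].rsplit(".", 1)[0]
    ),
    "MODEL_SYSTEM_TAXON": lambda d: d["modelSystem"].__setitem__("taxonCurie", "9606"),
    "LIBRARY_GENERATION_MODE": lambda d: d["library"].__setitem__(
        "generationMode", "spontaneousMutation"
    ),
    "ASSAY_READOUT_TERM": lambda d: d["assay"].__setitem__("readoutTerms", []),
    "SEQUENCING_METHOD_TERM": lambda d: d["sequencing"].pop("methodTerm"),
    "RAW_READS_DEPOSITION": lambda d: d["sequencing"].__setitem__("rawReadDepositions", []),
    "RAW_READ_FILE_DESCRIPTIONS": lambda d: d["sequencing"]["rawReadDepositions"][0].__setitem__(
        "fileDescriptions", []
    ),
    "DISEASE_TERM_SOURCE": lambda d: d["disease"].__setitem__("diseaseCurie", "DOID:0050"),
    "GENE_DISEASE_ENTITY": lambda d: d["disease"].__setitem__("geneDiseaseMechanism", ""),
    "SOFTWARE_VERSIONS": lambda d: d["analysis"]["software"][0].__setitem__("version", ""),
    "CODE_ARCHIVE_DOI": lambda d: d["analysis"].pop("archiveDoi"),
    "CALIBRATION_VARIANT_SOURCE": lambda d: d["assay"]["calibrationVariants"][0].__setitem__(
        "evidenceSource", ""
    ),
    "ENV_VARIABLES_DOCUMENTED": lambda d: d["assay"].__setitem__("environmentalVariables", []),
    "RAW_COUNTS_SHARED": lambda d: _drop_deposition(d, DataType.raw_counts.value),
    "PRENORMALIZED_SCORES_SHARED": lambda d: _drop_deposition(
        d, DataType.unprocessed_scores.value
    ),
    "REFERENCE_IDENTICAL_ALLELE": _mutate_context,
    "CUSTOM_TERM": lambda d: d["assay"]["readoutTerms"][0].__setitem__(
        "label", "bespoke unlisted readout"
    ),
    "UNKNOWN_FIELD": lambda d: d.__setitem__("vendorNotes", "not part of the model"),
}


def ablate(doc: MetadataDocument, rule_id: str) -> MetadataDocument:
    """Copy of ``doc`` with exactly the field guarded by ``rule_id`` corrupted.

    Drives the validator coverage matrix: ablating a compliant preset must
    trigger exactly the named rule.
    """
    if rule_id not in _ABLATIONS or rule_id not in RULE_TABLE:
        raise UnknownRuleError(f"no ablation defined for rule {rule_id!r}")
    data = copy.deepcopy(doc.data)
    _ABLATIONS[rule_id](data)
    return MetadataDocument(data)


# --- fuzz generators ---------------------------------------------------------

def random_variant(
    rng: np.random.Generator,
    molecule_type: MoleculeType = MoleculeType.dna,
    max_position: int = 200,
    allow_multi: bool = True,
) -> MaveHgvsVariant:
    """A random grammar-valid variant (not necessarily applicable to any target)."""
    mt = MoleculeType(molecule_type)
    n_edits = int(rng.integers(2, 4)) if allow_multi and rng.random() < 0.25 else 1
    edits: list[SequenceEdit] = []
    cursor = 1
    for _ in range(n_edits):
        if cursor >= max_position - 10:
            break
        start = int(rng.integers(cursor, cursor + 20))
        kinds = (
            EditKind.substitution,
            EditKind.deletion,
            EditKind.duplication,
            EditKind.insertion,
            EditKind.delins,
        )
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if mt is MoleculeType.dna:
            def res(k: int) -> str:
                return "".join(rng.choice(list("ACGT"), size=k))

            if kind is EditKind.substitution:
                ref = res(1)
                alt = rng.choice([b for b in "ACGT" if b != ref])
                e = SequenceEdit(kind, start, start, ref=ref, alt=alt)
            elif kind is EditKind.insertion:
                e = SequenceEdit(kind, start, start + 1, alt=res(int(rng.integers(1, 4))))
            else:
                end = start + int(rng.integers(0, 4))
                alt = res(int(rng.integers(1, 4))) if kind is EditKind.delins else None
                e = SequenceEdit(kind, start, end, alt=alt)
        else:
            three = list(mavehgvs.AA_1TO3[a] for a in AMINO_ACIDS)

            def aa(k: int) -> str:
                return "".join(rng.choice(three, size=k))

            if kind is EditKind.substitution:
                e = SequenceEdit(kind, start, start, ref=aa(1), alt=aa(1))
            elif kind is EditKind.insertion:
                e = SequenceEdit(
                    kind, start, start + 1, ref=aa(1) + aa(1), alt=aa(int(rng.integers(1, 3)))
                )
            else:
                end = start + int(rng.integers(0, 4))
                ref = aa(1) if end == start else aa(1) + aa(1)
                alt = aa(int(rng.integers(1, 3))) if kind is EditKind.delins else None
                e = SequenceEdit(kind, start, end, ref=ref, alt=alt)
        edits.append(e)
        cursor = e.end + 1 + int(rng.integers(1, 5))
    prefix = "p" if mt is MoleculeType.protein else str(rng.choice(["c", "n", "g"]))
    v = MaveHgvsVariant(prefix, tuple(edits))
    return MaveHgvsVariant(prefix, tuple(edits), raw_text=format_variant(v))
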