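"""Controlled vocabulary registry, metadata document model, and validator.

Every MAVE shares a core pipeline — variant library generation, delivery into
a model system, functional separation, sequencing-based quantification, and
score calculation — and reusable datasets require consistent metadata for
each step.  This module provides:

* a term registry over the vocabulary categories (project scope, library
  generation, library integration/expression, assay type, sequencing method,
  phenotype/disease relevance), loaded from bundled JSON data;
* a lenient JSON document model (:class:`MetadataDocument`) for one MAVE
  experiment, with typed builders for programmatic construction;
* a rule-based validator that maps reporting recommendations onto findings
  at three severities — must/essential requirements are errors,
  should/recommend items are warnings, encourage/suggest items are info;
* emission of a JSON Schema (Draft 2020-12) whose hard constraints coincide
  with the validator's error-severity rules.

Validation never raises on bad documents: problems come back as
:class:`ValidationFinding` values with JSON Pointer paths into the input.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Iterable

from .errors import (
    DuplicateTermError,
    RegistryFormatError,
    UnknownCategoryError,
    UnknownRuleError,
)
from .seqid import parse_accession, reverse_complement
from .errors import MissingVersionError, AlphabetError

CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.]*:[A-Za-z0-9._-]+$")

REQUIRED_CATEGORIES = (
    "projectScope",
    "libraryGeneration",
    "libraryIntegrationExpression",
    "assayType",
    "sequencingMethod",
    "phenotypeRelevance",
)


@dataclass(frozen=True)
class ControlledTerm:
    category: str
    label: str
    curie: str | None = None
    definition: str | None = None
    source: str = "bundled"

    def __post_init__(self) -> None:
        if self.curie is not None and not CURIE_RE.match(self.curie):
            raise RegistryFormatError(
                f"term {self.label!r}: curie {self.curie!r} is not a valid CURIE"
            )

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"category": self.category, "label": self.label}
        if self.curie:
            d["curie"] = self.curie
        return d


@dataclass(frozen=True)
class TermRegistry:
    categories: tuple[str, ...]
    terms: tuple[ControlledTerm, ...]
    version: str

    def terms_in(self, category: str) -> list[ControlledTerm]:
        if category not in self.categories:
            raise UnknownCategoryError(
                f"unknown category {category!r}; declared: {', '.join(self.categories)}"
            )
        return [t for t in self.terms if t.category == category]

    def labels_in(self, category: str) -> set[str]:
        return {t.label for t in self.terms_in(category)}


def load_registry(source: str | Path | None = None) -> TermRegistry:
    """Load a term registry from JSON; with no argument, the bundled default."""
    if source is None:
        text = resources.files("mavekit.data").joinpath("registry.json").read_text()
        origin = "bundled"
    else:
        text = Path(source).read_text()
        origin = str(source)
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RegistryFormatError(
            f"registry {origin}: invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    categories = tuple(raw.get("categories", []))
    missing = [c for c in REQUIRED_CATEGORIES if c not in categories]
    if missing:
        raise RegistryFormatError(
            f"registry {origin}: required categories missing: {', '.join(missing)}"
        )
    terms: list[ControlledTerm] = []
    seen: set[tuple[str, str]] = set()
    for i, t in enumerate(raw.get("terms", [])):
        if not isinstance(t, dict) or "category" not in t or "label" not in t:
            raise RegistryFormatError(
                f"registry {origin}: term #{i} lacks 'category'/'label' fields"
            )
        if t["category"] not in categories:
            raise RegistryFormatError(
                f"registry {origin}: term {t['label']!r} names undeclared "
                f"category {t['category']!r}"
            )
        key = (t["category"], t["label"])
        if key in seen:
            raise DuplicateTermError(
                f"registry {origin}: duplicate term {t['label']!r} in {t['category']!r}"
            )
        seen.add(key)
        terms.append(
            ControlledTerm(
                category=t["category"],
                label=t["label"],
                curie=t.get("curie"),
                definition=t.get("definition"),
                source=origin,
            )
        )
    return TermRegistry(
        categories=categories, terms=tuple(terms), version=str(raw.get("version", "0"))
    )


def lookup_terms(registry: TermRegistry, category: str, query: str = "") -> list[ControlledTerm]:
    """Case-insensitive substring search over a category's labels and CURIEs."""
    q = query.lower()
    return [
        t
        for t in registry.terms_in(category)
        if q in t.label.lower() or (t.curie and q in t.curie.lower())
    ]


# --- typed builders for document parts ---------------------------------------

@dataclass(frozen=True)
class ModelSystem:
    taxon_curie: str
    cell_line_curie: str | None = None
    description: str = ""

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"taxonCurie": self.taxon_curie, "description": self.description}
        if self.cell_line_curie:
            d["cellLineCurie"] = self.cell_line_curie
        return d


class GenerationMode(str, Enum):
    endogenous = "endogenousLocusEditing"
    in_vitro = "inVitroLibraryGeneration"


@dataclass(frozen=True)
class LibraryDescriptor:
    generation_mode: GenerationMode
    generation_method_term: ControlledTerm
    delivery_method_term: ControlledTerm

    def to_dict(self) -> dict:
        return {
            "generationMode": GenerationMode(self.generation_mode).value,
            "generationMethodTerm": self.generation_method_term.to_dict(),
            "deliveryMethodTerm": self.delivery_method_term.to_dict(),
        }


@dataclass(frozen=True)
class CalibrationVariant:
    variant: str
    known_effect: str
    evidence_source: str

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "knownEffect": self.known_effect,
            "evidenceSource": self.evidence_source,
        }


@dataclass(frozen=True)
class AssayDescriptor:
    readout_terms: tuple[ControlledTerm, ...]
    environmental_variables: tuple[tuple[str, str, str], ...] = ()
    protocol_uri: str | None = None
    calibration_variants: tuple[CalibrationVariant, ...] = ()

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "readoutTerms": [t.to_dict() for t in self.readout_terms],
            "environmentalVariables": [
                {"name": n, "value": v, "units": u}
                for n, v, u in self.environmental_variables
            ],
            "calibrationVariants": [c.to_dict() for c in self.calibration_variants],
        }
        if self.protocol_uri:
            d["protocolUri"] = self.protocol_uri
        return d


@dataclass(frozen=True)
class SequencingDescriptor:
    method_term: ControlledTerm
    raw_read_depositions: tuple[tuple[str, str, tuple[str, ...]], ...] = ()

    def to_dict(self) -> dict:
        return {
            "methodTerm": self.method_term.to_dict(),
            "rawReadDepositions": [
                {
                    "resourceName": r,
                    "accession": a,
                    "fileDescriptions": list(fd),
                }
                for r, a, fd in self.raw_read_depositions
            ],
        }


@dataclass(frozen=True)
class DiseaseAnnotation:
    disease_curie: str
    gene_disease_mechanism: str = ""
    assay_mechanism_relevance: str = ""

    def to_dict(self) -> dict:
        return {
            "diseaseCurie": self.disease_curie,
            "geneDiseaseMechanism": self.gene_disease_mechanism,
            "assayMechanismRelevance": self.assay_mechanism_relevance,
        }


@dataclass(frozen=True)
class AnalysisDescriptor:
    pipeline_description: str
    software: tuple[tuple[str, str], ...] = ()
    code_repository_uri: str | None = None
    archive_doi: str | None = None

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "pipelineDescription": self.pipeline_description,
            "software": [{"name": n, "version": v} for n, v in self.software],
        }
        if self.code_repository_uri:
            d["codeRepositoryUri"] = self.code_repository_uri
        if self.archive_doi:
            d["archiveDoi"] = self.archive_doi
        return d


class DataType(str, Enum):
    processed_scores = "processedScores"
    unprocessed_scores = "unprocessedScores"
    raw_counts = "rawCounts"
    raw_sequence_reads = "rawSequenceReads"
    target_sequence = "targetSequence"
    linked_sequence_references = "linkedSequenceReferences"
    sequence_metadata_digests = "sequenceMetadataDigests"
    variant_library = "variantLibrary"
    analysis_code = "analysisCode"
    structured_vocabulary_description = "structuredVocabularyDescription"


@dataclass(frozen=True)
class DepositionRecord:
    data_type: DataType
    location: str
    accession_or_uri: str = ""

    def to_dict(self) -> dict:
        return {
            "dataType": DataType(self.data_type).value,
            "location": self.location,
            "accessionOrUri": self.accession_or_uri,
        }


# Recommended deposition locations by data type, order-preserving.
DEPOSITION_MATRIX: dict[DataType, tuple[str, ...]] = {
    DataType.processed_scores: ("MaveDB",),
    DataType.unprocessed_scores: ("MaveDB",),
    DataType.raw_counts: ("MaveDB",),
    DataType.raw_sequence_reads: ("Sequence Read Archive", "Gene Expression Omnibus"),
    DataType.target_sequence: ("MaveDB",),
    DataType.linked_sequence_references: ("MaveDB",),
    DataType.sequence_metadata_digests: ("MaveDB", "SeqRepo"),
    DataType.variant_library: ("MaveDB",),
    DataType.analysis_code: ("GitHub", "Zenodo"),
    DataType.structured_vocabulary_description: ("This work", "MaveDB"),
}


def recommended_repositories(data_type: DataType | str) -> list[str]:
    """Recommended deposition locations for one data type."""
    try:
        dt = DataType(data_type)
    except ValueError as exc:
        raise UnknownCategoryError(f"unknown data type {data_type!r}") from exc
    return list(DEPOSITION_MATRIX[dt])


KNOWN_DOC_FIELDS = (
    "title",
    "projectScopeTerm",
    "targets",
    "referenceLinks",
    "modelSystem",
    "library",
    "assay",
    "sequencing",
    "disease",
    "analysis",
    "depositions",
)


class MetadataDocument:
    """One MAVE experiment's structured metadata record.

    Deliberately lenient: wraps the JSON document as-is (camelCase fields,
    unknown fields preserved) so that incomplete or invalid documents can be
    loaded and then *validated*, with problems reported as findings rather
    than construction errors.  Use :meth:`build` to assemble a document from
    the typed descriptor classes.
    """

    def __init__(self, data: dict[str, Any]):
        self.data = data

    def to_dict(self) -> dict:
        return copy.deepcopy(self.data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "MetadataDocument":
        return cls(copy.deepcopy(data))

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "MetadataDocument":
        return cls(json.loads(text))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MetadataDocument) and self.data == other.data

    @classmethod
    def build(
        cls,
        title: str,
        project_scope_term: ControlledTerm,
        targets: Iterable[Any],
        reference_links: Iterable[Any],
        model_system: ModelSystem,
        library: LibraryDescriptor,
        assay: AssayDescriptor,
        sequencing: SequencingDescriptor,
        analysis: AnalysisDescriptor,
        depositions: Iterable[DepositionRecord] = (),
        disease: DiseaseAnnotation | None = None,
    ) -> "MetadataDocument":
        data: dict[str, Any] = {
            "title": title,
            "projectScopeTerm": project_scope_term.to_dict(),
            "targets": [t.to_dict() for t in targets],
            "referenceLinks": [r.to_dict() for r in reference_links],
            "modelSystem": model_system.to_dict(),
            "library": library.to_dict(),
            "assay": assay.to_dict(),
            "sequencing": sequencing.to_dict(),
            "analysis": analysis.to_dict(),
            "depositions": [d.to_dict() for d in depositions],
        }
        if disease is not None:
            data["disease"] = disease.to_dict()
        return cls(data)


# --- findings and rules ------------------------------------------------------

class Severity(str, Enum):
    error = "error"
    warning = "warning"
    info = "info"


_SEVERITY_RANK = {Severity.error: 0, Severity.warning: 1, Severity.info: 2}


@dataclass(frozen=True)
class ValidationFinding:
    severity: Severity
    rule_id: str
    path: str
    message: str

    def to_dict(self) -> dict:
        return {
            "severity": self.severity.value,
            "ruleId": self.rule_id,
            "path": self.path,
            "message": self.message,
        }

    def __str__(self) -> str:
        return f"{self.severity.value.upper():7s} {self.rule_id} at {self.path or '/'}: {self.message}"


def resolve_pointer(doc: dict, pointer: str) -> Any:
    """Resolve an RFC 6901 JSON Pointer in a document; raises KeyError/IndexError."""
    if pointer == "":
        return doc
    node: Any = doc
    for token in pointer.lstrip("/").split("/"):
        token = token.replace("~1", "/").replace("~0", "~")
        if isinstance(node, list):
            node = node[int(token)]
        else:
            node = node[token]
    return node


RuleFn = Callable[[dict, TermRegistry], list[ValidationFinding]]
_RULES: list[tuple[str, Severity, RuleFn]] = []


def _rule(rule_id: str, severity: Severity):
    def deco(fn: RuleFn):
        _RULES.append((rule_id, severity, fn))
        return fn

    return deco


def _f(severity: Severity, rule_id: str, path: str, message: str) -> ValidationFinding:
    return ValidationFinding(severity, rule_id, path, message)


def _nonempty_str(x: Any) -> bool:
    return isinstance(x, str) and bool(x.strip())


@_rule("TARGET_SEQUENCE_REQUIRED", Severity.error)
def _r_target(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    out = []
    targets = doc.get("targets")
    if not isinstance(targets, list) or not targets:
        return [
            _f(
                Severity.error,
                "TARGET_SEQUENCE_REQUIRED",
                "/targets" if "targets" in doc else "",
                "the entire target sequence used in the assay must be provided",
            )
        ]
    for i, t in enumerate(targets):
        if not isinstance(t, dict) or not _nonempty_str(t.get("residues")):
            path = f"/targets/{i}/residues" if isinstance(t, dict) and "residues" in t else f"/targets/{i}"
            out.append(
                _f(
                    Severity.error,
                    "TARGET_SEQUENCE_REQUIRED",
                    path,
                    "target sequence residues are empty; the full assayed sequence is required",
                )
            )
    return out


@_rule("VERSIONED_ACCESSION_REQUIRED", Severity.error)
def _r_accession(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    out = []
    links = doc.get("referenceLinks")
    if not isinstance(links, list) or not links:
        return [
            _f(
                Severity.error,
                "VERSIONED_ACCESSION_REQUIRED",
                "/referenceLinks" if "referenceLinks" in doc else "",
                "target must be linked to a versioned stable identifier on a "
                "widely used resource (RefSeq, Ensembl, UniProt)",
            )
        ]
    for i, link in enumerate(links):
        acc = link.get("accession", "") if isinstance(link, dict) else ""
        try:
            parse_accession(acc if isinstance(acc, str) else "")
        except MissingVersionError:
            out.append(
                _f(
                    Severity.error,
                    "VERSIONED_ACCESSION_REQUIRED",
                    f"/referenceLinks/{i}/accession" if isinstance(link, dict) and "accession" in link else f"/referenceLinks/{i}",
                    f"accession {acc!r} lacks an explicit version; use a versioned "
                    "stable identifier such as NM_000546.6",
                )
            )
    return out


@_rule("MODEL_SYSTEM_TAXON", Severity.error)
def _r_taxon(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    ms = doc.get("modelSystem")
    if not isinstance(ms, dict) or "taxonCurie" not in ms:
        return [
            _f(
                Severity.error,
                "MODEL_SYSTEM_TAXON",
                "/modelSystem" if isinstance(ms, dict) else "",
                "model system must be identified by an NCBI Taxonomy CURIE",
            )
        ]
    out = []
    curie = ms["taxonCurie"]
    if not (_nonempty_str(curie) and CURIE_RE.match(curie) and curie.split(":")[0] == "NCBITaxon"):
        out.append(
            _f(
                Severity.error,
                "MODEL_SYSTEM_TAXON",
                "/modelSystem/taxonCurie",
                f"taxon identifier {curie!r} is not an NCBITaxon CURIE (e.g. NCBITaxon:9606)",
            )
        )
    return out


@_rule("LIBRARY_GENERATION_MODE", Severity.error)
def _r_genmode(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    lib = doc.get("library")
    modes = {m.value for m in GenerationMode}
    if not isinstance(lib, dict) or "generationMode" not in lib:
        return [
            _f(
                Severity.error,
                "LIBRARY_GENERATION_MODE",
                "/library" if isinstance(lib, dict) else "",
                "library generation mode (endogenous locus editing vs in vitro "
                "library generation) must be stated",
            )
        ]
    if lib["generationMode"] not in modes:
        return [
            _f(
                Severity.error,
                "LIBRARY_GENERATION_MODE",
                "/library/generationMode",
                f"generationMode {lib['generationMode']!r} is not one of {sorted(modes)}",
            )
        ]
    return []


@_rule("ASSAY_READOUT_TERM", Severity.error)
def _r_readout(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    assay = doc.get("assay")
    terms = assay.get("readoutTerms") if isinstance(assay, dict) else None
    if not isinstance(terms, list) or not terms:
        path = "/assay/readoutTerms" if isinstance(assay, dict) and "readoutTerms" in assay else ("/assay" if isinstance(assay, dict) else "")
        return [
            _f(
                Severity.error,
                "ASSAY_READOUT_TERM",
                path,
                "at least one assay readout term (assayType category / OBI shortlist) is required",
            )
        ]
    return []


@_rule("SEQUENCING_METHOD_TERM", Severity.error)
def _r_seqmethod(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    seq = doc.get("sequencing")
    term = seq.get("methodTerm") if isinstance(seq, dict) else None
    if not isinstance(term, dict) or not _nonempty_str(term.get("label")):
        path = "/sequencing/methodTerm" if isinstance(seq, dict) and "methodTerm" in seq else ("/sequencing" if isinstance(seq, dict) else "")
        return [
            _f(
                Severity.error,
                "SEQUENCING_METHOD_TERM",
                path,
                "the high-throughput sequencing method must be described with a "
                "sequencingMethod vocabulary term",
            )
        ]
    return []


@_rule("RAW_READS_DEPOSITION", Severity.warning)
def _r_rawreads(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    seq = doc.get("sequencing")
    deps = seq.get("rawReadDepositions") if isinstance(seq, dict) else None
    if not isinstance(deps, list) or not deps:
        path = "/sequencing/rawReadDepositions" if isinstance(seq, dict) and "rawReadDepositions" in seq else ("/sequencing" if isinstance(seq, dict) else "")
        return [
            _f(
                Severity.warning,
                "RAW_READS_DEPOSITION",
                path,
                "raw sequence reads should be deposited in a suitable repository "
                "(Sequence Read Archive or Gene Expression Omnibus)",
            )
        ]
    return []


@_rule("RAW_READ_FILE_DESCRIPTIONS", Severity.warning)
def _r_filedesc(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    seq = doc.get("sequencing")
    deps = seq.get("rawReadDepositions") if isinstance(seq, dict) else None
    out = []
    if isinstance(deps, list):
        for i, d in enumerate(deps):
            fds = d.get("fileDescriptions") if isinstance(d, dict) else None
            if not isinstance(fds, list) or not any(_nonempty_str(x) for x in fds):
                out.append(
                    _f(
                        Severity.warning,
                        "RAW_READ_FILE_DESCRIPTIONS",
                        f"/sequencing/rawReadDepositions/{i}",
                        "each deposited file should carry a description "
                        "(e.g., time point and sample information)",
                    )
                )
    return out


@_rule("DISEASE_TERM_SOURCE", Severity.warning)
def _r_disease(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    dis = doc.get("disease")
    if dis is None:
        return []
    curie = dis.get("diseaseCurie", "") if isinstance(dis, dict) else ""
    ok = _nonempty_str(curie) and CURIE_RE.match(curie) and curie.split(":")[0] in ("MONDO", "OMIM")
    if not ok:
        path = "/disease/diseaseCurie" if isinstance(dis, dict) and "diseaseCurie" in dis else "/disease"
        return [
            _f(
                Severity.warning,
                "DISEASE_TERM_SOURCE",
                path,
                f"disease term {curie!r} should come from the Mondo Disease Ontology "
                "(MONDO) or OMIM",
            )
        ]
    return []


@_rule("GENE_DISEASE_ENTITY", Severity.info)
def _r_genedisease(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    dis = doc.get("disease")
    if dis is None or not isinstance(dis, dict):
        return []
    if not _nonempty_str(dis.get("geneDiseaseMechanism")):
        return [
            _f(
                Severity.info,
                "GENE_DISEASE_ENTITY",
                "/disease/geneDiseaseMechanism" if "geneDiseaseMechanism" in dis else "/disease",
                "ideally the assay is associated with a particular gene-disease "
                "entity describing the mechanism of disease",
            )
        ]
    return []


@_rule("SOFTWARE_VERSIONS", Severity.warning)
def _r_software(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    ana = doc.get("analysis")
    if not isinstance(ana, dict):
        return [
            _f(
                Severity.warning,
                "SOFTWARE_VERSIONS",
                "",
                "the analysis pipeline, including software versions, should be described",
            )
        ]
    sw = ana.get("software")
    out = []
    if not isinstance(sw, list) or not sw:
        out.append(
            _f(
                Severity.warning,
                "SOFTWARE_VERSIONS",
                "/analysis/software" if "software" in ana else "/analysis",
                "analysis software, including versions, should be listed",
            )
        )
    else:
        for i, s in enumerate(sw):
            if not isinstance(s, dict) or not _nonempty_str(s.get("version")):
                out.append(
                    _f(
                        Severity.warning,
                        "SOFTWARE_VERSIONS",
                        f"/analysis/software/{i}",
                        "each software entry should state an explicit version",
                    )
                )
    return out


@_rule("CODE_ARCHIVE_DOI", Severity.info)
def _r_doi(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    ana = doc.get("analysis")
    if not isinstance(ana, dict):
        return []
    if not _nonempty_str(ana.get("archiveDoi")):
        return [
            _f(
                Severity.info,
                "CODE_ARCHIVE_DOI",
                "/analysis/archiveDoi" if "archiveDoi" in ana else "/analysis",
                "custom code is encouraged to be archived with a DOI-minting "
                "service such as Zenodo",
            )
        ]
    return []


@_rule("CALIBRATION_VARIANT_SOURCE", Severity.warning)
def _r_calibration(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    assay = doc.get("assay")
    cals = assay.get("calibrationVariants") if isinstance(assay, dict) else None
    out = []
    if isinstance(cals, list):
        for i, c in enumerate(cals):
            ok = (
                isinstance(c, dict)
                and _nonempty_str(c.get("variant"))
                and _nonempty_str(c.get("knownEffect"))
                and _nonempty_str(c.get("evidenceSource"))
            )
            if not ok:
                out.append(
                    _f(
                        Severity.warning,
                        "CALIBRATION_VARIANT_SOURCE",
                        f"/assay/calibrationVariants/{i}",
                        "calibration variants should state the variant, its known "
                        "effect, and the source of the information",
                    )
                )
    return out


@_rule("ENV_VARIABLES_DOCUMENTED", Severity.info)
def _r_env(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    assay = doc.get("assay")
    env = assay.get("environmentalVariables") if isinstance(assay, dict) else None
    if not isinstance(env, list) or not env:
        path = "/assay/environmentalVariables" if isinstance(assay, dict) and "environmentalVariables" in assay else ("/assay" if isinstance(assay, dict) else "")
        return [
            _f(
                Severity.info,
                "ENV_VARIABLES_DOCUMENTED",
                path,
                "environmental variables (e.g., temperature, small molecules) are "
                "suggested to be documented explicitly",
            )
        ]
    out = []
    for i, e in enumerate(env):
        if not isinstance(e, dict) or not _nonempty_str(e.get("name")) or not _nonempty_str(str(e.get("value", ""))):
            out.append(
                _f(
                    Severity.info,
                    "ENV_VARIABLES_DOCUMENTED",
                    f"/assay/environmentalVariables/{i}",
                    "each environmental variable should have a non-empty name and value",
                )
            )
    return out


@_rule("RAW_COUNTS_SHARED", Severity.warning)
def _r_counts(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    deps = doc.get("depositions")
    types = {d.get("dataType") for d in deps if isinstance(d, dict)} if isinstance(deps, list) else set()
    if DataType.raw_counts.value not in types:
        return [
            _f(
                Severity.warning,
                "RAW_COUNTS_SHARED",
                "/depositions" if "depositions" in doc else "",
                "raw counts should be shared for each dataset; they have "
                "tremendous utility for reanalysis",
            )
        ]
    return []


@_rule("PRENORMALIZED_SCORES_SHARED", Severity.warning)
def _r_prenorm(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    deps = doc.get("depositions")
    types = {d.get("dataType") for d in deps if isinstance(d, dict)} if isinstance(deps, list) else set()
    if DataType.unprocessed_scores.value not in types:
        return [
            _f(
                Severity.warning,
                "PRENORMALIZED_SCORES_SHARED",
                "/depositions" if "depositions" in doc else "",
                "scores prior to normalization or imputation should also be reported",
            )
        ]
    return []


@_rule("REFERENCE_IDENTICAL_ALLELE", Severity.info)
def _r_refidentical(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    targets = {
        t.get("digest"): t.get("residues")
        for t in doc.get("targets", [])
        if isinstance(t, dict)
    } if isinstance(doc.get("targets"), list) else {}
    links = doc.get("referenceLinks")
    out = []
    if isinstance(links, list):
        for i, link in enumerate(links):
            if not isinstance(link, dict):
                continue
            ctx = link.get("referenceContext")
            residues = targets.get(link.get("targetDigest"))
            if not (_nonempty_str(ctx) and _nonempty_str(residues)):
                continue
            window = ctx[: len(residues)]
            if link.get("strand") == "minus":
                try:
                    window = reverse_complement(window)
                except AlphabetError:
                    continue
            if window != residues:
                out.append(
                    _f(
                        Severity.info,
                        "REFERENCE_IDENTICAL_ALLELE",
                        f"/referenceLinks/{i}/referenceContext",
                        "target differs from the aligned reference window; a "
                        "reference-identical allele is suggested when it does not "
                        "otherwise affect the study design",
                    )
                )
    return out


@_rule("CUSTOM_TERM", Severity.warning)
def _r_customterm(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    """Terms outside the bundled shortlist are allowed, with a warning."""
    checks: list[tuple[str, str, Any]] = []
    if isinstance(doc.get("projectScopeTerm"), dict):
        checks.append(("projectScope", "/projectScopeTerm", doc["projectScopeTerm"]))
    lib = doc.get("library")
    if isinstance(lib, dict):
        if isinstance(lib.get("generationMethodTerm"), dict):
            checks.append(("libraryGeneration", "/library/generationMethodTerm", lib["generationMethodTerm"]))
        if isinstance(lib.get("deliveryMethodTerm"), dict):
            checks.append(("libraryIntegrationExpression", "/library/deliveryMethodTerm", lib["deliveryMethodTerm"]))
    assay = doc.get("assay")
    if isinstance(assay, dict) and isinstance(assay.get("readoutTerms"), list):
        for i, t in enumerate(assay["readoutTerms"]):
            if isinstance(t, dict):
                checks.append(("assayType", f"/assay/readoutTerms/{i}", t))
    seq = doc.get("sequencing")
    if isinstance(seq, dict) and isinstance(seq.get("methodTerm"), dict):
        checks.append(("sequencingMethod", "/sequencing/methodTerm", seq["methodTerm"]))
    out = []
    for category, path, term in checks:
        label = term.get("label", "")
        if _nonempty_str(label) and label not in reg.labels_in(category):
            out.append(
                _f(
                    Severity.warning,
                    "CUSTOM_TERM",
                    path,
                    f"term {label!r} is not in the {category} shortlist; custom "
                    "terms are welcome but reduce comparability",
                )
            )
    return out


@_rule("UNKNOWN_FIELD", Severity.info)
def _r_unknown(doc: dict, reg: TermRegistry) -> list[ValidationFinding]:
    out = []
    for key in doc:
        if key not in KNOWN_DOC_FIELDS:
            out.append(
                _f(
                    Severity.info,
                    "UNKNOWN_FIELD",
                    f"/{key.replace('~', '~0').replace('/', '~1')}",
                    f"field {key!r} is not part of the document model; it is "
                    "preserved but not validated",
                )
            )
    return out


RULE_TABLE: dict[str, Severity] = {rule_id: sev for rule_id, sev, _ in _RULES}


def validate_metadata(
    doc: "MetadataDocument | dict", registry: TermRegistry | None = None
) -> list[ValidationFinding]:
    """Run every reporting rule over a document; return sorted findings.

    The result is empty iff the document satisfies every rule.  Findings are
    sorted by (severity, path); the function is deterministic and
    side-effect-free, and every finding's path resolves by JSON Pointer in
    the input document.
    """
    if registry is None:
        registry = load_registry()
    data = doc.data if isinstance(doc, MetadataDocument) else doc
    findings: list[ValidationFinding] = []
    for _rule_id, _sev, fn in _RULES:
        findings.extend(fn(data, registry))
    return sorted(findings, key=lambda f: (_SEVERITY_RANK[f.severity], f.path, f.rule_id))


def findings_to_jsonl(findings: Iterable[ValidationFinding]) -> str:
    return "\n".join(json.dumps(f.to_dict(), sort_keys=True) for f in findings)


def findings_to_text(findings: Iterable[ValidationFinding]) -> str:
    lines = [str(f) for f in findings]
    return "\n".join(lines) if lines else "no findings"


# --- schema emission ---------------------------------------------------------

SCHEMA_DIALECT = "https://json-schema.org/draft/2020-12/schema"


def emit_schema(registry: TermRegistry | None = None) -> dict:
    """JSON Schema (Draft 2020-12) for MetadataDocument.

    The schema's hard constraints are exactly the validator's error-severity
    rules; recommendation-level rules (warnings/info) are deliberately not
    enforced so that schema acceptance matches "no errors".  Per-category
    term shortlists are embedded as enums under ``$defs`` for tooling.
    """
    if registry is None:
        registry = load_registry()
    term_enums = {
        f"{cat}Terms": {
            "description": f"Shortlist of {cat} vocabulary terms (custom terms allowed).",
            "enum": sorted(t.label for t in registry.terms_in(cat)),
        }
        for cat in registry.categories
    }
    controlled_term = {
        "type": "object",
        "properties": {
            "category": {"type": "string", "enum": list(registry.categories)},
            "label": {"type": "string", "minLength": 1},
            "curie": {"type": "string", "pattern": CURIE_RE.pattern},
        },
        "required": ["label"],
    }
    schema = {
        "$schema": SCHEMA_DIALECT,
        "$id": "https://mavekit.invalid/schema/metadata-document.json",
        "title": "MAVE metadata document",
        "description": (
            "Minimum-information metadata for one multiplexed assay of "
            f"variant effect; vocabulary registry version {registry.version}."
        ),
        "type": "object",
        "properties": {
            "title": {"type": "string"},
            "projectScopeTerm": {"$ref": "#/$defs/controlledTerm"},
            "targets": {
                "type": "array",
                "minItems": 1,
                "items": {
                    "type": "object",
                    "properties": {
                        "label": {"type": "string"},
                        "residues": {"type": "string", "minLength": 1},
                        "moleculeType": {"enum": ["dna", "protein"]},
                        "digest": {
                            "type": "string",
                            "pattern": "^[A-Za-z0-9_-]{32}$",
                        },
                    },
                    "required": ["residues"],
                },
            },
            "referenceLinks": {
                "type": "array",
                "minItems": 1,
                "items": {
                    "type": "object",
                    "properties": {
                        "targetDigest": {"type": "string"},
                        "accession": {
                            "type": "string",
                            "pattern": r"^.+\.[1-9][0-9]*$",
                        },
                        "anchorPosition": {"type": "integer", "minimum": 1},
                        "strand": {"enum": ["plus", "minus"]},
                        "referenceContext": {"type": "string"},
                    },
                    "required": ["accession", "anchorPosition"],
                },
            },
            "modelSystem": {
                "type": "object",
                "properties": {
                    "taxonCurie": {"type": "string", "pattern": r"^NCBITaxon:\d+$"},
                    "cellLineCurie": {"type": "string", "pattern": r"^CLO:[A-Za-z0-9._-]+$"},
                    "description": {"type": "string"},
                },
                "required": ["taxonCurie"],
            },
            "library": {
                "type": "object",
                "properties": {
                    "generationMode": {"enum": [m.value for m in GenerationMode]},
                    "generationMethodTerm": {"$ref": "#/$defs/controlledTerm"},
                    "deliveryMethodTerm": {"$ref": "#/$defs/controlledTerm"},
                },
                "required": ["generationMode"],
            },
            "assay": {
                "type": "object",
                "properties": {
                    "readoutTerms": {
                        "type": "array",
                        "minItems": 1,
                        "items": {"$ref": "#/$defs/controlledTerm"},
                    },
                    "environmentalVariables": {"type": "array"},
                    "protocolUri": {"type": "string"},
                    "calibrationVariants": {"type": "array"},
                },
                "required": ["readoutTerms"],
            },
            "sequencing": {
                "type": "object",
                "properties": {
                    "methodTerm": {"$ref": "#/$defs/controlledTerm"},
                    "rawReadDepositions": {"type": "array"},
                },
                "required": ["methodTerm"],
            },
            "disease": {
                "type": "object",
                "properties": {
                    "diseaseCurie": {"type": "string", "pattern": CURIE_RE.pattern},
                    "geneDiseaseMechanism": {"type": "string"},
                    "assayMechanismRelevance": {"type": "string"},
                },
            },
            "analysis": {
                "type": "object",
                "properties": {
                    "pipelineDescription": {"type": "string"},
                    "software": {"type": "array"},
                    "codeRepositoryUri": {"type": "string"},
                    "archiveDoi": {"type": "string"},
                },
            },
            "depositions": {
                "type": "array",
                "items": {
                    "type": "object",
                    "properties": {
                        "dataType": {"enum": [d.value for d in DataType]},
                        "location": {"type": "string"},
                        "accessionOrUri": {"type": "string"},
                    },
                    "required": ["dataType"],
                },
            },
        },
        "required": [
            "targets",
            "referenceLinks",
            "modelSystem",
            "library",
            "assay",
            "sequencing",
        ],
        "$defs": {"controlledTerm": controlled_term, **term_enums},
    }
    return schema
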