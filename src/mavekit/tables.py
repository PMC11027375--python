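"""Variant score sets and count sets: CSV I/O and validation.

Score tables follow the MaveDB CSV convention: a header row with ``hgvs_nt``
and/or ``hgvs_pro`` variant columns and a ``score`` column; any further
columns ride along as extras.  Count tables have one variant column plus one
column of non-negative integer counts per sample/timepoint.

Validation checks each variant string against the grammar and the target
sequence, and checks the set against the data-sharing recommendations: raw
counts should accompany scores, and normalized or imputed scores should be
published alongside the scores they were derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import (
    BoundsError,
    DuplicateRecordError,
    MaveHgvsParseError,
    ReferenceMismatchError,
    TableFormatError,
)
from . import mavehgvs
from .seqid import MoleculeType, TargetSequence
from .vocabulary import Severity, ValidationFinding

VARIANT_COLUMNS = ("hgvs_nt", "hgvs_pro")
MISSING_TOKENS = {"", "NA"}


class ScoreKind(str, Enum):
    raw = "raw"
    normalized = "normalized"
    imputed = "imputed"


@dataclass
class ScoreRecord:
    hgvs_nt: str | None
    hgvs_pro: str | None
    score: float | None
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def variant_key(self) -> str:
        return self.hgvs_nt or self.hgvs_pro or ""


@dataclass
class ScoreSet:
    records: list[ScoreRecord]
    score_kind: ScoreKind = ScoreKind.raw
    target_digest: str | None = None

    def variant_strings(self) -> set[str]:
        return {r.variant_key for r in self.records}


@dataclass
class CountSet:
    samples: list[str]
    records: list[tuple[str, list[int]]]
    target_digest: str | None = None

    def variant_strings(self) -> set[str]:
        return {v for v, _ in self.records}


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_scores(
    path: str | Path,
    score_kind: ScoreKind | str = ScoreKind.raw,
    target_digest: str | None = None,
) -> ScoreSet:
    """Read a MaveDB-style score CSV.

    Empty cells and ``NA`` in the score column read as missing, never zero.
    """
    df = _read_csv(path)
    headers = list(df.columns)
    if "score" not in headers or not any(c in headers for c in VARIANT_COLUMNS):
        raise TableFormatError(
            f"score file {path} needs a 'score' column and at least one of "
            f"{VARIANT_COLUMNS}; found headers: {headers}"
        )
    extra_cols = [c for c in headers if c != "score" and c not in VARIANT_COLUMNS]
    records: list[ScoreRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        nt = row.get("hgvs_nt", "") or None
        pro = row.get("hgvs_pro", "") or None
        if nt is None and pro is None:
            raise TableFormatError(f"row {idx + 2} of {path} has no variant string")
        raw_score = str(row["score"]).strip()
        score = None if raw_score in MISSING_TOKENS else float(raw_score)
        rec = ScoreRecord(
            hgvs_nt=nt,
            hgvs_pro=pro,
            score=score,
            extras={c: row[c] for c in extra_cols},
        )
        if rec.variant_key in seen:
            raise DuplicateRecordError(
                f"variant {rec.variant_key!r} appears more than once in {path}"
            )
        seen.add(rec.variant_key)
        records.append(rec)
    return ScoreSet(records=records, score_kind=ScoreKind(score_kind), target_digest=target_digest)


def write_scores(scores: ScoreSet, path: str | Path) -> None:
    """Write a score set back to CSV in canonical column order."""
    extra_cols = sorted({k for r in scores.records for k in r.extras})
    rows = []
    for r in scores.records:
        row = {
            "hgvs_nt": r.hgvs_nt or "",
            "hgvs_pro": r.hgvs_pro or "",
            "score": "NA" if r.score is None else repr(float(r.score)),
        }
        row.update({c: r.extras.get(c, "") for c in extra_cols})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["hgvs_nt", "hgvs_pro", "score", *extra_cols])
    df.to_csv(path, index=False)


def read_counts(path: str | Path, target_digest: str | None = None) -> CountSet:
    """Read a count CSV: one variant column, every other column a sample."""
    df = _read_csv(path)
    headers = list(df.columns)
    variant_col = next((c for c in VARIANT_COLUMNS if c in headers), None)
    if variant_col is None:
        raise TableFormatError(
            f"count file {path} needs a variant column ({VARIANT_COLUMNS}); "
            f"found headers: {headers}"
        )
    samples = [c for c in headers if c != variant_col]
    if not samples:
        raise TableFormatError(f"count file {path} has no sample columns")
    records: list[tuple[str, list[int]]] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        variant = row[variant_col]
        if variant in seen:
            raise DuplicateRecordError(
                f"variant {variant!r} appears more than once in {path}"
            )
        seen.add(variant)
        counts = []
        for s in samples:
            value = float(row[s])
            if value < 0 or value != int(value):
                raise TableFormatError(
                    f"row {idx + 2} of {path}: count {row[s]!r} in {s!r} is not a "
                    "non-negative integer"
                )
            counts.append(int(value))
        records.append((variant, counts))
    return CountSet(samples=samples, records=records, target_digest=target_digest)


def write_counts(counts: CountSet, path: str | Path) -> None:
    rows = [
        {"hgvs_nt": v, **dict(zip(counts.samples, c))} for v, c in counts.records
    ]
    df = pd.DataFrame(rows, columns=["hgvs_nt", *counts.samples])
    df.to_csv(path, index=False)


def _finding(sev: Severity, rule: str, path: str, msg: str) -> ValidationFinding:
    return ValidationFinding(sev, rule, path, msg)


def validate_scoreset(
    scores: ScoreSet,
    target: TargetSequence,
    counts: CountSet | None = None,
    protein_target: TargetSequence | None = None,
    raw_scores_available: bool = False,
) -> list[ValidationFinding]:
    """Validate a score set against its target and the sharing rules.

    Per record: the variant must parse, stay in bounds, and agree with the
    target's residues (each an error finding).  ``hgvs_nt`` is checked
    against the DNA target; ``hgvs_pro`` against ``protein_target`` when
    supplied, otherwise syntax-only with a warning.  Set-level: missing
    counts, normalized/imputed scores without a raw sibling, and
    score/count variant-set disagreement are warnings.
    """
    findings: list[ValidationFinding] = []
    for i, rec in enumerate(scores.records):
        for col, text in (("hgvs_nt", rec.hgvs_nt), ("hgvs_pro", rec.hgvs_pro)):
            if text is None:
                continue
            path = f"/records/{i}/{col}"
            try:
                variant = mavehgvs.parse_variant(text)
            except MaveHgvsParseError as exc:
                findings.append(
                    _finding(Severity.error, "VARIANT_GRAMMAR", path, str(exc))
                )
                continue
            if col == "hgvs_nt":
                check_target = target
            elif protein_target is not None:
                check_target = protein_target
            else:
                findings.append(
                    _finding(
                        Severity.warning,
                        "PROTEIN_TARGET_UNAVAILABLE",
                        path,
                        f"{text!r} checked for syntax only: no protein target supplied",
                    )
                )
                continue
            for single in mavehgvs.decompose(variant):
                try:
                    mavehgvs.apply_variant(check_target, single)
                except BoundsError as exc:
                    findings.append(
                        _finding(Severity.error, "VARIANT_OUT_OF_BOUNDS", path, str(exc))
                    )
                except ReferenceMismatchError as exc:
                    findings.append(
                        _finding(Severity.error, "VARIANT_REFERENCE_MISMATCH", path, str(exc))
                    )
                except MaveHgvsParseError as exc:
                    findings.append(
                        _finding(Severity.error, "VARIANT_GRAMMAR", path, str(exc))
                    )
    if counts is None:
        findings.append(
            _finding(
                Severity.warning,
                "RAW_COUNTS_SHARED",
                "",
                "no count set accompanies these scores; raw counts should be "
                "shared for each dataset",
            )
        )
    else:
        if counts.variant_strings() != scores.variant_strings():
            only_scores = len(scores.variant_strings() - counts.variant_strings())
            only_counts = len(counts.variant_strings() - scores.variant_strings())
            findings.append(
                _finding(
                    Severity.warning,
                    "SCORE_COUNT_CONSISTENCY",
                    "",
                    f"score and count variant sets differ ({only_scores} only in "
                    f"scores, {only_counts} only in counts)",
                )
            )
    if scores.score_kind in (ScoreKind.normalized, ScoreKind.imputed) and not raw_scores_available:
        findings.append(
            _finding(
                Severity.warning,
                "PRENORMALIZED_SCORES_SHARED",
                "",
                f"{scores.score_kind.value} scores without a declared raw-score "
                "sibling; scores prior to normalization or imputation should be reported",
            )
        )
    rank = {Severity.error: 0, Severity.warning: 1, Severity.info: 2}
    return sorted(findings, key=lambda f: (rank[f.severity], f.path, f.rule_id))


def saturation_completeness(scores: ScoreSet, target: TargetSequence) -> float:
    """Fraction of all possible single-residue substitutions that have a record.

    A variant effect map ideally covers all single-nucleotide (or single
    amino-acid) variants of the target; this is the observed coverage of
    that saturation library, in [0, 1].
    """
    universe = {
        mavehgvs.format_variant(v) for v in mavehgvs.enumerate_saturation(target)
    }
    want_col = "hgvs_pro" if target.molecule_type is MoleculeType.protein else "hgvs_nt"
    observed = set()
    for rec in scores.records:
        text = getattr(rec, want_col)
        if text is None:
            continue
        try:
            variant = mavehgvs.parse_variant(text)
        except MaveHgvsParseError:
            continue
        canonical = mavehgvs.format_variant(variant)
        if canonical in universe:
            observed.add(canonical)
    return len(observed) / len(universe)
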