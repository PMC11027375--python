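"""Parsing, formatting, and application of MAVE-HGVS variant strings.

MAVE-HGVS is a strict, machine-parsable subset of HGVS nomenclature for
describing variants relative to a full target sequence.  Because MAVE targets
are contiguous assayed sequences, the grammar here deliberately admits plain
integer positions only: no intronic (``+``/``-``) or UTR offsets, no uncertain
``(...)`` ranges, no rearrangements.  Supported productions:

==================  =========================  =========================
kind                nucleotide (c./n./g.)      protein (p.)
==================  =========================  =========================
substitution        ``c.1A>G``                 ``p.Glu27Trp``
deletion            ``c.3_5del``, ``c.3del``   ``p.Lys2_Gly3del``
duplication         ``c.3_5dup``               ``p.Gly3dup``
insertion           ``c.3_4insTT``             ``p.Lys2_Gly3insTrp``
delins              ``c.3_5delinsAT``          ``p.Lys2_Gly3delinsArg``
synonymous          —                          ``p.Arg5=``, ``p.=``
multi-edit          ``c.[1A>G;5del]``          ``p.[Glu2Lys;Gly5del]``
==================  =========================  =========================

Protein residues are written with three-letter codes; one-letter input is
accepted and normalized to three-letter form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

from .errors import (
    BoundsError,
    MaveHgvsParseError,
    ReferenceMismatchError,
)
from .seqid import AMINO_ACIDS, MoleculeType, TargetSequence

AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

_AA3 = "|".join(AA_3TO1)
_AA = rf"(?:{_AA3}|[ACDEFGHIKLMNPQRSTVWY*])"
_NT = "[ACGT]"


class EditKind(str, Enum):
    substitution = "substitution"
    deletion = "deletion"
    duplication = "duplication"
    insertion = "insertion"
    delins = "delins"
    synonymous = "synonymousEquals"


@dataclass(frozen=True)
class SequenceEdit:
    """One edit on a target sequence, in 1-based closed coordinates.

    For protein edits ``ref``/``alt`` hold three-letter codes; ranged edits
    store the two flanking residue codes concatenated (e.g. ``"LysGly"``).
    """

    kind: EditKind
    start: int
    end: int
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise MaveHgvsParseError(
                f"invalid positions {self.start}_{self.end}: need 1 <= start <= end"
            )
        if self.kind is EditKind.insertion and self.end != self.start + 1:
            raise MaveHgvsParseError(
                "insertion positions must be adjacent (start+1 == end)"
            )
        if self.kind is EditKind.insertion and not self.alt:
            raise MaveHgvsParseError("insertion requires inserted residues")
        if self.kind is EditKind.substitution and self.start != self.end:
            raise MaveHgvsParseError("substitution is single-position")

    @property
    def span_length(self) -> int:
        """Number of target residues the edit consumes."""
        if self.kind in (EditKind.insertion, EditKind.synonymous):
            return 0
        return self.end - self.start + 1

    def length_delta(self, alt_length: int | None = None) -> int:
        """Change in sequence length when this edit is applied."""
        n = self.end - self.start + 1
        if self.kind is EditKind.substitution or self.kind is EditKind.synonymous:
            return 0
        if self.kind is EditKind.deletion:
            return -n
        if self.kind is EditKind.duplication:
            return n
        alt_n = alt_length if alt_length is not None else _residue_count(self.alt or "")
        if self.kind is EditKind.insertion:
            return alt_n
        return alt_n - n  # delins


def _residue_count(code_string: str) -> int:
    """Residue count of an alt string that may use three-letter codes."""
    if not code_string:
        return 0
    if len(code_string) % 3 == 0 and _split_aa3(code_string) is not None:
        return len(code_string) // 3
    return len(code_string)


def _split_aa3(s: str) -> list[str] | None:
    if len(s) % 3:
        return None
    codes = [s[i : i + 3] for i in range(0, len(s), 3)]
    return codes if all(c in AA_3TO1 for c in codes) else None


def aa_to_one(code_string: str) -> str:
    """Convert a (possibly three-letter-coded) residue string to one-letter."""
    codes = _split_aa3(code_string)
    if codes is not None:
        return "".join(AA_3TO1[c] for c in codes)
    return code_string


def aa_to_three(code_string: str) -> str:
    """Normalize a residue string to three-letter codes."""
    if _split_aa3(code_string) is not None:
        return code_string
    try:
        return "".join(AA_1TO3[c] for c in code_string)
    except KeyError as exc:
        raise MaveHgvsParseError(f"unknown amino-acid code in {code_string!r}") from exc


@dataclass(frozen=True)
class MaveHgvsVariant:
    """A parsed MAVE-HGVS variant: a prefix plus one or more ordered edits."""

    prefix: str
    edits: tuple[SequenceEdit, ...]
    raw_text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.prefix not in ("c", "n", "g", "p"):
            raise MaveHgvsParseError(f"unsupported prefix {self.prefix!r}")
        if not self.edits:
            raise MaveHgvsParseError("variant needs at least one edit")
        object.__setattr__(self, "edits", tuple(self.edits))
        prev: SequenceEdit | None = None
        for e in self.edits:
            if prev is not None and e.start <= prev.end:
                raise MaveHgvsParseError(
                    f"edits out of order or overlapping at position {e.start}"
                )
            prev = e

    @property
    def is_multi(self) -> bool:
        return len(self.edits) > 1

    def __str__(self) -> str:
        return format_variant(self)


# --- parsing -----------------------------------------------------------------

_NT_PATTERNS = [
    (EditKind.substitution, re.compile(rf"^(\d+)({_NT})>({_NT})$")),
    (EditKind.delins, re.compile(rf"^(\d+)(?:_(\d+))?delins({_NT}+)$")),
    (EditKind.deletion, re.compile(r"^(\d+)(?:_(\d+))?del$")),
    (EditKind.duplication, re.compile(r"^(\d+)(?:_(\d+))?dup$")),
    (EditKind.insertion, re.compile(rf"^(\d+)_(\d+)ins({_NT}+)$")),
]

_PRO_SUB = re.compile(rf"^({_AA})(\d+)({_AA})$")
_PRO_EQ = re.compile(rf"^(?:({_AA})(\d+))?=$")
_PRO_DELINS = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?delins((?:{_AA3})+|[A-Z*]+)$")
_PRO_DEL = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?del$")
_PRO_DUP = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?dup$")
_PRO_INS = re.compile(rf"^({_AA})(\d+)_({_AA})(\d+)ins((?:{_AA3})+|[A-Z*]+)$")

_FORBIDDEN_NT = "+*()="
_FORBIDDEN_PRO = "+()>"


def _norm_aa(code: str) -> str:
    return code if code in AA_3TO1 else AA_1TO3[code]


def _check_forbidden(body: str, text: str, prefix: str) -> None:
    forbidden = _FORBIDDEN_PRO if prefix == "p" else _FORBIDDEN_NT
    for ch in forbidden:
        idx = body.find(ch)
        if idx >= 0 and not (prefix == "p" and ch == "="):
            raise MaveHgvsParseError(
                f"unsupported token {ch!r}", text, text.index(body) + idx
            )
    if prefix != "p":
        # UTR/intronic negative offsets like c.-12A>G
        m = re.search(r"(?<![0-9])-\d", body)
        if m:
            raise MaveHgvsParseError(
                "negative/UTR positions are not representable on a contiguous target",
                text,
                text.index(body) + m.start(),
            )


def _parse_nt_edit(body: str, text: str) -> SequenceEdit:
    for kind, pat in _NT_PATTERNS:
        m = pat.match(body)
        if m is None:
            continue
        if kind is EditKind.substitution:
            p = int(m.group(1))
            return SequenceEdit(kind, p, p, ref=m.group(2), alt=m.group(3))
        if kind is EditKind.insertion:
            s, e = int(m.group(1)), int(m.group(2))
            return SequenceEdit(kind, s, e, alt=m.group(3))
        s = int(m.group(1))
        e = int(m.group(2)) if m.group(2) else s
        alt = m.group(3) if kind is EditKind.delins else None
        return SequenceEdit(kind, s, e, alt=alt)
    raise MaveHgvsParseError(f"unrecognized edit {body!r}", text, text.index(body))


def _parse_pro_edit(body: str, text: str) -> SequenceEdit:
    m = _PRO_SUB.match(body)
    if m:
        p = int(m.group(2))
        return SequenceEdit(
            EditKind.substitution, p, p, ref=_norm_aa(m.group(1)), alt=_norm_aa(m.group(3))
        )
    m = _PRO_EQ.match(body)
    if m:
        if m.group(1) is None:
            return SequenceEdit(EditKind.synonymous, 1, 1)
        p = int(m.group(2))
        return SequenceEdit(EditKind.synonymous, p, p, ref=_norm_aa(m.group(1)))
    for kind, pat in (
        (EditKind.delins, _PRO_DELINS),
        (EditKind.deletion, _PRO_DEL),
        (EditKind.duplication, _PRO_DUP),
    ):
        m = pat.match(body)
        if m is None:
            continue
        s = int(m.group(2))
        if m.group(3) is not None:
            e = int(m.group(4))
            ref = _norm_aa(m.group(1)) + _norm_aa(m.group(3))
        else:
            e = s
            ref = _norm_aa(m.group(1))
        alt = aa_to_three(m.group(5)) if kind is EditKind.delins else None
        return SequenceEdit(kind, s, e, ref=ref, alt=alt)
    m = _PRO_INS.match(body)
    if m:
        s, e = int(m.group(2)), int(m.group(4))
        ref = _norm_aa(m.group(1)) + _norm_aa(m.group(3))
        return SequenceEdit(EditKind.insertion, s, e, ref=ref, alt=aa_to_three(m.group(5)))
    raise MaveHgvsParseError(f"unrecognized edit {body!r}", text, text.index(body))


def parse_variant(text: str) -> MaveHgvsVariant:
    """Parse a MAVE-HGVS string into its structured form.

    Raises :class:`MaveHgvsParseError` on anything outside the supported
    grammar, including intronic/UTR offsets and uncertain positions.
    """
    if not text or not text.strip():
        raise MaveHgvsParseError("empty variant string", text, 0)
    text = text.strip()
    m = re.match(r"^([A-Za-z])\.(.+)$", text)
    if m is None:
        raise MaveHgvsParseError("expected '<prefix>.<edit>' form", text, 0)
    prefix, rest = m.group(1), m.group(2)
    if prefix not in ("c", "n", "g", "p"):
        raise MaveHgvsParseError(f"unsupported prefix {prefix!r}", text, 0)
    parse_edit = _parse_pro_edit if prefix == "p" else _parse_nt_edit
    if rest.startswith("["):
        if not rest.endswith("]"):
            raise MaveHgvsParseError("unterminated '[' multi-edit", text, len(text) - 1)
        bodies = rest[1:-1].split(";")
        if any(not b for b in bodies):
            raise MaveHgvsParseError("empty edit in multi-edit list", text, 0)
    else:
        bodies = [rest]
    edits = []
    for body in bodies:
        _check_forbidden(body, text, prefix)
        edits.append(parse_edit(body, text))
    return MaveHgvsVariant(prefix=prefix, edits=tuple(edits), raw_text=text)


# --- formatting --------------------------------------------------------------

def _format_pro_pos(ref: str | None, pos: int, which: int = 0) -> str:
    code = ""
    if ref:
        codes = _split_aa3(ref) or []
        if which < len(codes):
            code = codes[which]
        elif codes:
            code = codes[0]
    return f"{code}{pos}"


def _format_edit(e: SequenceEdit, prefix: str) -> str:
    if prefix == "p":
        if e.kind is EditKind.substitution:
            return f"{e.ref}{e.start}{e.alt}"
        if e.kind is EditKind.synonymous:
            return f"{e.ref}{e.start}=" if e.ref else "="
        left = _format_pro_pos(e.ref, e.start, 0)
        right = _format_pro_pos(e.ref, e.end, 1)
        if e.kind is EditKind.insertion:
            return f"{left}_{right}ins{e.alt}"
        rng = left if e.start == e.end else f"{left}_{right}"
        if e.kind is EditKind.deletion:
            return f"{rng}del"
        if e.kind is EditKind.duplication:
            return f"{rng}dup"
        return f"{rng}delins{e.alt}"
    if e.kind is EditKind.substitution:
        return f"{e.start}{e.ref}>{e.alt}"
    if e.kind is EditKind.insertion:
        return f"{e.start}_{e.end}ins{e.alt}"
    rng = str(e.start) if e.start == e.end else f"{e.start}_{e.end}"
    if e.kind is EditKind.deletion:
        return f"{rng}del"
    if e.kind is EditKind.duplication:
        return f"{rng}dup"
    if e.kind is EditKind.delins:
        return f"{rng}delins{e.alt}"
    raise MaveHgvsParseError(f"cannot format edit kind {e.kind} with prefix {prefix}")


def format_variant(v: MaveHgvsVariant) -> str:
    """Canonical MAVE-HGVS string for a structured variant.

    ``parse_variant(format_variant(v))`` is structurally equal to ``v``.
    Constructing an invariant-violating variant raises before this point, so
    formatting only sees well-formed input.
    """
    bodies = [_format_edit(e, v.prefix) for e in v.edits]
    if len(bodies) == 1:
        return f"{v.prefix}.{bodies[0]}"
    return f"{v.prefix}.[{';'.join(bodies)}]"


# --- application -------------------------------------------------------------

_PREFIX_FOR = {MoleculeType.dna: ("c", "n", "g"), MoleculeType.protein: ("p",)}


def _edit_ref_one(e: SequenceEdit, prefix: str) -> str | None:
    if e.ref is None:
        return None
    return aa_to_one(e.ref) if prefix == "p" else e.ref


def _edit_alt_one(e: SequenceEdit, prefix: str) -> str:
    if e.alt is None:
        return ""
    return aa_to_one(e.alt) if prefix == "p" else e.alt


def _check_ref(residues: str, pos: int, expected: str) -> None:
    observed = residues[pos - 1]
    if observed != expected:
        raise ReferenceMismatchError(pos, expected, observed)


def apply_variant(target: TargetSequence, v: MaveHgvsVariant) -> str:
    """Apply a variant to a target sequence, returning the edited residues.

    Edits are applied right-to-left so that all positions refer to the
    unedited target.  Stated reference residues are checked against the
    target and a mismatch raises :class:`ReferenceMismatchError`.
    """
    if v.prefix not in _PREFIX_FOR[target.molecule_type]:
        raise MaveHgvsParseError(
            f"prefix {v.prefix!r} incompatible with {target.molecule_type.value} target"
        )
    residues = target.residues
    n = len(residues)
    for e in v.edits:
        last = e.start if e.kind is EditKind.insertion else e.end
        if last > n or e.start > n:
            raise BoundsError(
                f"edit at {e.start}_{e.end} exceeds target length {n}"
            )
    out = residues
    for e in sorted(v.edits, key=lambda e: e.start, reverse=True):
        ref1 = _edit_ref_one(e, v.prefix)
        alt1 = _edit_alt_one(e, v.prefix)
        if e.kind is EditKind.substitution:
            _check_ref(residues, e.start, ref1)
            out = out[: e.start - 1] + alt1 + out[e.start :]
        elif e.kind is EditKind.synonymous:
            if ref1:
                _check_ref(residues, e.start, ref1)
        elif e.kind is EditKind.deletion:
            _check_span_refs(residues, e, ref1)
            out = out[: e.start - 1] + out[e.end :]
        elif e.kind is EditKind.duplication:
            _check_span_refs(residues, e, ref1)
            out = out[: e.end] + residues[e.start - 1 : e.end] + out[e.end :]
        elif e.kind is EditKind.insertion:
            _check_span_refs(residues, e, ref1)
            out = out[: e.start] + alt1 + out[e.start :]
        elif e.kind is EditKind.delins:
            _check_span_refs(residues, e, ref1)
            out = out[: e.start - 1] + alt1 + out[e.end :]
    return out


def _check_span_refs(residues: str, e: SequenceEdit, ref1: str | None) -> None:
    """Check stated flanking/endpoint residues of a ranged (protein) edit."""
    if not ref1:
        return
    _check_ref(residues, e.start, ref1[0])
    if len(ref1) > 1:
        _check_ref(residues, e.end, ref1[-1])


def enumerate_saturation(target: TargetSequence) -> list[MaveHgvsVariant]:
    """All single-residue substitutions of a target, in deterministic order.

    Position-major, alphabetical alternate.  A DNA target of length L yields
    3L variants; a protein target of length N (without stop residues) yields
    19N, drawing alternates from the 20 standard amino acids.
    """
    variants: list[MaveHgvsVariant] = []
    if target.molecule_type is MoleculeType.dna:
        for i, ref in enumerate(target.residues, start=1):
            for alt in "ACGT":
                if alt == ref:
                    continue
                e = SequenceEdit(EditKind.substitution, i, i, ref=ref, alt=alt)
                v = MaveHgvsVariant("c", (e,))
                variants.append(
                    MaveHgvsVariant("c", (e,), raw_text=format_variant(v))
                )
    else:
        for i, ref in enumerate(target.residues, start=1):
            for alt in AMINO_ACIDS:
                if alt == ref:
                    continue
                e = SequenceEdit(
                    EditKind.substitution, i, i, ref=AA_1TO3[ref], alt=AA_1TO3[alt]
                )
                v = MaveHgvsVariant("p", (e,))
                variants.append(
                    MaveHgvsVariant("p", (e,), raw_text=format_variant(v))
                )
    return variants


def decompose(v: MaveHgvsVariant) -> Iterator[MaveHgvsVariant]:
    """Yield single-edit variants from a (possibly multi-edit) variant."""
    for e in v.edits:
        single = MaveHgvsVariant(v.prefix, (e,))
        yield MaveHgvsVariant(v.prefix, (e,), raw_text=format_variant(single))
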