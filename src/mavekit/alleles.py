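"""VRS-compatible allele representation and target-to-reference mapping.

Variants are exchanged as *simple alleles*: an inter-residue (0-based,
half-open) location on an identified sequence plus a replacement state.
Inter-residue coordinates index the gaps between residues, which makes
insertions unambiguous.  Alleles are canonicalized by fully-justified
normalization: every representation of the same edit within a repeat context
collapses to one allele spanning the entire ambiguity interval, so equality
of normalized alleles is equality of meaning, and the sha512t24u identifier
of the canonical serialization is a globally unique variant identifier.

A target allele is projected onto its linked reference through an ungapped
anchor (position + strand); the projected variant carries the
``homologous_to`` relation and an emitted reference-side HGVS ``g.`` string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    BoundsError,
    DecomposeError,
    MavekitError,
    OutOfWindowError,
    WrongSequenceError,
)
from .mavehgvs import EditKind, MaveHgvsVariant, aa_to_one
from .seqid import (
    ReferenceLink,
    Strand,
    TargetSequence,
    compute_sha512t24u,
    reverse_complement,
)

HOMOLOGOUS_TO = "homologous_to"


@dataclass(frozen=True)
class InterbaseLocation:
    """A 0-based half-open interval on an identified sequence.

    ``sequence_id`` is the sha512t24u digest of the sequence for target
    alleles; reference-side alleles use the versioned accession string,
    since the full reference sequence (and hence its digest) is not
    available offline.
    """

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise BoundsError(f"invalid interbase interval [{self.start}, {self.end})")

    def to_dict(self) -> dict:
        return {"sequenceId": self.sequence_id, "start": self.start, "end": self.end}


@dataclass(frozen=True)
class SimpleAllele:
    """Replacement of the residues in ``location`` with ``state``."""

    location: InterbaseLocation
    state: str

    def apply(self, residues: str) -> str:
        loc = self.location
        if loc.end > len(residues):
            raise BoundsError(
                f"allele [{loc.start}, {loc.end}) exceeds sequence length {len(residues)}"
            )
        return residues[: loc.start] + self.state + residues[loc.end :]

    def to_dict(self) -> dict:
        return {"location": self.location.to_dict(), "state": self.state}


@dataclass(frozen=True)
class MappedVariant:
    """A target allele and its homologous projection onto a linked reference."""

    target_allele: SimpleAllele
    reference_allele: SimpleAllele
    reference_hgvs: str
    relation: str = field(default=HOMOLOGOUS_TO)

    def __post_init__(self) -> None:
        if self.relation != HOMOLOGOUS_TO:
            raise MavekitError(f"relation must be {HOMOLOGOUS_TO!r}")

    def to_dict(self) -> dict:
        return {
            "targetAllele": self.target_allele.to_dict(),
            "referenceAllele": self.reference_allele.to_dict(),
            "relation": self.relation,
            "referenceHgvs": self.reference_hgvs,
        }


def to_allele(v: MaveHgvsVariant, target: TargetSequence) -> SimpleAllele:
    """Convert a single-edit variant to an inter-residue allele on the target.

    1-based closed coordinates become 0-based half-open: a substitution at p
    occupies [p-1, p); a deletion p_q occupies [p-1, q) with empty state; an
    insertion between p and p+1 is the empty interval [p, p); a duplication
    p_q is an insertion of target[p-1..q) at [q, q).  Multi-edit variants are
    rejected — decompose first, one allele per edit.
    """
    if v.is_multi:
        raise DecomposeError("multi-edit variant: decompose into single edits first")
    e = v.edits[0]
    last = e.start if e.kind is EditKind.insertion else e.end
    if last > len(target):
        raise BoundsError(f"edit at {e.start}_{e.end} exceeds target length {len(target)}")
    is_protein = v.prefix == "p"

    def one(s: str | None) -> str:
        if not s:
            return ""
        return aa_to_one(s) if is_protein else s

    if e.kind is EditKind.substitution:
        loc = InterbaseLocation(target.digest, e.start - 1, e.start)
        return SimpleAllele(loc, one(e.alt))
    if e.kind is EditKind.synonymous:
        p = e.start - 1
        return SimpleAllele(InterbaseLocation(target.digest, p, p), "")
    if e.kind is EditKind.deletion:
        return SimpleAllele(InterbaseLocation(target.digest, e.start - 1, e.end), "")
    if e.kind is EditKind.insertion:
        return SimpleAllele(InterbaseLocation(target.digest, e.start, e.start), one(e.alt))
    if e.kind is EditKind.duplication:
        unit = target.residues[e.start - 1 : e.end]
        return SimpleAllele(InterbaseLocation(target.digest, e.end, e.end), unit)
    # delins
    return SimpleAllele(InterbaseLocation(target.digest, e.start - 1, e.end), one(e.alt))


# --- normalization -----------------------------------------------------------

def _trim(residues: str, start: int, end: int, state: str) -> tuple[int, int, str]:
    ref = residues[start:end]
    alt = state
    # common prefix
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    ref, alt, start = ref[p:], alt[p:], start + p
    # common suffix
    s = 0
    while s < len(ref) and s < len(alt) and ref[-1 - s] == alt[-1 - s]:
        s += 1
    if s:
        ref, alt, end = ref[:-s], alt[:-s], end - s
    else:
        end = start + len(ref)
    return start, end, alt


def normalize(allele: SimpleAllele, residues: str) -> SimpleAllele:
    """Fully-justified normalization of an allele against its sequence.

    Residues shared between the reference span and the state are trimmed
    from both ends.  If the trimmed allele is a pure insertion or pure
    deletion it may be ambiguous within a repeat context; the allele is then
    rolled left and right to its maximal ambiguity interval and re-expressed
    spanning the whole interval, flanking repeat residues included in both
    reference span and state.  Unambiguous alleles are returned trimmed
    only.  Idempotent by construction.
    """
    loc = allele.location
    if loc.end > len(residues):
        raise BoundsError(
            f"allele [{loc.start}, {loc.end}) exceeds sequence length {len(residues)}"
        )
    start, end, alt = _trim(residues, loc.start, loc.end, allele.state)
    ref = residues[start:end]
    if ref and alt:  # substitution/delins: unambiguous
        return SimpleAllele(InterbaseLocation(loc.sequence_id, start, end), alt)
    if not ref and not alt:  # identity allele: trim-only result
        return SimpleAllele(InterbaseLocation(loc.sequence_id, start, end), alt)

    if ref:  # pure deletion of k residues
        k = end - start
        ls, le = start, end
        while ls > 0 and residues[ls - 1] == residues[le - 1]:
            ls, le = ls - 1, le - 1
        rs, re_ = start, end
        while re_ < len(residues) and residues[re_] == residues[rs]:
            rs, re_ = rs + 1, re_ + 1
        left, right = ls, re_
        state = residues[left + k : right]
    else:  # pure insertion of unit alt
        unit = alt
        ls, lu = start, unit
        while ls > 0 and residues[ls - 1] == lu[-1]:
            lu = residues[ls - 1] + lu[:-1]
            ls -= 1
        rs, ru = start, unit
        while rs < len(residues) and residues[rs] == ru[0]:
            ru = ru[1:] + residues[rs]
            rs += 1
        left, right = ls, rs
        state = residues[left:right] + ru
    return SimpleAllele(InterbaseLocation(loc.sequence_id, left, right), state)


def allele_identifier(allele: SimpleAllele, residues: Optional[str] = None) -> str:
    """sha512t24u identifier of the canonical (normalized) allele.

    Serialization is the fixed ASCII join ``sequenceId|start|end|state``;
    identifier stability depends on this exact format.  When ``residues`` is
    supplied the allele is normalized first; otherwise it is assumed to be
    already normalized.
    """
    a = normalize(allele, residues) if residues is not None else allele
    loc = a.location
    return compute_sha512t24u(f"{loc.sequence_id}|{loc.start}|{loc.end}|{a.state}")


# --- reference mapping -------------------------------------------------------

def _hgvs_from_reference_allele(
    accession: str, start: int, end: int, state: str, window: str | None, window_offset: int
) -> str:
    """Emit a reference-side HGVS g. string from an interbase allele.

    The allele is reduced to a minimal right-shifted edit (maximal common
    prefix trimmed first, then suffix), which realizes the HGVS 3'-rule for
    indels in repeat regions.  ``window``/``window_offset`` give plus-strand
    reference residues for the covered region when available.
    """
    if window is not None:
        ref = window[start - window_offset : end - window_offset]
        p = 0
        while p < len(ref) and p < len(state) and ref[p] == state[p]:
            p += 1
        ref2, alt2, s2 = ref[p:], state[p:], start + p
        s_ = 0
        while s_ < len(ref2) and s_ < len(alt2) and ref2[-1 - s_] == alt2[-1 - s_]:
            s_ += 1
        if s_:
            ref2, alt2 = ref2[:-s_], alt2[:-s_]
        e2 = s2 + len(ref2)
    else:
        ref2, alt2, s2, e2 = None, state, start, end
    if ref2 is not None:
        if len(ref2) == 1 and len(alt2) == 1:
            return f"{accession}:g.{s2 + 1}{ref2}>{alt2}"
        if not alt2:
            if len(ref2) == 1:
                return f"{accession}:g.{s2 + 1}del"
            return f"{accession}:g.{s2 + 1}_{e2}del"
        if not ref2:
            return f"{accession}:g.{s2}_{s2 + 1}ins{alt2}"
        return f"{accession}:g.{s2 + 1}_{e2}delins{alt2}"
    # no window: cannot trim, emit a generic delins-style description
    if not alt2:
        if e2 - s2 == 1:
            return f"{accession}:g.{s2 + 1}del"
        return f"{accession}:g.{s2 + 1}_{e2}del"
    if s2 == e2:
        return f"{accession}:g.{s2}_{s2 + 1}ins{alt2}"
    return f"{accession}:g.{s2 + 1}_{e2}delins{alt2}"


def lift_to_reference(
    allele: SimpleAllele, link: ReferenceLink, target_length: int
) -> MappedVariant:
    """Project a target allele onto the linked reference sequence.

    Plus strand: reference interbase start = (anchor − 1) + target start,
    state unchanged.  Minus strand: reference start = (anchor − 1) +
    (target length − target end), and the state is reverse-complemented.
    The result carries the ``homologous_to`` relation and an emitted
    reference HGVS string against the versioned accession.
    """
    loc = allele.location
    if loc.sequence_id != link.target_digest:
        raise WrongSequenceError(
            f"allele is on sequence {loc.sequence_id!r}, link anchors {link.target_digest!r}"
        )
    if loc.end > target_length:
        raise OutOfWindowError(
            f"allele [{loc.start}, {loc.end}) exceeds the {target_length}-residue aligned window"
        )
    anchor0 = link.anchor_position - 1
    acc = str(link.accession)
    ctx = link.reference_context
    if ctx is not None and len(ctx) < target_length:
        raise OutOfWindowError("referenceContext shorter than the target")
    if link.strand is Strand.plus:
        ref_start = anchor0 + loc.start
        ref_end = anchor0 + loc.end
        state = allele.state
    else:
        if any(ch not in "ACGT" for ch in allele.state):
            raise MavekitError("minus-strand mapping is not supported for protein alleles")
        ref_start = anchor0 + (target_length - loc.end)
        ref_end = anchor0 + (target_length - loc.start)
        state = reverse_complement(allele.state)
    ref_allele = SimpleAllele(InterbaseLocation(acc, ref_start, ref_end), state)
    hgvs = _hgvs_from_reference_allele(acc, ref_start, ref_end, state, ctx, anchor0)
    return MappedVariant(
        target_allele=allele, reference_allele=ref_allele, reference_hgvs=hgvs
    )


def project_from_reference(
    mapped: SimpleAllele, link: ReferenceLink, target: TargetSequence
) -> SimpleAllele:
    """Inverse of :func:`lift_to_reference`: reference allele back to target."""
    anchor0 = link.anchor_position - 1
    loc = mapped.location
    n = len(target)
    if link.strand is Strand.plus:
        t_start = loc.start - anchor0
        t_end = loc.end - anchor0
        state = mapped.state
    else:
        t_start = n - (loc.end - anchor0)
        t_end = n - (loc.start - anchor0)
        state = reverse_complement(mapped.state)
    if t_start < 0 or t_end > n:
        raise OutOfWindowError("reference allele falls outside the aligned target")
    return SimpleAllele(InterbaseLocation(target.digest, t_start, t_end), state)
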