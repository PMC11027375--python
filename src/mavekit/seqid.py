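"""Target sequences, sha512t24u computed identifiers, and reference links.

A MAVE target is the exact sequence assayed, supplied in full so that a
globally unique computed identifier can be derived from it.  The identifier
scheme is sha512t24u as used by GA4GH refget/VRS: the base64url encoding (no
padding) of the first 24 bytes of the SHA-512 digest of the ASCII sequence
bytes.  Twenty-four bytes encode to exactly 32 characters over
``[A-Za-z0-9_-]``.

Targets must additionally be anchored to a versioned stable identifier on a
widely used reference resource (RefSeq, Ensembl, UniProt); the version is
mandatory because unversioned accessions are not stable.
"""

from __future__ import annotations

import base64
import hashlib
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import AlphabetError, BoundsError, MissingVersionError

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard residues, sorted

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def compute_sha512t24u(residues: str) -> str:
    """Return the sha512t24u digest of a sequence string.

    base64url (unpadded) encoding of the first 24 bytes of SHA-512 of the
    ASCII bytes.  Defined for any ASCII string, including the empty string.
    """
    try:
        raw = residues.encode("ascii")
    except UnicodeEncodeError as exc:
        raise AlphabetError(f"sequence is not ASCII: {exc}") from exc
    digest = hashlib.sha512(raw).digest()[:24]
    return base64.urlsafe_b64encode(digest).decode("ascii")


class MoleculeType(str, Enum):
    dna = "dna"
    protein = "protein"


@dataclass(frozen=True)
class TargetSequence:
    """The full sequence assayed in a MAVE, with its computed identifier.

    Residues are uppercased on construction; RNA input is stored as DNA
    (U -> T) so that digest identity does not depend on transcription state.
    """

    label: str
    residues: str
    molecule_type: MoleculeType = MoleculeType.dna
    digest: str = field(init=False)

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        mt = MoleculeType(self.molecule_type)
        if mt is MoleculeType.dna:
            residues = residues.replace("U", "T")
            alphabet = DNA_ALPHABET
        else:
            alphabet = PROTEIN_ALPHABET
        if not residues:
            raise AlphabetError("target sequence must be non-empty")
        bad = set(residues) - alphabet
        if bad:
            raise AlphabetError(
                f"invalid {mt.value} residues {sorted(bad)} in target {self.label!r}"
            )
        object.__setattr__(self, "residues", residues)
        object.__setattr__(self, "molecule_type", mt)
        object.__setattr__(self, "digest", compute_sha512t24u(residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def curie_digest(self) -> str:
        """Digest in the 'SQ.'-prefixed form used inside allele identifiers."""
        return f"SQ.{self.digest}"

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "residues": self.residues,
            "moleculeType": self.molecule_type.value,
            "digest": self.digest,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetSequence":
        return cls(
            label=d.get("label", ""),
            residues=d.get("residues", ""),
            molecule_type=d.get("moleculeType", "dna"),
        )


class Resource(str, Enum):
    refseq = "RefSeq"
    ensembl = "Ensembl"
    uniprot = "UniProt"
    other = "other"


_REFSEQ_RE = re.compile(r"^(?:AC|NC|NG|NM|NP|NR|NT|NW|XM|XP|XR|YP|WP)_\d+$")
_ENSEMBL_RE = re.compile(r"^ENS[A-Z]*[GTPE]\d{11}$")
# UniProtKB accession format (6- or 10-character forms).
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)
_VERSION_RE = re.compile(r"^(?P<base>.+)\.(?P<version>[1-9]\d*)$")


@dataclass(frozen=True)
class VersionedAccession:
    """A versioned stable identifier such as NM_000546.6 or ENST00000269305.9."""

    resource: Resource
    accession: str
    version: int

    def __str__(self) -> str:
        return f"{self.accession}.{self.version}"

    def to_dict(self) -> dict:
        return {
            "resource": self.resource.value,
            "accession": self.accession,
            "version": self.version,
        }


def parse_accession(text: str) -> VersionedAccession:
    """Parse a versioned accession, classifying the source resource by prefix.

    Raises :class:`MissingVersionError` when the trailing ``.N`` version is
    absent — this is the signal the metadata validator converts into the
    VERSIONED_ACCESSION_REQUIRED finding.
    """
    if not text:
        raise MissingVersionError("empty accession string")
    m = _VERSION_RE.match(text.strip())
    if m is None:
        raise MissingVersionError(
            f"accession {text!r} lacks an explicit '.N' version component; "
            "versioned stable identifiers are required"
        )
    base = m.group("base")
    version = int(m.group("version"))
    if _REFSEQ_RE.match(base):
        resource = Resource.refseq
    elif _ENSEMBL_RE.match(base):
        resource = Resource.ensembl
    elif _UNIPROT_RE.match(base):
        resource = Resource.uniprot
    else:
        resource = Resource.other
    return VersionedAccession(resource=resource, accession=base, version=version)


def reverse_complement(residues: str) -> str:
    """Reverse complement of a DNA string; an involution."""
    bad = set(residues) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"cannot reverse-complement non-DNA residues {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


class Strand(str, Enum):
    plus = "plus"
    minus = "minus"


@dataclass(frozen=True)
class ReferenceLink:
    """Ungapped anchor of a target sequence onto a versioned reference.

    ``anchor_position`` is the 1-based reference position that target
    position 1 maps to on the plus strand of the reference; for minus-strand
    links the target reads as the reverse complement of the reference window
    starting there.  ``reference_context``, when supplied, is the plus-strand
    reference window beginning at ``anchor_position`` and must cover the
    whole target.
    """

    target_digest: str
    accession: VersionedAccession
    anchor_position: int
    strand: Strand = Strand.plus
    reference_context: str | None = None

    def __post_init__(self) -> None:
        if self.anchor_position < 1:
            raise BoundsError("anchorPosition must be >= 1")
        object.__setattr__(self, "strand", Strand(self.strand))

    def to_dict(self) -> dict:
        d = {
            "targetDigest": self.target_digest,
            "accession": str(self.accession),
            "anchorPosition": self.anchor_position,
            "strand": self.strand.value,
        }
        if self.reference_context is not None:
            d["referenceContext"] = self.reference_context
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceLink":
        return cls(
            target_digest=d.get("targetDigest", ""),
            accession=parse_accession(d.get("accession", "")),
            anchor_position=int(d.get("anchorPosition", 1)),
            strand=d.get("strand", "plus"),
            reference_context=d.get("referenceContext"),
        )


def read_fasta(path: str | Path) -> list[TargetSequence]:
    """Read target sequences from FASTA.

    Record id becomes the label; a ``moleculeType=<dna|protein>`` token in the
    description selects the alphabet, defaulting to dna.
    """
    targets = []
    for rec in SeqIO.parse(str(path), "fasta"):
        mt = "dna"
        for token in rec.description.split():
            if token.startswith("moleculeType="):
                mt = token.split("=", 1)[1]
        targets.append(TargetSequence(label=rec.id, residues=str(rec.seq), molecule_type=mt))
    return targets


def write_fasta(targets: Iterable[TargetSequence], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(t.residues),
            id=t.label,
            description=f"moleculeType={t.molecule_type.value}",
        )
        for t in targets
    ]
    SeqIO.write(records, str(path), "fasta")
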