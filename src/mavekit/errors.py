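"""Exception hierarchy.

All toolkit errors derive from :class:`MavekitError` so callers can catch one
base class; parse-type errors carry enough context (offset, token) to point a
user at the offending input.
"""

from __future__ import annotations


class MavekitError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(MavekitError):
    """Sequence contains characters outside the declared alphabet."""


class MaveHgvsParseError(MavekitError):
    """Variant string does not conform to the supported MAVE-HGVS grammar.

    ``offset`` is the 0-based index of the offending token in the input, when
    it can be localized.
    """

    def __init__(self, message: str, text: str = "", offset: int | None = None):
        self.text = text
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset} in {text!r})"
        super().__init__(message)


class MissingVersionError(MavekitError):
    """Accession lacks the explicit '.N' version component."""


class BoundsError(MavekitError):
    """Position or interval falls outside the sequence."""


class ReferenceMismatchError(MavekitError):
    """Variant's stated reference residue disagrees with the target sequence."""

    def __init__(self, position: int, expected: str, observed: str):
        self.position = position
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"reference mismatch at position {position}: variant states "
            f"{expected!r} but target has {observed!r}"
        )


class DuplicateTermError(MavekitError):
    """Registry declares the same (category, label) pair twice."""


class UnknownCategoryError(MavekitError):
    """Requested vocabulary category is not declared in the registry."""


class RegistryFormatError(MavekitError):
    """Registry file is malformed."""


class TableFormatError(MavekitError):
    """Score/count table lacks required columns or structure."""


class DuplicateRecordError(MavekitError):
    """Score/count table contains the same variant twice."""


class WrongSequenceError(MavekitError):
    """Allele digest does not match the sequence the operation expects."""


class OutOfWindowError(MavekitError):
    """Allele span falls outside the aligned reference window."""


class DecomposeError(MavekitError):
    """Multi-edit variant must be decomposed into single-edit alleles first."""


class UnknownRuleError(MavekitError):
    """Rule id is not in the published rule table."""
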