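import re

import numpy as np
import pytest

from mavekit import (
    TargetSequence,
    allele_identifier,
    lift_to_reference,
    normalize,
    parse_variant,
    project_from_reference,
    reverse_complement,
    to_allele,
)
from mavekit.alleles import HOMOLOGOUS_TO, InterbaseLocation, SimpleAllele
from mavekit.errors import (
    BoundsError,
    DecomposeError,
    OutOfWindowError,
    WrongSequenceError,
)
from mavekit.seqid import ReferenceLink, parse_accession

from conftest import equivalence_class


def _allele(seq_id, start, end, state):
    return SimpleAllele(InterbaseLocation(seq_id, start, end), state)


class TestToAllele:
    @pytest.mark.parametrize(
        "text,start,end,state",
        [
            ("c.2T>C", 1, 2, "C"),
            ("c.3_4del", 2, 4, ""),
            ("c.3_4insTT", 3, 3, "TT"),
            ("c.2_3dup", 3, 3, "TG"),
            ("c.2_3delinsAA", 1, 3, "AA"),
        ],
    )
    def test_interbase_conversion(self, dna_target, text, start, end, state):
        a = to_allele(parse_variant(text), dna_target)
        assert (a.location.start, a.location.end, a.state) == (start, end, state)
        assert a.location.sequence_id == dna_target.digest

    def test_application_matches_variant_application(self, dna_target):
        from mavekit import apply_variant

        for text in ["c.2T>C", "c.3_4del", "c.3_4insTT", "c.2_3dup", "c.2_3delinsAA"]:
            v = parse_variant(text)
            assert to_allele(v, dna_target).apply(dna_target.residues) == apply_variant(
                dna_target, v
            )

    def test_multi_edit_must_be_decomposed(self, dna_target):
        with pytest.raises(DecomposeError):
            to_allele(parse_variant("c.[1A>G;5del]"), dna_target)

    def test_protein_state_is_one_letter(self, protein_target):
        a = to_allele(parse_variant("p.Lys2Arg"), protein_target)
        assert a.state == "R"


class TestNormalize:
    def test_repeat_deletion_expands_to_full_interval(self):
        a = normalize(_allele("D", 1, 2, ""), "CAAAT")
        assert (a.location.start, a.location.end, a.state) == (1, 4, "AA")

    def test_repeat_insertion_expands_to_full_interval(self):
        a = normalize(_allele("D", 2, 2, "A"), "CAAAT")
        assert (a.location.start, a.location.end, a.state) == (1, 4, "AAAA")

    def test_substitution_unchanged(self):
        a = _allele("D", 1, 2, "C")
        assert normalize(a, "ATGAAA") == a

    def test_identity_allele_trims_only(self):
        a = normalize(_allele("D", 1, 4, "TGA"), "ATGAAA")
        assert a.state == "" and a.location.start == a.location.end

    def test_out_of_bounds(self):
        with pytest.raises(BoundsError):
            normalize(_allele("D", 0, 10, ""), "ACGT")

    def test_idempotent_on_fuzz(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 30))
            residues = "".join(rng.choice(list("ACGT"), p=[0.4, 0.4, 0.1, 0.1], size=n))
            s = int(rng.integers(0, n))
            e = int(rng.integers(s, min(n, s + 4) + 1))
            state = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 4))))
            a = normalize(_allele("D", s, e, state), residues)
            assert normalize(a, residues) == a


def test_normalization_canonicality_brute_force(rng):
    checked = 0
    while checked < 200:
        n = int(rng.integers(6, 30))
        residues = "".join(rng.choice(list("ACGT"), p=[0.35, 0.35, 0.15, 0.15], size=n))
        s = int(rng.integers(0, n))
        if rng.random() < 0.5:  # deletion
            e = int(rng.integers(s + 1, min(n, s + 3) + 1))
            state = ""
        else:  # insertion
            e = s
            state = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
        canonical = normalize(_allele("D", s, e, state), residues)
        members = equivalence_class(residues, s, e, state)
        assert (s, e, state) in members
        for ms, me, mstate in members:
            got = normalize(_allele("D", ms, me, mstate), residues)
            assert got == canonical, (residues, (s, e, state), (ms, me, mstate))
        checked += 1


class TestIdentifier:
    def test_equivalent_representations_share_identifier(self):
        residues = "CAAAT"
        a = _allele("D", 1, 2, "")
        b = _allele("D", 3, 4, "")
        assert a != b
        assert allele_identifier(a, residues) == allele_identifier(b, residues)

    def test_32_char_base64url(self):
        ident = allele_identifier(_allele("D", 1, 2, "C"), "ATGAAA")
        assert re.fullmatch(r"[A-Za-z0-9_-]{32}", ident)

    def test_different_sequences_differ(self):
        a = allele_identifier(_allele("D1", 1, 2, "C"))
        b = allele_identifier(_allele("D2", 1, 2, "C"))
        assert a != b


class TestLift:
    def _link(self, target, strand="plus", anchor=101, context=True):
        if context:
            ctx = (
                target.residues
                if strand == "plus"
                else reverse_complement(target.residues)
            )
        else:
            ctx = None
        return ReferenceLink(
            target_digest=target.digest,
            accession=parse_accession("NM_000546.6"),
            anchor_position=anchor,
            strand=strand,
            reference_context=ctx,
        )

    def test_plus_strand_offset_and_hgvs(self, dna_target):
        a = to_allele(parse_variant("c.2T>C"), dna_target)
        m = lift_to_reference(a, self._link(dna_target), len(dna_target))
        assert (m.reference_allele.location.start, m.reference_allele.location.end) == (101, 102)
        assert m.reference_allele.state == "C"
        assert m.reference_hgvs == "NM_000546.6:g.102T>C"
        assert m.relation == HOMOLOGOUS_TO

    def test_minus_strand_state_reverse_complemented(self, dna_target):
        a = to_allele(parse_variant("c.2T>C"), dna_target)
        m = lift_to_reference(a, self._link(dna_target, "minus"), len(dna_target))
        assert m.reference_allele.state == "G"

    def test_substitution_hgvs_pattern(self, rng):
        pattern = re.compile(r"^.+:g\.\d+[ACGT]>[ACGT]$")
        target = TargetSequence("t", "".join(rng.choice(list("ACGT"), size=40)))
        for strand in ("plus", "minus"):
            link = self._link(target, strand)
            for v in np.random.default_rng(1).permutation(
                [f"c.{i}{target.residues[i-1]}>{a}" for i in range(1, 41) for a in "ACGT" if a != target.residues[i-1]]
            )[:30]:
                allele = to_allele(parse_variant(str(v)), target)
                m = lift_to_reference(allele, link, len(target))
                assert pattern.match(m.reference_hgvs), m.reference_hgvs

    def test_wrong_digest_rejected(self, dna_target):
        a = _allele("not-the-digest", 1, 2, "C")
        with pytest.raises(WrongSequenceError):
            lift_to_reference(a, self._link(dna_target), len(dna_target))

    def test_span_outside_window_rejected(self, dna_target):
        a = _allele(dna_target.digest, 1, 20, "")
        with pytest.raises(OutOfWindowError):
            lift_to_reference(a, self._link(dna_target, context=False), len(dna_target))

    def test_edit_then_align_equals_align_then_edit_both_strands(self, rng):
        """Oracle: applying the target allele then aligning the result must
        equal applying the mapped allele to the reference window."""
        checked = 0
        while checked < 250:
            n = int(rng.integers(6, 40))
            target = TargetSequence("t", "".join(rng.choice(list("ACGT"), size=n)))
            s = int(rng.integers(0, n))
            e = int(rng.integers(s, min(n, s + 5) + 1))
            state = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 4))))
            if s == e and not state:
                continue
            allele = _allele(target.digest, s, e, state)
            strand = "plus" if rng.random() < 0.5 else "minus"
            anchor = int(rng.integers(1, 500))
            link = self._link(target, strand, anchor=anchor)
            mapped = lift_to_reference(allele, link, n)
            edited_target = allele.apply(target.residues)
            ref_window = link.reference_context
            loc = mapped.reference_allele.location
            window_allele = _allele(
                "w", loc.start - (anchor - 1), loc.end - (anchor - 1),
                mapped.reference_allele.state,
            )
            edited_window = window_allele.apply(ref_window)
            if strand == "plus":
                assert edited_window == edited_target
            else:
                assert reverse_complement(edited_window) == edited_target
            # round-trip: inverse projection recovers the original allele
            assert project_from_reference(mapped.reference_allele, link, target) == allele
            checked += 1
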