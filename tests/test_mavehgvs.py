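import numpy as np
import pytest

from mavekit import (
    TargetSequence,
    apply_variant,
    decompose,
    enumerate_saturation,
    format_variant,
    parse_variant,
)
from mavekit.errors import BoundsError, MaveHgvsParseError, ReferenceMismatchError
from mavekit.mavehgvs import EditKind, MaveHgvsVariant, SequenceEdit
from mavekit.fixtures import random_variant


class TestParse:
    @pytest.mark.parametrize(
        "text,kind,start,end,ref,alt",
        [
            ("c.1A>G", EditKind.substitution, 1, 1, "A", "G"),
            ("c.3_5del", EditKind.deletion, 3, 5, None, None),
            ("c.3del", EditKind.deletion, 3, 3, None, None),
            ("c.3_5dup", EditKind.duplication, 3, 5, None, None),
            ("c.3_4insTT", EditKind.insertion, 3, 4, None, "TT"),
            ("c.3_5delinsAT", EditKind.delins, 3, 5, None, "AT"),
            ("p.Glu27Trp", EditKind.substitution, 27, 27, "Glu", "Trp"),
            ("p.Lys2_Gly3del", EditKind.deletion, 2, 3, "LysGly", None),
            ("p.Gly3dup", EditKind.duplication, 3, 3, "Gly", None),
            ("p.Lys2_Gly3insTrpSer", EditKind.insertion, 2, 3, "LysGly", "TrpSer"),
            ("p.Arg5=", EditKind.synonymous, 5, 5, "Arg", None),
            ("n.4G>T", EditKind.substitution, 4, 4, "G", "T"),
            ("g.12_13insA", EditKind.insertion, 12, 13, None, "A"),
        ],
    )
    def test_single_edit_grammar(self, text, kind, start, end, ref, alt):
        v = parse_variant(text)
        (e,) = v.edits
        assert (e.kind, e.start, e.end, e.ref, e.alt) == (kind, start, end, ref, alt)

    def test_multi_edit(self):
        v = parse_variant("c.[1A>G;5del]")
        assert [e.kind for e in v.edits] == [EditKind.substitution, EditKind.deletion]
        assert [e.start for e in v.edits] == [1, 5]

    def test_one_letter_protein_normalized(self):
        assert format_variant(parse_variant("p.E27W")) == "p.Glu27Trp"
        assert parse_variant("p.E27W") == parse_variant("p.Glu27Trp")

    @pytest.mark.parametrize(
        "text",
        [
            "c.78+1G>A",       # intronic offset
            "c.-12A>G",        # UTR offset
            "c.*5A>G",         # 3' UTR offset
            "c.(78)A>G",       # uncertain position
            "m.1A>G",          # unsupported prefix
            "c.1A>U",          # RNA alphabet
            "c.0A>G",          # positions are 1-based
            "c.5_3del",        # inverted range
            "c.3_5insTT",      # non-adjacent insertion
            "c.[1A>G;1T>C]",   # equal-position multi-edit
            "c.[5del;1A>G]",   # out-of-order multi-edit
            "p.Xyz12Trp",      # unknown residue code
            "c.1A>",           # truncated
            "",
        ],
    )
    def test_rejections(self, text):
        with pytest.raises(MaveHgvsParseError):
            parse_variant(text)

    def test_error_reports_offset(self):
        with pytest.raises(MaveHgvsParseError) as exc:
            parse_variant("c.78+1G>A")
        assert "offset" in str(exc.value)


class TestFormatRoundTrip:
    def test_canonical_substitution(self):
        v = MaveHgvsVariant("c", (SequenceEdit(EditKind.substitution, 2, 2, "T", "C"),))
        assert format_variant(v) == "c.2T>C"

    def test_fuzz_round_trip_identity(self):
        rng = np.random.default_rng(7)
        for i in range(500):
            mt = "protein" if i % 2 else "dna"
            v = random_variant(rng, mt)
            text = format_variant(v)
            assert parse_variant(text) == v, text

    def test_out_of_order_edits_refused(self):
        with pytest.raises(MaveHgvsParseError):
            MaveHgvsVariant(
                "c",
                (
                    SequenceEdit(EditKind.deletion, 5, 6),
                    SequenceEdit(EditKind.substitution, 1, 1, "A", "G"),
                ),
            )


class TestApply:
    @pytest.mark.parametrize(
        "text,expect",
        [
            ("c.2T>C", "ACGAAA"),
            ("c.3_4del", "ATAA"),
            ("c.3_4insTT", "ATGTTAAA"),
            ("c.3_4dup", "ATGAGAAA"),
            ("c.2_3delinsCCC", "ACCCAAA"),
            ("c.[1A>G;5del]", "GTGAA"),
        ],
    )
    def test_known_edits(self, dna_target, text, expect):
        assert apply_variant(dna_target, parse_variant(text)) == expect

    def test_protein_edit(self, protein_target):
        assert apply_variant(protein_target, parse_variant("p.Lys2Arg")) == "MRLVEQ"
        assert apply_variant(protein_target, parse_variant("p.Lys2_Leu3del")) == "MVEQ"

    def test_reference_mismatch(self, dna_target):
        with pytest.raises(ReferenceMismatchError) as exc:
            apply_variant(dna_target, parse_variant("c.2A>G"))
        msg = str(exc.value)
        assert "'A'" in msg and "'T'" in msg

    def test_out_of_bounds(self, dna_target):
        with pytest.raises(BoundsError):
            apply_variant(dna_target, parse_variant("c.7A>G"))

    def test_prefix_molecule_compatibility(self, dna_target, protein_target):
        with pytest.raises(MaveHgvsParseError):
            apply_variant(dna_target, parse_variant("p.Met1Leu"))
        with pytest.raises(MaveHgvsParseError):
            apply_variant(protein_target, parse_variant("c.1A>G"))

    def test_length_delta_law_on_fuzz(self, rng):
        target = TargetSequence("t", "".join(rng.choice(list("ACGT"), size=80)))
        for _ in range(300):
            v = random_variant(rng, "dna", max_position=70)
            try:
                edited = apply_variant(target, v)
            except (ReferenceMismatchError, BoundsError):
                continue
            delta = sum(e.length_delta() for e in v.edits)
            assert len(edited) - len(target) == delta, format_variant(v)

    def test_multi_edit_equals_sequential_descending(self, rng):
        target = TargetSequence("t", "".join(rng.choice(list("ACGT"), size=60)))
        applied = 0
        for _ in range(4000):
            if applied >= 25:
                break
            v = random_variant(rng, "dna", max_position=50, allow_multi=True)
            if not v.is_multi:
                continue
            try:
                whole = apply_variant(target, v)
            except (ReferenceMismatchError, BoundsError):
                continue
            seq = target.residues
            for single in sorted(
                decompose(v), key=lambda s: s.edits[0].start, reverse=True
            ):
                seq = apply_variant(
                    TargetSequence("step", seq), single
                )
            assert seq == whole
            applied += 1
        assert applied >= 25


class TestSaturation:
    def test_dna_count_is_3l(self):
        t = TargetSequence("t", "ATGAAA")
        variants = enumerate_saturation(t)
        assert len(variants) == 18
        assert len({format_variant(v) for v in variants}) == 18

    def test_protein_count_is_19n(self):
        t = TargetSequence("p", "MKLVEQWERT", molecule_type="protein")
        assert len(enumerate_saturation(t)) == 190

    def test_order_position_major_alphabetical(self):
        t = TargetSequence("t", "AT")
        texts = [format_variant(v) for v in enumerate_saturation(t)]
        assert texts == ["c.1A>C", "c.1A>G", "c.1A>T", "c.2T>A", "c.2T>C", "c.2T>G"]

    def test_every_variant_applies_cleanly(self, rng):
        t = TargetSequence("t", "".join(rng.choice(list("ACGT"), size=25)))
        for v in enumerate_saturation(t):
            edited = apply_variant(t, v)
            assert len(edited) == len(t)
            assert edited != t.residues
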