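"""Structure parsing, dangle microstates, and structure evaluation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldspace.oracle import enumerate_structures, random_sequences
from foldspace.sequence import RnaSequence, SequenceError
from foldspace.structures import (
    MicroStructure,
    SecondaryStructure,
    StructureError,
    count_dangle_variants,
    dangle_sites,
    enumerate_dangle_variants,
    evaluate_structure_energy,
    parse_ct,
    parse_dotbracket,
    parse_extended,
    rescore_structures,
    write_ct,
)
from tests.conftest import DANGLE_EXAMPLE, DANGLE_EXAMPLE_TOTAL, EXAMPLE_STRUCTURE


class TestSequences:
    def test_t_mapped_to_u(self):
        assert RnaSequence("ACGT").seq == "ACGU"

    def test_invalid_letter_reports_position(self):
        with pytest.raises(SequenceError, match="position 3"):
            RnaSequence("ACXG")


class TestParsing:
    def test_two_nested_pairs(self):
        s = parse_dotbracket("((...))")
        assert s.pairs == frozenset({(1, 7), (2, 6)})

    def test_worked_example_has_13_pairs(self):
        assert len(parse_dotbracket(EXAMPLE_STRUCTURE).pairs) == 13

    @pytest.mark.parametrize("bad", ["((.", "())", "(a)"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(StructureError):
            parse_dotbracket(bad)

    def test_roundtrip_is_identity(self):
        for seq in random_sequences(15, 5, seed=3):
            for s in enumerate_structures(seq):
                assert parse_dotbracket(s.dotbracket) == s

    def test_crossing_pairs_rejected(self):
        with pytest.raises(StructureError):
            SecondaryStructure.from_pairs(10, [(1, 6), (3, 9)])

    def test_ct_roundtrip(self):
        s = parse_dotbracket("((..((...)).))")
        seq = "GGAAGGAAACCACC"
        seq2, s2 = parse_ct(write_ct(seq, s, "toy"))
        assert seq2 == seq and s2 == s


class TestDangleVariants:
    def test_printed_example_has_36_variants(self):
        s = parse_dotbracket(DANGLE_EXAMPLE)
        variants = enumerate_dangle_variants(s)
        assert len(variants) == DANGLE_EXAMPLE_TOTAL
        assert len({v.extended for v in variants}) == DANGLE_EXAMPLE_TOTAL

    def test_printed_variant_strings_are_legal(self):
        for ext in [
            "((d.((...))b((...))b))",
            "((.b((...))b((...))b))",
            "((db((...))b((...))b))",
            "((..((...))d((...))b))",
            "((..((...))b((...)).))",
        ]:
            m = parse_extended(ext)
            assert m.extended == ext
            assert m.base == parse_dotbracket(DANGLE_EXAMPLE)

    def test_hairpin_only_structure_has_one_variant(self):
        assert len(enumerate_dangle_variants(parse_dotbracket("((...))"))) == 1

    def test_open_chain_has_one_variant(self):
        assert len(enumerate_dangle_variants(parse_dotbracket("...."))) == 1

    def test_count_factorizes_over_sites(self):
        for seq in random_sequences(18, 10, seed=4):
            for s in enumerate_structures(seq):
                assert count_dangle_variants(s) == len(enumerate_dangle_variants(s))

    def test_illegal_assignment_rejected(self):
        s = parse_dotbracket("((...))")
        with pytest.raises(StructureError):
            MicroStructure(base=s, dangles=((3, "d"),))  # hairpin loop base


class TestEvaluation:
    def test_open_chain_is_zero_for_all_models(self, params):
        s = parse_dotbracket("." * 9)
        for model in ("NoDangle", "OverDangle", "MicroState", "MacroState"):
            assert evaluate_structure_energy("AAAAAAAAA", s, model, params) == 0.0

    def test_noncanonical_pair_rejected(self, params):
        s = parse_dotbracket("((...))")
        with pytest.raises(StructureError):
            evaluate_structure_energy("AAAAAAA", s, "NoDangle", params)

    def test_microstate_optimum_is_min_over_variants(self, params):
        for seq in random_sequences(20, 8, seed=5):
            for s in enumerate_structures(seq):
                best = min(
                    evaluate_structure_energy(seq, m, "MicroState", params)
                    for m in enumerate_dangle_variants(s)
                )
                opt = evaluate_structure_energy(seq, s, "MicroState", params)
                assert opt == pytest.approx(best, abs=1e-9)

    def test_all_dots_variant_equals_nodangle(self, params):
        for seq in random_sequences(18, 8, seed=6):
            for s in enumerate_structures(seq):
                plain = MicroStructure(base=s, dangles=())
                assert evaluate_structure_energy(
                    seq, plain, "MicroState", params
                ) == evaluate_structure_energy(seq, s, "NoDangle", params)

    def test_overdangle_never_above_nodangle(self, params):
        # all Turner'99 dangle energies are <= 0
        for seq in random_sequences(22, 10, seed=7):
            for s in enumerate_structures(seq):
                eo = evaluate_structure_energy(seq, s, "OverDangle", params)
                en_ = evaluate_structure_energy(seq, s, "NoDangle", params)
                assert eo <= en_ + 1e-9


class TestRescoring:
    def test_identity_rescore_keeps_order(self, params):
        seq = random_sequences(20, 1, seed=8)[0]
        structs = enumerate_structures(seq)
        out = rescore_structures(seq, structs, "NoDangle", "NoDangle", params)
        energies = [e for _, e in out]
        assert energies == sorted(energies)

    def test_empty_list(self, params):
        assert rescore_structures("ACGU", [], "NoDangle", "MicroState", params) == []

    def test_order_can_invert_between_models(self, params):
        # search a seeded corpus for a pair of structures whose OverDangle
        # order inverts under MicroState energies, then check rescoring
        found = False
        for seq in random_sequences(30, 40, seed=9):
            structs = enumerate_structures(seq)
            scored = [
                (
                    evaluate_structure_energy(seq, s, "OverDangle", params),
                    evaluate_structure_energy(seq, s, "MicroState", params),
                    s,
                )
                for s in structs
            ]
            for a in range(len(scored)):
                for b in range(len(scored)):
                    if scored[a][0] < scored[b][0] and scored[a][1] > scored[b][1]:
                        sa, sb = scored[a][2], scored[b][2]
                        out = rescore_structures(
                            seq, [sa, sb], "OverDangle", "MicroState", params
                        )
                        assert out[0][0] == sb and out[1][0] == sa
                        found = True
                        break
                if found:
                    break
            if found:
                break
        assert found, "no inversion found in the seeded corpus"
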