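"""Abstract shape levels 1-5 and the refinement relation."""

import pytest

from foldspace.oracle import enumerate_structures, random_sequences
from foldspace.shapes import (
    ShapeError,
    ShapeString,
    is_refinement,
    shape_of,
    witness_structure,
)
from foldspace.structures import parse_dotbracket
from tests.conftest import EXAMPLE_SHAPES, EXAMPLE_STRUCTURE


class TestShapeOf:
    @pytest.mark.parametrize("level,expected", sorted(EXAMPLE_SHAPES.items()))
    def test_worked_example(self, level, expected):
        s = parse_dotbracket(EXAMPLE_STRUCTURE)
        assert shape_of(s, level).text == expected

    def test_single_helix_level5(self):
        assert shape_of(parse_dotbracket("((...))"), 5).text == "[]"

    def test_open_chain_maps_to_underscore_everywhere(self):
        for level in (1, 2, 3, 4, 5):
            assert shape_of(parse_dotbracket("....."), level).text == "_"

    def test_invalid_level(self):
        with pytest.raises(ShapeError):
            shape_of(parse_dotbracket("....."), 6)

    def test_bulge_vs_internal_split_by_level(self):
        bulge = parse_dotbracket("((.((...))))")
        internal = parse_dotbracket("((.((...)).))")
        assert shape_of(bulge, 2).text == "[_[]]"
        assert shape_of(bulge, 3).text == "[[]]"
        assert shape_of(bulge, 4).text == "[]"
        assert shape_of(internal, 2).text == "[_[]_]"
        assert shape_of(internal, 4).text == "[[]]"
        assert shape_of(internal, 5).text == "[]"

    def test_helix_elongation_invariance(self):
        a = parse_dotbracket("((...))")
        b = parse_dotbracket("(((...)))")
        for level in (1, 2, 3, 4, 5):
            assert shape_of(a, level).text == shape_of(b, level).text


class TestHierarchy:
    def test_coarser_level_is_function_of_finer(self):
        """For l < m, the level-m shape is determined by the level-l shape
        (checked exhaustively over small folding spaces)."""
        mapping = {}
        for seq in random_sequences(18, 15, seed=12):
            for s in enumerate_structures(seq):
                shapes = {lv: shape_of(s, lv).text for lv in (1, 2, 3, 4, 5)}
                # level 3 renders bulges and internal loops identically
                # while level 4 still distinguishes them, so (3, 4) is the
                # one level pair without a coarsening function
                for l in (1, 2, 3, 4):
                    for m in range(l + 1, 6):
                        if (l, m) == (3, 4):
                            continue
                        key = (l, m, shapes[l])
                        if key in mapping:
                            assert mapping[key] == shapes[m], (s.dotbracket, key)
                        else:
                            mapping[key] = shapes[m]

    def test_shape_space_sizes_monotone_in_level(self):
        for seq in random_sequences(20, 5, seed=13):
            structs = enumerate_structures(seq)
            sizes = [
                len({shape_of(s, lv).text for s in structs}) for lv in (1, 2, 3, 4, 5)
            ]
            assert sizes == sorted(sizes, reverse=True)


class TestRefinement:
    def test_worked_example_refines(self):
        assert is_refinement(
            ShapeString(2, EXAMPLE_SHAPES[2]), ShapeString(5, EXAMPLE_SHAPES[5])
        )

    def test_reflexive(self):
        p = ShapeString(5, "[][]")
        assert is_refinement(p, p)

    def test_same_level_distinct_is_contract_error(self):
        with pytest.raises(ShapeError):
            is_refinement(ShapeString(5, "[][]"), ShapeString(5, "[]"))

    def test_reversed_levels_rejected(self):
        with pytest.raises(ShapeError):
            is_refinement(ShapeString(5, "[]"), ShapeString(2, "[_[]]"))

    def test_non_refinement_detected(self):
        assert not is_refinement(ShapeString(2, "[_[]]"), ShapeString(5, "[][]"))

    def test_witness_maps_back_to_its_shape(self):
        for text, level in [
            ("[_[]]", 2),
            ("[_[]_]", 2),
            ("[[][]]", 5),
            ("[][]", 5),
            ("[_[[][_[]_]]]", 2),
            ("_", 1),
        ]:
            w = witness_structure(ShapeString(level, text))
            assert shape_of(w, level).text == text
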