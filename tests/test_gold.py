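"""Gold-structure derivation from annotated base-pair lists."""

import pytest

from foldspace.gold import (
    AnnotatedPairList,
    GoldError,
    Rejection,
    apply_pseudoknot_policy,
    build_gold_structure,
    filter_canonical_cwc,
    parse_mc_annotate,
    parse_pair_tsv,
    remove_lonely_pairs,
    write_fasta_like,
)
from foldspace.structures import SecondaryStructure

SEQ20 = "GGGGGAAAAACCCCCAAAAA"


def seq_for(pairs, n=20):
    """A sequence on which every given pair is G:C."""
    s = ["A"] * n
    for (i, j) in pairs:
        s[i - 1] = "G"
        s[j - 1] = "C"
    return "".join(s)


def apl(interactions, seq=None):
    if seq is None:
        seq = seq_for([(i, j) for (i, j, t) in interactions])
    return AnnotatedPairList(sequence=seq, interactions=tuple(interactions))


class TestCwcFilter:
    def test_canonical_cwc_kept_others_dropped(self):
        a = apl(
            [
                (1, 15, "cWC"),  # G:C kept
                (2, 8, "cWC"),  # G:A non-canonical, dropped
                (3, 13, "stacking"),  # wrong class, dropped
                (4, 12, "cWC"),  # G:C kept
            ],
            seq=SEQ20,
        )
        assert filter_canonical_cwc(a) == {(1, 15), (4, 12)}

    def test_empty_list(self):
        assert filter_canonical_cwc(apl([], seq=SEQ20)) == set()

    def test_out_of_range_rejected(self):
        with pytest.raises(GoldError):
            apl([(1, 99, "cWC")], seq=SEQ20)

    def test_multi_paired_position_dropped(self):
        a = apl([(1, 15, "cWC"), (1, 14, "cWC"), (4, 12, "cWC")], seq=SEQ20)
        assert filter_canonical_cwc(a) == {(4, 12)}


class TestLonelyPairs:
    def test_single_pair_removed(self):
        assert remove_lonely_pairs({(1, 10)}) == set()

    def test_stacked_pairs_kept(self):
        assert remove_lonely_pairs({(1, 10), (2, 9)}) == {(1, 10), (2, 9)}

    def test_fixpoint(self):
        assert remove_lonely_pairs({(1, 10), (2, 9), (5, 20)}) == {(1, 10), (2, 9)}


class TestPseudoknotPolicy:
    def test_nested_unchanged(self):
        pairs = {(1, 10), (2, 9), (4, 8)}
        assert apply_pseudoknot_policy(pairs) == (pairs, None)

    def test_single_crossing_pair_removed(self):
        pairs = {(1, 10), (2, 9), (5, 15)}
        out, removed = apply_pseudoknot_policy(pairs)
        assert removed == (5, 15) and out == {(1, 10), (2, 9)}

    def test_two_pair_knot_rejected(self):
        pairs = {(1, 10), (2, 9), (5, 15), (6, 14)}
        res = apply_pseudoknot_policy(pairs)
        assert isinstance(res, Rejection)


class TestPipeline:
    def test_nested_canonical_input_is_identity(self):
        a = apl([(1, 15, "cWC"), (2, 14, "cWC"), (3, 13, "cWC")])
        s = build_gold_structure(a)
        assert isinstance(s, SecondaryStructure)
        assert s.pairs == {(1, 15), (2, 14), (3, 13)}

    def test_filtering_can_create_lonely_pair(self):
        # (5,12) is stacked only on (4,13); (4,13) is non-canonical here
        # and falls to the cWC filter, after which (5,12) must go as well
        seq = list(seq_for([(1, 15), (2, 14), (5, 12)]))
        seq[3] = "G"
        seq[12] = "G"  # (4,13) = G:G
        a = AnnotatedPairList(
            sequence="".join(seq),
            interactions=(
                (1, 15, "cWC"),
                (2, 14, "cWC"),
                (4, 13, "cWC"),
                (5, 12, "cWC"),
            ),
        )
        s = build_gold_structure(a)
        assert s.pairs == {(1, 15), (2, 14)}

    def test_knot_removal_rechecks_lonely_pairs(self):
        # the crosser (6,18) is removed by the pseudoknot policy; (8,12)
        # then has no stacked neighbor left and must also be removed
        inter = [
            (1, 15, "cWC"),
            (2, 14, "cWC"),
            (8, 12, "cWC"),
            (6, 18, "cWC"),  # crosses (1,15) and (2,14)
        ]
        a = apl(inter)
        s = build_gold_structure(a)
        assert isinstance(s, SecondaryStructure)
        assert s.pairs == {(1, 15), (2, 14)}

    def test_empty_input_gives_open_chain(self):
        s = build_gold_structure(apl([], seq=SEQ20))
        assert isinstance(s, SecondaryStructure) and not s.pairs

    def test_two_pair_knot_rejection_propagates(self):
        a = apl(
            [
                (1, 10, "cWC"),
                (2, 9, "cWC"),
                (5, 15, "cWC"),
                (6, 14, "cWC"),
            ]
        )
        res = build_gold_structure(a)
        assert isinstance(res, Rejection) and "pseudoknot" in res.reason

    def test_idempotent_and_monotone(self):
        corpus = [
            [(1, 15, "cWC"), (2, 14, "cWC"), (4, 12, "cWC"), (5, 11, "cWC")],
            [(1, 15, "cWC"), (2, 14, "cWC"), (3, 19, "cWC")],
            [(2, 14, "cWC"), (3, 13, "cWC"), (6, 18, "cWC"), (7, 17, "cWC")],
        ]
        for rows in corpus:
            a = apl(rows)
            out = build_gold_structure(a)
            if isinstance(out, Rejection):
                continue
            cwc = filter_canonical_cwc(a)
            assert out.pairs <= cwc  # monotone
            again = build_gold_structure(
                AnnotatedPairList(
                    sequence=a.sequence,
                    interactions=tuple((i, j, "cWC") for (i, j) in out.pairs),
                )
            )
            assert again.pairs == out.pairs  # idempotent
            # output is always nested, lonely-free, canonical
            for (i, j) in out.pairs:
                assert (i + 1, j - 1) in out.pairs or (i - 1, j + 1) in out.pairs


class TestFormats:
    def test_tsv_parser(self):
        a = parse_pair_tsv(SEQ20, "i\tj\tclass\n1\t15\tcWC\n3\t13\tstacking\n")
        assert a.interactions == ((1, 15, "cWC"), (3, 13, "stacking"))

    def test_mc_annotate_parser(self):
        text = (
            "A1-A15 : G-C Ww/Ww pairing antiparallel cis XIX\n"
            "A3-A13 : G-C Hh/Ww pairing trans\n"
            "garbage line\n"
        )
        a = parse_mc_annotate(SEQ20, text)
        tags = {(i, j): t for i, j, t in a.interactions}
        assert tags[(1, 15)] == "cWC"
        assert tags[(3, 13)] != "cWC"

    def test_fasta_like_writer(self):
        s = SecondaryStructure.from_pairs(5, [(1, 5)])
        out = write_fasta_like("x", "GAAAC", s)
        assert out == ">x\nGAAAC\n(...)\n"
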