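"""Comparison statistics: SPS, KL, asymmetric base-pair distance, ranks."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foldspace as fs
from foldspace.compare import (
    ComparisonError,
    RankSummary,
    closest_cooptimal,
    lower_quantile,
    run_comparison,
)
from foldspace.structures import parse_dotbracket
from tests.conftest import SHIFT_EXAMPLE_PROBS


class _Dist:
    """Minimal stand-in distribution for statistic-level tests."""

    def __init__(self, probs, level=5, sequence=""):
        self._p = dict(probs)
        self.level = level
        self.sequence = sequence

    def as_dict(self):
        return dict(self._p)


class TestSps:
    def test_identical_distributions(self):
        d = _Dist({"[]": 0.7, "_": 0.3})
        assert fs.sps(d, d) == 0.0

    def test_disjoint_supports(self):
        assert fs.sps(_Dist({"[]": 1.0}), _Dist({"_": 1.0})) == pytest.approx(1.0)

    def test_printed_distributions_give_03411(self):
        a = _Dist({k: v / 100 for k, v in SHIFT_EXAMPLE_PROBS["MacroState"].items()})
        b = _Dist({k: v / 100 for k, v in SHIFT_EXAMPLE_PROBS["MicroState"].items()})
        assert fs.sps(a, b) == pytest.approx(0.3411, abs=1e-6)

    def test_level_mismatch_rejected(self):
        with pytest.raises(ComparisonError):
            fs.sps(_Dist({"[]": 1.0}, level=5), _Dist({"[]": 1.0}, level=2))

    @staticmethod
    def _random_dists(draw_probs):
        shapes = ["[]", "[][]", "[[][]]", "_"]
        dists = []
        for ps in draw_probs:
            total = sum(ps)
            dists.append(_Dist({s: p / total for s, p in zip(shapes, ps)}))
        return dists

    @given(
        st.lists(
            st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_metric_axioms(self, probs):
        a, b, c = self._random_dists(probs)
        dab, dba = fs.sps(a, b), fs.sps(b, a)
        assert dab == pytest.approx(dba, abs=1e-12)  # symmetry
        assert fs.sps(a, a) == 0.0  # identity
        assert dab <= fs.sps(a, c) + fs.sps(c, b) + 1e-9  # triangle
        assert 0.0 <= dab <= 1.0

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
           st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(max_examples=60, derandomize=True)
    def test_total_variation_identity(self, pa, pb):
        a, b = self._random_dists([pa, pb])
        da, db = a.as_dict(), b.as_dict()
        overlap = sum(min(da[s], db[s]) for s in da)
        assert fs.sps(a, b) == pytest.approx(1.0 - overlap, abs=1e-12)


class TestKl:
    def test_identical_is_zero(self):
        d = _Dist({"[]": 0.6, "_": 0.4})
        assert fs.kl_divergence(d, d) == pytest.approx(0.0)

    def test_asymmetric_on_printed_distributions(self):
        a = _Dist({k: v / 100 for k, v in SHIFT_EXAMPLE_PROBS["MacroState"].items()})
        b = _Dist({k: v / 100 for k, v in SHIFT_EXAMPLE_PROBS["MicroState"].items()})
        ab = fs.kl_divergence(a, b, "ab")
        ba = fs.kl_divergence(a, b, "ba")
        assert ab != pytest.approx(ba)
        assert ab > 0 and ba > 0

    def test_support_mismatch_is_infinite(self):
        a = _Dist({"[]": 0.5, "_": 0.5})
        b = _Dist({"[]": 1.0})
        assert math.isinf(fs.kl_divergence(a, b))


class TestBpDistance:
    def test_identical_structures(self):
        s = parse_dotbracket("((..((...)).))")
        assert fs.asymmetric_bp_distance(s, s).distance == 0

    def test_slippage_costs_two(self):
        ref = parse_dotbracket("(...).")
        pred = parse_dotbracket(".(...)")  # the gold pair slipped by one
        d = fs.asymmetric_bp_distance(ref, pred)
        assert d.distance == 2

    def test_compatible_extra_pairs_are_free(self):
        ref = parse_dotbracket(".((...))......")
        pred = parse_dotbracket(".((...)).(...)")  # one extra compatible pair
        d = fs.asymmetric_bp_distance(ref, pred)
        assert d.distance == 0
        assert d.compatible_removed == {(10, 14)}

    def test_crossing_extra_pair_counts(self):
        ref = parse_dotbracket("((...))...")
        pred = parse_dotbracket("...(....).")  # (4,9) crosses (1,7)
        assert fs.asymmetric_bp_distance(ref, pred).distance == 2 + 1

    def test_reduces_to_traditional_distance(self):
        # no compatible extras: prediction pairs clash with the reference
        ref = parse_dotbracket("((...))..")
        pred = parse_dotbracket(".((...)).")
        R, P = ref.pairs, pred.pairs
        d = fs.asymmetric_bp_distance(ref, pred)
        assert d.distance == len(R - P) + len(P - R)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ComparisonError):
            fs.asymmetric_bp_distance(
                parse_dotbracket("....."), parse_dotbracket("....")
            )


class TestRanks:
    def test_dominant_gold_shape_has_rank_one(self, params):
        seq = "GGGAAACCC"
        sd = fs.shape_distribution(seq, "MacroState", 5, params)
        gold = parse_dotbracket("(((...)))")
        gr = fs.gold_shape_rank(sd, gold)
        assert gr.rank == 1 and not gr.absent

    def test_absent_shape_flagged(self, params):
        seq = "GGGAAACCC"
        # a high cutoff leaves only the dominant shape in the list
        sd = fs.shape_distribution(seq, "MacroState", 5, params, cutoff=0.5)
        gold = parse_dotbracket("." * 9)
        gr = fs.gold_shape_rank(sd, gold)
        assert gr.absent and gr.rank == len(sd.entries) + 1

    def test_lower_quantile_convention(self):
        assert lower_quantile([1, 1, 2], 0.5) == 1
        assert lower_quantile([1, 1, 2], 0.9) == 2
        rs = RankSummary.from_ranks([1, 1, 2])
        assert (rs.median, rs.q90, rs.max) == (1, 2, 2)


class TestRunComparison:
    def _corpus(self, params):
        corpus = []
        for seq in fs.random_sequences(25, 6, seed=400):
            res = fs.fold_mfe(seq, "MicroState", params)
            base = res.structures[0]
            base = base.base if hasattr(base, "base") else base
            corpus.append((seq, base))
        return corpus[:3]

    def test_identical_models_give_zero_sps(self, params):
        corpus = self._corpus(params)[:1]
        rep = run_comparison(
            corpus, models=("MicroState", "MicroState"), levels=(5,), params=params
        )
        assert float(rep.sps_mean[5].iloc[0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_report_matches_hand_aggregation(self, params):
        corpus = self._corpus(params)
        models = ("NoDangle", "MacroState")
        rep = run_comparison(corpus, models=models, levels=(5,), params=params)
        # hand-computed aggregation
        sps_sum = 0.0
        agree = {m: 0 for m in models}
        dist = {m: 0 for m in models}
        for seq, gold in corpus:
            dists = {
                m: fs.shape_distribution(seq, m, 5, params) for m in models
            }
            sps_sum += fs.sps(dists[models[0]], dists[models[1]])
            g = fs.shape_of(gold, 5).text
            for m in models:
                if dists[m].entries[0].shape == g:
                    agree[m] += 1
                _, d = closest_cooptimal(fs.fold_mfe(seq, m, params), gold)
                dist[m] += d
        n = len(corpus)
        assert float(rep.sps_mean[5].loc[models[0], models[1]]) == pytest.approx(
            sps_sum / n
        )
        for m in models:
            assert float(rep.agreement.loc[5, m]) == pytest.approx(agree[m] / n)
            assert rep.distances[m] == dist[m]

    def test_mismatched_entries_skipped(self, params):
        seq = fs.random_sequences(20, 1, seed=401)[0]
        bad_gold = parse_dotbracket("." * 10)
        good = self._corpus(params)[:1]
        rep = run_comparison(
            good + [(seq, bad_gold)],
            models=("NoDangle",),
            levels=(5,),
            params=params,
        )
        assert rep.n_sequences == 1 and len(rep.skipped) == 1
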