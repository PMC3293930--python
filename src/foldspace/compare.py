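"""Model-comparison statistics.

* shape probability shift (SPS): half the L1 distance between two shape
  probability distributions -- the probability mass that moves between
  shapes when switching models;
* Kullback-Leibler divergence (both directions) as the rejected
  alternative measure;
* an asymmetric base-pair distance that forgives predicted extra pairs
  compatible with the reference;
* rank of the gold shape in a probability-sorted shape list, with
  lower-empirical-quantile summaries (coverage semantics: the 90% quantile
  r means the gold shape is within the top r shapes in 90% of cases).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .engine import ShapeDistribution, fold_mfe, shape_distribution
from .params import load_parameters
from .sequence import as_sequence
from .shapes import shape_of
from .structures import MicroStructure, SecondaryStructure

log = logging.getLogger(__name__)


class ComparisonError(ValueError):
    pass


def sps(dist_a: ShapeDistribution, dist_b: ShapeDistribution) -> float:
    """Shape probability shift: 0.5 * sum_p |Prob_A(p) - Prob_B(p)|.

    Shapes absent from one distribution count with probability 0.  Equals
    the total-variation distance between the two distributions.
    """
    if dist_a.level != dist_b.level:
        raise ComparisonError(
            f"shape levels differ: {dist_a.level} vs {dist_b.level}"
        )
    if dist_a.sequence and dist_b.sequence and dist_a.sequence != dist_b.sequence:
        raise ComparisonError("distributions belong to different sequences")
    pa = dist_a.as_dict() if hasattr(dist_a, "as_dict") else dict(dist_a)
    pb = dist_b.as_dict() if hasattr(dist_b, "as_dict") else dict(dist_b)
    return 0.5 * sum(
        abs(pa.get(p, 0.0) - pb.get(p, 0.0)) for p in set(pa) | set(pb)
    )


def kl_divergence(dist_a, dist_b, direction: str = "ab") -> float:
    """Kullback-Leibler divergence between shape distributions.

    ``direction="ab"`` computes KL(A||B) = sum p_A log(p_A/p_B);
    ``"ba"`` the reverse.  Infinite when the support condition fails.
    """
    pa = dist_a.as_dict() if hasattr(dist_a, "as_dict") else dict(dist_a)
    pb = dist_b.as_dict() if hasattr(dist_b, "as_dict") else dict(dist_b)
    if direction == "ba":
        pa, pb = pb, pa
    elif direction != "ab":
        raise ComparisonError(f"direction must be 'ab' or 'ba', got {direction!r}")
    total = 0.0
    for p, q in pa.items():
        if q <= 0:
            continue
        if pb.get(p, 0.0) <= 0:
            return math.inf
        total += q * math.log(q / pb[p])
    return total


@dataclass(frozen=True)
class DistanceResult:
    """Asymmetric base-pair distance |R\\P| + |P^{-c}\\R|."""

    reference_pairs: frozenset
    predicted_pairs: frozenset
    compatible_removed: frozenset  # predicted extra pairs compatible with R
    distance: int


def _compatible_with(pair, reference: SecondaryStructure) -> bool:
    """Both ends unpaired in the reference and no pseudoknot introduced."""
    a, b = pair
    partner = reference.partner()
    if partner[a - 1] != -1 or partner[b - 1] != -1:
        return False
    for (i, j) in reference.pairs:
        if (i < a < j < b) or (a < i < b < j):
            return False
    return True


def asymmetric_bp_distance(
    reference: SecondaryStructure, prediction: SecondaryStructure
) -> DistanceResult:
    """Base-pair distance treating compatible extra predictions as free.

    ``P^{-c}`` removes from the prediction those pairs absent from the
    reference whose bases are both unpaired there and which do not cross
    any reference pair.  No base-pair slippage is allowed: a reference
    pair (i, j) predicted as (i+1, j) still contributes distance 2.
    """
    if reference.length != prediction.length:
        raise ComparisonError(
            f"length mismatch: {reference.length} vs {prediction.length}"
        )
    R = reference.pairs
    P = prediction.pairs
    removed = frozenset(
        p for p in P - R if _compatible_with(p, reference)
    )
    pc = P - removed
    distance = len(R - P) + len(pc - R)
    return DistanceResult(
        reference_pairs=frozenset(R),
        predicted_pairs=frozenset(P),
        compatible_removed=removed,
        distance=distance,
    )


@dataclass(frozen=True)
class GoldRank:
    rank: int  # 1-based position in the probability-sorted list
    absent: bool  # gold shape missing from the (cutoff-filtered) list


def gold_shape_rank(dist: ShapeDistribution, gold: SecondaryStructure) -> GoldRank:
    """Rank of the gold structure's shape in the sorted shape list."""
    gshape = shape_of(gold, dist.level).text
    for pos, e in enumerate(dist.entries, start=1):
        if e.shape == gshape:
            return GoldRank(rank=pos, absent=False)
    return GoldRank(rank=len(dist.entries) + 1, absent=True)


def lower_quantile(values: Sequence, p: float):
    """Lower empirical quantile (type 1): smallest x with F(x) >= p."""
    if not values:
        raise ComparisonError("empty sample")
    xs = sorted(values)
    k = max(1, math.ceil(p * len(xs)))
    return xs[k - 1]


@dataclass
class RankSummary:
    ranks: List[int]
    median: int
    q75: int
    q90: int
    max: int
    n_absent: int

    @classmethod
    def from_ranks(cls, ranks: List[int], n_absent: int = 0) -> "RankSummary":
        return cls(
            ranks=list(ranks),
            median=lower_quantile(ranks, 0.5),
            q75=lower_quantile(ranks, 0.75),
            q90=lower_quantile(ranks, 0.90),
            max=max(ranks),
            n_absent=n_absent,
        )


@dataclass
class ComparisonReport:
    """Aggregated model-comparison statistics over a corpus."""

    models: Tuple[str, ...]
    levels: Tuple[int, ...]
    n_sequences: int
    sps_mean: Dict[int, pd.DataFrame]  # level -> model x model mean SPS
    agreement: pd.DataFrame  # level x model: dominant shape == gold shape
    ranks: Dict[Tuple[int, str], RankSummary]  # (level, model) -> summary
    distances: Dict[str, int]  # model -> summed asymmetric bp distance
    skipped: List[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "models": list(self.models),
            "levels": list(self.levels),
            "n_sequences": self.n_sequences,
            "sps_mean": {
                str(lv): df.round(6).to_dict() for lv, df in self.sps_mean.items()
            },
            "agreement": self.agreement.round(6).to_dict(),
            "ranks": {
                f"{lv}/{m}": {
                    "median": rs.median,
                    "q75": rs.q75,
                    "q90": rs.q90,
                    "max": rs.max,
                    "n_absent": rs.n_absent,
                }
                for (lv, m), rs in self.ranks.items()
            },
            "distances": dict(self.distances),
            "skipped": list(self.skipped),
        }


def closest_cooptimal(mfe_result, gold: SecondaryStructure):
    """Among co-optimal MFE structures, the one closest to the reference
    under the asymmetric base-pair distance."""
    best = None
    best_d = None
    for s in mfe_result.structures:
        base = s.base if isinstance(s, MicroStructure) else s
        d = asymmetric_bp_distance(gold, base).distance
        if best_d is None or d < best_d:
            best, best_d = base, d
    return best, best_d


def run_comparison(
    corpus,
    models: Sequence[str] = ("NoDangle", "OverDangle", "MicroState", "MacroState"),
    levels: Sequence[int] = (5, 2),
    params=None,
    cutoff: float = 1e-6,
) -> ComparisonReport:
    """Full model comparison over ``corpus`` = [(sequence, gold structure)].

    Computes, per abstraction level: the mean pairwise SPS matrix, the
    ratio of sequences whose dominant shape equals the gold shape, and the
    gold-shape rank quantiles; plus the summed asymmetric base-pair
    distance of each model's MFE prediction (closest co-optimal) to gold.
    """
    params = params or load_parameters()
    models = tuple(models)
    levels = tuple(levels)
    if not corpus:
        raise ComparisonError("empty corpus")
    skipped: List[str] = []
    entries = []
    for seq, gold in corpus:
        seq = as_sequence(seq)
        if gold.length != len(seq):
            msg = f"{seq.id or seq.seq[:20]}: sequence/structure length mismatch"
            log.warning("skipping %s", msg)
            skipped.append(msg)
            continue
        entries.append((seq, gold))
    if not entries:
        raise ComparisonError("no usable corpus entries")

    sps_sums = {lv: pd.DataFrame(0.0, index=models, columns=models) for lv in levels}
    agree = pd.DataFrame(0.0, index=levels, columns=models)
    rank_lists: Dict[Tuple[int, str], List[int]] = {
        (lv, m): [] for lv in levels for m in models
    }
    absents: Dict[Tuple[int, str], int] = {(lv, m): 0 for lv in levels for m in models}
    distances = {m: 0 for m in models}

    for seq, gold in entries:
        for m in models:
            res = fold_mfe(seq, m, params)
            _, d = closest_cooptimal(res, gold)
            distances[m] += d
        for lv in levels:
            dists = {
                m: shape_distribution(seq, m, lv, params, cutoff=cutoff)
                for m in models
            }
            gshape = shape_of(gold, lv).text
            for m in models:
                if dists[m].entries and dists[m].entries[0].shape == gshape:
                    agree.loc[lv, m] += 1
                gr = gold_shape_rank(dists[m], gold)
                rank_lists[(lv, m)].append(gr.rank)
                if gr.absent:
                    absents[(lv, m)] += 1
            for ma, mb in itertools.combinations(models, 2):
                v = sps(dists[ma], dists[mb])
                sps_sums[lv].loc[ma, mb] += v
                sps_sums[lv].loc[mb, ma] += v

    n = len(entries)
    return ComparisonReport(
        models=models,
        levels=levels,
        n_sequences=n,
        sps_mean={lv: df / n for lv, df in sps_sums.items()},
        agreement=agree / n,
        ranks={
            key: RankSummary.from_ranks(ranks, absents[key])
            for key, ranks in rank_lists.items()
        },
        distances=distances,
        skipped=skipped,
    )
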