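"""Folding-space growth experiment.

The number of secondary structures grows asymptotically like
``a * b**n * n**(-3/2)`` with b = 1.44358 (a = 3.45373); microstates add a
factor of roughly ``4**k(n)`` for the ~k(n) helices of a structure.  This
module measures mean folding-space sizes over uniformly random sequences
per length and estimates the per-base growth factor b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import pandas as pd

from .engine import count_structures
from .oracle import random_sequences

GROWTH_B = 1.44358
GROWTH_A = 3.45373

DEFAULT_MODELS = ("NoDangle", "OverDangle", "MacroState", "MicroState")


@dataclass
class GrowthConfig:
    """Lengths 30..60 in steps of 5, 100 uniformly random sequences per
    data point by default."""

    lengths: Sequence[int] = tuple(range(30, 61, 5))
    replicates: int = 100
    seed: int = 0
    models: Tuple[str, ...] = DEFAULT_MODELS

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(n < 1 for n in self.lengths):
            raise ValueError("lengths must be positive")


def growth_experiment(cfg: GrowthConfig) -> pd.DataFrame:
    """Mean folding-space size per length (rows) and model (columns).

    The same seeded sequences are used for every model, so the
    NoDangle/OverDangle/MacroState columns must agree exactly (identical
    folding spaces) while MicroState counts microstates.
    """
    rows = {}
    for idx, n in enumerate(cfg.lengths):
        seqs = random_sequences(n, cfg.replicates, seed=cfg.seed + idx)
        means = {}
        for model in cfg.models:
            total = sum(count_structures(s, model) for s in seqs)
            means[model] = total / cfg.replicates
        rows[n] = means
    return pd.DataFrame.from_dict(rows, orient="index")[list(cfg.models)]


def growth_factor(table: pd.DataFrame, model: str = "NoDangle") -> float:
    """Per-base growth factor: exp of the least-squares slope of
    ln(mean count) against length."""
    ns = list(table.index)
    ys = [math.log(v) for v in table[model]]
    n = len(ns)
    mx = sum(ns) / n
    my = sum(ys) / n
    slope = sum((x - mx) * (y - my) for x, y in zip(ns, ys)) / sum(
        (x - mx) ** 2 for x in ns
    )
    return math.exp(slope)
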