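"""Brute-force folding-space oracle and seeded random sequences.

:func:`brute_force_fold` enumerates the complete folding space of a short
sequence by direct recursion over the structural alternatives (canonical
pairs, two stacked closing pairs everywhere, hairpins >= 3, bulge/internal
strands <= 30) and scores every member with
:func:`foldspace.structures.evaluate_structure_energy`.  No dynamic
programming over energies is involved, so it serves as an independent
oracle for the grammar walkers.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .params import EnergyParameters, load_parameters, pair_type
from .sequence import RnaSequence, as_sequence
from .shapes import shape_of
from .structures import (
    MicroStructure,
    SecondaryStructure,
    enumerate_dangle_variants,
    evaluate_structure_energy,
    macrostate_ensemble_energy,
)

DEFAULT_CAP = 22
MICRO_CAP = 18
MAXLOOP = 30


def random_sequences(n: int, count: int, seed: int) -> List[RnaSequence]:
    """``count`` i.i.d. uniform ACGU sequences of length ``n`` (seeded)."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    rng = random.Random(seed)
    return [
        RnaSequence("".join(rng.choice("ACGU") for _ in range(n)), id=f"rnd{k}")
        for k in range(count)
    ]


def enumerate_structures(seq) -> List[SecondaryStructure]:
    """All folding-space members of ``seq`` (shared model filters)."""
    code = as_sequence(seq).code
    n = len(code)

    def pt(i, j):
        return pair_type(code[i], code[j])

    closed_memo: Dict[Tuple[int, int], list] = {}

    def closed(i, j):  # structures whose outermost pair is exactly (i, j)
        key = (i, j)
        if key in closed_memo:
            return closed_memo[key]
        res = []
        if j - i >= 6 and pt(i, j) and pt(i + 1, j - 1):
            outer = ((i + 1, j + 1), (i + 2, j))  # 1-based pair tuples
            # stack: extend the helix
            for c in closed(i + 1, j - 1):
                res.append(((i + 1, j + 1),) + c)
            # hairpin
            if j - i - 3 >= 3:
                res.append(outer)
            # left/right bulge
            for lb in range(1, min(MAXLOOP, j - i - 7) + 1):
                for c in closed(i + 2 + lb, j - 2):
                    res.append(outer + c)
            for rb in range(1, min(MAXLOOP, j - i - 7) + 1):
                for c in closed(i + 2, j - 2 - rb):
                    res.append(outer + c)
            # internal loop
            for l5 in range(1, min(MAXLOOP, j - i - 8) + 1):
                for l3 in range(1, min(MAXLOOP, j - i - 8 - l5) + 1):
                    for c in closed(i + 2 + l5, j - 2 - l3):
                        res.append(outer + c)
            # multiloop: >= 2 components in the interior
            for comp in comps(i + 2, j - 1, 2):
                res.append(outer + comp)
        closed_memo[key] = res
        return res

    comps_memo: Dict[Tuple[int, int, int], list] = {}

    def comps(i, j, need):  # pair-lists over [i, j) with >= need components
        key = (i, j, min(need, 2))
        if key in comps_memo:
            return comps_memo[key]
        res = []
        if i >= j:
            res = [()] if need <= 0 else []
        else:
            res.extend(comps(i + 1, j, need))  # position i unpaired
            for l in range(i + 6, j):
                for c in closed(i, l):
                    for rest in comps(l + 1, j, need - 1):
                        res.append(c + rest)
        comps_memo[key] = res
        return res

    return [
        SecondaryStructure.from_pairs(n, pl) for pl in comps(0, n, 0)
    ]


@dataclass
class BruteForceResult:
    """Exhaustively enumerated folding space of one sequence and model."""

    model: str
    structures: list  # (structure-or-microstructure, mfe-energy, ensemble-energy)
    count: int
    mfe: float
    mfe_structures: list
    q: float

    def shape_masses(self, level: int) -> Dict[str, Tuple[float, float, object]]:
        """shape -> (mass, best ensemble energy, shrep)."""
        rt = self._rt
        out: Dict[str, Tuple[float, float, object]] = {}
        for s, _, e in self.structures:
            base = s.base if isinstance(s, MicroStructure) else s
            shp = shape_of(base, level).text
            w = math.exp(-e / rt)
            old = out.get(shp)
            if old is None:
                out[shp] = (w, e, s)
            else:
                out[shp] = (
                    old[0] + w,
                    *((e, s) if e < old[1] else (old[1], old[2])),
                )
        return out

    _rt: float = field(default=0.61633, repr=False)


def brute_force_fold(
    seq,
    model: str,
    params: Optional[EnergyParameters] = None,
    cap: int = DEFAULT_CAP,
) -> BruteForceResult:
    """Enumerate and score the complete folding space (small n only)."""
    seq = as_sequence(seq)
    params = params or load_parameters()
    limit = min(cap, MICRO_CAP) if model == "MicroState" else cap
    if len(seq) > limit:
        raise ValueError(
            f"brute force capped at {limit} nt for {model}, got {len(seq)}"
        )
    scored = []
    for s in enumerate_structures(seq):
        if model == "MicroState":
            for m in enumerate_dangle_variants(s):
                e = evaluate_structure_energy(seq, m, "MicroState", params)
                scored.append((m, e, e))
        elif model == "MacroState":
            e = evaluate_structure_energy(seq, s, model, params)
            scored.append((s, e, macrostate_ensemble_energy(seq, s, params)))
        else:
            e = evaluate_structure_energy(seq, s, model, params)
            scored.append((s, e, e))
    mfe = min(e for _, e, _ in scored)
    q = sum(math.exp(-ep / params.rt) for _, _, ep in scored)
    res = BruteForceResult(
        model=model,
        structures=scored,
        count=len(scored),
        mfe=mfe,
        mfe_structures=[s for s, e, _ in scored if e == mfe],
        q=q,
    )
    res._rt = params.rt
    return res
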