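"""Folding analyses over the four folding-space models.

Every analysis runs the model's grammar (see :mod:`foldspace._dp`) with a
dedicated evaluation algebra:

* :func:`fold_mfe` -- minimum free energy with *all* co-optimal structures;
* :func:`count_structures` -- exact folding-space size;
* :func:`partition_function` -- Boltzmann partition function Q;
* :func:`shape_distribution` -- accumulated Boltzmann mass, probability and
  shrep per abstract shape class;
* :func:`enumerate_suboptimals` -- complete enumeration of all structures
  within an energy band above the MFE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from . import _dp
from .algebras import CandidateAlgebra, CountAlgebra, PartitionAlgebra, ShapeAlgebra
from .params import EnergyParameters, load_parameters
from .sequence import RnaSequence, as_sequence
from .structures import (
    MODELS,
    MicroStructure,
    SecondaryStructure,
    parse_dotbracket,
    parse_extended,
    rescore_structures,
)

DEFAULT_SHAPE_CUTOFF = 1e-6


def _check(seq, model, params) -> Tuple[RnaSequence, str, EnergyParameters]:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    seq = as_sequence(seq)
    if len(seq) < 1:
        raise ValueError("empty sequence")
    return seq, model, (params or load_parameters())


def _run(seq, model, params, alg, ensemble=False):
    ctx = _dp.Ctx(seq.code, params)
    if model == "MicroState":
        return _dp.run_microstate(ctx, alg)
    if model == "MacroState":
        if ensemble:
            return _dp.run_macrostate_ensemble(ctx, alg)
        return _dp.run_macrostate(ctx, alg)
    return _dp.run_shared(ctx, alg, overdangle=(model == "OverDangle"))


@dataclass
class MfeResult:
    """Minimum free energy and all co-optimal structures."""

    energy: float  # kcal/mol
    structures: list  # SecondaryStructure (MicroState: MicroStructure)
    model: str

    @property
    def dotbrackets(self) -> List[str]:
        return [str(s) for s in self.structures]


@dataclass
class PartitionResult:
    """Partition function of the model's folding space."""

    q: float
    model: str
    params: EnergyParameters = field(repr=False)


@dataclass
class ShapeEntry:
    shape: str
    probability: float
    mass: float  # Q_p
    shrep: SecondaryStructure
    shrep_energy: float  # kcal/mol


@dataclass
class ShapeDistribution:
    """Shape probabilities Prob(p) = Q_p / Q at one abstraction level."""

    level: int
    model: str
    q: float
    entries: List[ShapeEntry]
    cutoff: float
    sequence: str = ""

    def probability(self, shape: str) -> float:
        for e in self.entries:
            if e.shape == shape:
                return e.probability
        return 0.0

    def as_dict(self):
        return {e.shape: e.probability for e in self.entries}

    def __iter__(self):
        return iter(self.entries)


def fold_mfe(seq, model: str, params=None) -> MfeResult:
    """MFE folding; reports all co-optimal structures.

    For MicroState, co-optimal microstates of the same macrostate (same
    base-pair set, different dangles) are collapsed to a single reported
    microstructure.
    """
    seq, model, params = _check(seq, model, params)
    cands = _run(seq, model, params, CandidateAlgebra(delta=0))
    best = min(e for e, _ in cands)
    structs = []
    seen = set()
    for e, s in sorted(cands):
        if e != best:
            continue
        if model == "MicroState":
            key = s.replace("d", ".").replace("b", ".")
            if key in seen:
                continue
            seen.add(key)
            structs.append(parse_extended(s))
        else:
            if s in seen:
                continue
            seen.add(s)
            structs.append(parse_dotbracket(s))
    return MfeResult(energy=best / 100.0, structures=structs, model=model)


def count_structures(seq, model: str) -> int:
    """Exact size of the model's folding space (MicroState counts
    microstates, the other three count classical structures)."""
    from . import _count

    seq, model, _ = _check(seq, model, None)
    if model in ("NoDangle", "OverDangle"):
        return _count.count_nodangle(seq.code)
    if model == "MicroState":
        return _count.count_microstate(seq.code)
    return _count.count_macrostate(seq.code)


def count_structures_generic(seq, model: str) -> int:
    """Folding-space size via the generic grammar walker (cross-check path
    for the optimized counters)."""
    seq, model, params = _check(seq, model, None)
    return _run(seq, model, params, CountAlgebra())


def partition_function(seq, model: str, params=None) -> PartitionResult:
    seq, model, params = _check(seq, model, params)
    q = _run(seq, model, params, PartitionAlgebra(params.rt), ensemble=True)
    return PartitionResult(q=q, model=model, params=params)


def shape_distribution(
    seq,
    model: str,
    level: int = 5,
    params=None,
    cutoff: float = DEFAULT_SHAPE_CUTOFF,
) -> ShapeDistribution:
    """Probabilities, Boltzmann masses and shreps of all shape classes.

    ``cutoff`` drops shapes with probability below it after normalization
    (0 keeps everything; the masses then sum exactly to Q).
    """
    if level not in (1, 2, 3, 4, 5):
        raise ValueError(f"shape level must be 1..5, got {level}")
    seq, model, params = _check(seq, model, params)
    table = _run(seq, model, params, ShapeAlgebra(level, params.rt), ensemble=True)
    table = {(shp if shp else "_"): v for shp, v in table.items()}
    q = sum(m for m, _, _ in table.values())
    entries = []
    for shp, (mass, be, bs) in table.items():
        prob = mass / q
        if cutoff and prob < cutoff:
            continue
        if model == "MicroState":
            shrep = parse_extended(bs).base
        else:
            shrep = parse_dotbracket(bs)
        entries.append(
            ShapeEntry(
                shape=shp,
                probability=prob,
                mass=mass,
                shrep=shrep,
                shrep_energy=be / 100.0,
            )
        )
    entries.sort(key=lambda e: (-e.probability, e.shape))
    return ShapeDistribution(
        level=level,
        model=model,
        q=q,
        entries=entries,
        cutoff=cutoff,
        sequence=seq.seq,
    )


def enumerate_suboptimals(
    seq,
    model: str,
    delta: Optional[float],
    rescore_to: Optional[str] = None,
    params=None,
):
    """All folding-space members within ``delta`` kcal/mol of the MFE,
    ascending by energy.  ``delta=None`` enumerates the complete space.

    With ``rescore_to``, the enumerated list is re-evaluated under another
    model and re-sorted (stable); note the re-scored list is then ordered
    by the new energies, and the target model's true MFE structure need not
    be present when it fell outside the enumeration band.
    Returns a list of ``(structure, energy_kcal)``.
    """
    if delta is not None and delta < 0:
        raise ValueError("delta must be >= 0")
    seq, model, params = _check(seq, model, params)
    delta_c = None if delta is None else int(round(delta * 100))
    cands = _run(seq, model, params, CandidateAlgebra(delta=delta_c))
    best = min(e for e, _ in cands)
    out = []
    for e, s in sorted(cands):
        if delta_c is not None and e > best + delta_c:
            continue
        st = parse_extended(s) if model == "MicroState" else parse_dotbracket(s)
        out.append((st, e / 100.0))
    if rescore_to is not None:
        structs = [s for s, _ in out]
        return rescore_structures(seq, structs, model, rescore_to, params)
    return out
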