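"""Elementary free-energy functions of the nearest-neighbor model.

Every function here is a pure table lookup / closed-form combination over an
:class:`~foldspace.params.EnergyParameters` set and returns an **integer in
centi-kcal/mol**.  The four grammar variants and the structure evaluator all
call these functions and nothing else, so the energy model is shared by
construction.

Loop conventions (matching the RNAfold family the models mirror):

* hairpins of size 3 take the terminal-AU penalty and no mismatch term;
  larger hairpins take the terminal mismatch; tabulated tetra-/tri-/hexaloop
  sequences (closing pair + loop) replace the whole hairpin term;
* a length-1 bulge keeps the helix stack across the bulge and takes no
  terminal-AU penalty; longer bulges take terminal-AU at both closing pairs;
* internal loops use the special 1x1 / 1x2 / 2x2 tables when applicable,
  dedicated mismatch tables for 1xn and 2x3 loops, and the generic
  length + Ninio-asymmetry + mismatch form otherwise;
* dangling-end energies for multiloop-closing pairs seen from the inside
  use the dangle tables of the reversed pair.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Tuple, Union

from .params import (
    BASES,
    INF,
    REVERSE_TYPE,
    EnergyParameters,
    encode,
    pair_type,
)

Base = int
Pair = Tuple[Base, Base]

MAX_TAB_LOOP = 30  # largest tabulated loop length


class EnergyError(ValueError):
    """Invalid input to an energy function (non-canonical pair, bad loop)."""


def _norm_base(b: Union[int, str]) -> int:
    if isinstance(b, str):
        b = b.upper().replace("T", "U")
        if b not in BASES:
            raise EnergyError(f"not a nucleotide: {b!r}")
        return BASES.index(b)
    if not 0 <= b <= 3:
        raise EnergyError(f"base code out of range: {b}")
    return b


def _norm_pair(p: Union[Pair, str, Sequence]) -> Tuple[int, int]:
    if isinstance(p, str):
        if len(p) != 2:
            raise EnergyError(f"pair must be two bases, got {p!r}")
        p = (p[0], p[1])
    return _norm_base(p[0]), _norm_base(p[1])


def _norm_region(r: Union[str, Iterable]) -> Tuple[int, ...]:
    if isinstance(r, str):
        return encode(r.upper().replace("T", "U"))
    return tuple(_norm_base(b) for b in r)


def _ptype(p: Union[Pair, str, Sequence]) -> Tuple[int, Tuple[int, int]]:
    b5, b3 = _norm_pair(p)
    t = pair_type(b5, b3)
    if t == 0:
        raise EnergyError(f"non-canonical base pair {BASES[b5]}:{BASES[b3]}")
    return t, (b5, b3)


def _extrapolate(table: list, size: int, params: EnergyParameters) -> int:
    """Loop length penalty, Jacobson-Stockmayer extrapolated beyond 30 nt."""
    if size <= MAX_TAB_LOOP:
        return table[size]
    return table[MAX_TAB_LOOP] + int(params.lxc * math.log(size / MAX_TAB_LOOP))


# ---------------------------------------------------------------------------
# basic model (no dangles)


def sr_energy(outer_pair, inner_pair, params: EnergyParameters) -> int:
    """Stacking energy of ``inner_pair`` directly inside ``outer_pair``."""
    t1, _ = _ptype(outer_pair)
    ti, inner = _ptype(inner_pair)
    t2 = REVERSE_TYPE[ti]
    return params.stack_table[t1 - 1][t2 - 1]


def termau_energy(pair, params: EnergyParameters) -> int:
    """Penalty for a helix ending on a non-GC pair (A:U, U:A, G:U, U:G)."""
    t, _ = _ptype(pair)
    return params.terminal_au if t > 2 else 0


def hairpin_energy(closing_pair, loop_seq, params: EnergyParameters) -> int:
    """Energy of a hairpin loop ``loop_seq`` closed by ``closing_pair``."""
    t, (b5, b3) = _ptype(closing_pair)
    loop = _norm_region(loop_seq)
    size = len(loop)
    if size < 3:
        raise EnergyError(f"hairpin loop of size {size} < 3")
    e = _extrapolate(params.hairpin_length, size, params)
    key = BASES[b5] + "".join(BASES[b] for b in loop) + BASES[b3]
    if size == 4 and key in params.tetraloop_bonus:
        return params.tetraloop_bonus[key]
    if size == 6 and key in params.hexaloop_bonus:
        return params.hexaloop_bonus[key]
    if size == 3:
        if key in params.triloop_bonus:
            return params.triloop_bonus[key]
        return e + (params.terminal_au if t > 2 else 0)
    return e + params.mismatch_hairpin[t - 1][loop[0] + 1][loop[-1] + 1]


def bulge_energy(side, closing_pair, inner_pair, loop_seq, params) -> int:
    """Energy of a bulge loop (``side`` = "left"/"right" of the inner helix).

    The side only matters for input validation symmetry; the Turner bulge
    penalty itself is orientation independent, and the length-1 stack
    continuation uses both pairs either way.
    """
    if side not in ("left", "right"):
        raise EnergyError(f"bulge side must be 'left' or 'right', got {side!r}")
    t1, _ = _ptype(closing_pair)
    ti, _ = _ptype(inner_pair)
    t2 = REVERSE_TYPE[ti]
    loop = _norm_region(loop_seq)
    size = len(loop)
    if size < 1:
        raise EnergyError("empty bulge loop")
    if size > MAX_TAB_LOOP:
        raise EnergyError(f"bulge loop of size {size} > {MAX_TAB_LOOP}")
    e = params.bulge_length[size]
    if size == 1:
        e += params.stack_table[t1 - 1][t2 - 1]
    else:
        if t1 > 2:
            e += params.terminal_au
        if t2 > 2:
            e += params.terminal_au
    return e


def internal_energy(closing_pair, inner_pair, loop5, loop3, params) -> int:
    """Energy of an internal loop with 5' region ``loop5``, 3' region ``loop3``."""
    t1, _ = _ptype(closing_pair)
    ti, _ = _ptype(inner_pair)
    t2 = REVERSE_TYPE[ti]
    l5 = _norm_region(loop5)
    l3 = _norm_region(loop3)
    n1, n2 = len(l5), len(l3)
    if n1 == 0 or n2 == 0:
        raise EnergyError("internal loop regions must be non-empty (use a bulge)")
    si = l5[0] + 1  # base 3' of the closing pair's 5' side
    sp = l5[-1] + 1  # base 5' of the inner pair
    sq = l3[0] + 1  # base 3' of the inner pair
    sj = l3[-1] + 1  # base 5' of the closing pair's 3' side
    ns, nl = min(n1, n2), max(n1, n2)
    if ns == 1 and nl == 1:
        return params.int11[t1 - 1][t2 - 1][si][sj]
    if ns == 1 and nl == 2:
        if n1 == 1:
            return params.int21[t1 - 1][t2 - 1][si][sq][sj]
        return params.int21[t2 - 1][t1 - 1][sq][si][sp]
    if ns == 2 and nl == 2:
        return params.int22[t1 - 1][t2 - 1][si - 1][sp - 1][sq - 1][sj - 1]
    size = n1 + n2
    asym = min(params.ninio_max, (nl - ns) * params.ninio)
    if ns == 1:
        e = _extrapolate(params.internal_length, size, params) + asym
        mm = params.mismatch_internal_1n
    elif ns == 2 and nl == 3:
        e = params.internal_length[5] + asym
        mm = params.mismatch_internal_23
    else:
        e = _extrapolate(params.internal_length, size, params) + asym
        mm = params.mismatch_internal
    return e + mm[t1 - 1][si][sj] + mm[t2 - 1][sq][sp]


def multiloop_terms(n_branches: int, params: EnergyParameters) -> int:
    """Penalty of a multiloop with ``n_branches`` inner stems.

    The closing stem counts towards the per-stem penalty as well:
    ``ml_offset + (n_branches + 1) * ml_branch``.
    """
    if n_branches < 2:
        raise EnergyError("a multiloop has at least 2 inner stems")
    return params.ml_offset + (n_branches + 1) * params.ml_branch


# ---------------------------------------------------------------------------
# dangling ends

_DANGLE_KINDS = ("dl", "dr", "dli", "dri", "ext_mismatch", "ml_mismatch")


def dangle_energy(kind, pair, base5, base3, params: EnergyParameters) -> int:
    """Dangling-end / terminal-mismatch energy onto a helix-closing ``pair``.

    ``dl``/``dr``: base 5' (resp. 3') of the pair, seen from outside the
    helix.  ``dli``/``dri``: base just inside a multiloop-closing pair; the
    tables of the reversed pair are used.  ``ext_mismatch``/``ml_mismatch``:
    both sides combined additively.
    """
    t, _ = _ptype(pair)
    rt = REVERSE_TYPE[t]
    if kind == "dl":
        if base5 is None:
            raise EnergyError("dl requires the 5' base")
        return params.dangle5[t - 1][_norm_base(base5) + 1]
    if kind == "dr":
        if base3 is None:
            raise EnergyError("dr requires the 3' base")
        return params.dangle3[t - 1][_norm_base(base3) + 1]
    if kind == "dli":
        if base5 is None:
            raise EnergyError("dli requires the inner 5'-side base")
        return params.dangle3[rt - 1][_norm_base(base5) + 1]
    if kind == "dri":
        if base3 is None:
            raise EnergyError("dri requires the inner 3'-side base")
        return params.dangle5[rt - 1][_norm_base(base3) + 1]
    if kind == "ext_mismatch":
        e = 0
        if base5 is not None:
            e += params.dangle5[t - 1][_norm_base(base5) + 1]
        if base3 is not None:
            e += params.dangle3[t - 1][_norm_base(base3) + 1]
        return e
    if kind == "ml_mismatch":
        if base5 is None or base3 is None:
            raise EnergyError("ml_mismatch requires both inner bases")
        return (
            params.dangle3[rt - 1][_norm_base(base5) + 1]
            + params.dangle5[rt - 1][_norm_base(base3) + 1]
        )
    raise EnergyError(f"unknown dangle kind {kind!r}; expected {_DANGLE_KINDS}")


def boltzmann_weight(energy_kcal: float, params: EnergyParameters) -> float:
    """Boltzmann weight exp(-E / RT) of a free energy in kcal/mol."""
    if not math.isfinite(energy_kcal):
        raise EnergyError("energy must be finite")
    return math.exp(-energy_kcal / params.rt)


def to_kcal(centi: int) -> float:
    """Convert internal centi-kcal/mol integers to kcal/mol."""
    return centi / 100.0
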