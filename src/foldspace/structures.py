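"""Secondary structures, dangle-annotated microstates, and their energies.

A :class:`SecondaryStructure` is a nested set of base pairs (1-based
positions) with a dot-bracket form.  A :class:`MicroStructure` additionally
assigns dangling ends to unpaired bases: ``d`` marks a base stacking onto
the helix ending directly to its left, ``b`` onto the helix starting
directly to its right.  Dangles exist only in the exterior loop and inside
multiloops; loop regions of hairpins, bulges and internal loops are part of
the loop energies and never dangle.

:func:`evaluate_structure_energy` scores a given (micro)structure under any
of the four model variants (NoDangle, OverDangle, MicroState, MacroState)
by decomposing it into loops and summing the elementary energy functions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import energy as en
from .params import EnergyParameters, pair_type
from .sequence import RnaSequence, as_sequence

MODELS = ("NoDangle", "OverDangle", "MicroState", "MacroState")


class StructureError(ValueError):
    pass


def _check_model(model: str) -> str:
    if model not in MODELS:
        raise StructureError(f"unknown model {model!r}; expected one of {MODELS}")
    return model


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure.

    ``pairs`` are 1-based ``(i, j)`` with ``i < j``; ``length`` is the
    sequence length the structure refers to.
    """

    length: int
    pairs: frozenset

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair ({i},{j}) out of range 1..{self.length}")
            if i in seen or j in seen:
                raise StructureError(f"position in more than one pair near ({i},{j})")
            seen.add(i)
            seen.add(j)
        for (i, j), (k, l) in itertools.combinations(sorted(self.pairs), 2):
            if i < k < j < l:
                raise StructureError(f"crossing pairs ({i},{j}) and ({k},{l})")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_pairs(cls, length: int, pairs: Iterable) -> "SecondaryStructure":
        return cls(length=length, pairs=frozenset(tuple(p) for p in pairs))

    @classmethod
    def open_chain(cls, length: int) -> "SecondaryStructure":
        return cls(length=length, pairs=frozenset())

    # -- views -------------------------------------------------------------

    @property
    def dotbracket(self) -> str:
        out = ["."] * self.length
        for i, j in self.pairs:
            out[i - 1] = "("
            out[j - 1] = ")"
        return "".join(out)

    def partner(self) -> List[int]:
        """0-based partner array; -1 for unpaired."""
        p = [-1] * self.length
        for i, j in self.pairs:
            p[i - 1] = j - 1
            p[j - 1] = i - 1
        return p

    def __str__(self) -> str:
        return self.dotbracket

    def __len__(self) -> int:
        return self.length

    # -- folding-space membership -----------------------------------------

    def is_folding_space_member(self, seq: Optional[RnaSequence] = None) -> bool:
        """True iff the structure satisfies the shared model filters:
        canonical pairs only (when a sequence is given), hairpin loops >= 3,
        bulge/internal loop regions <= 30, and no lonely pairs (every pair
        stacked on a neighbor)."""
        if seq is not None:
            code = as_sequence(seq).code
            if len(code) != self.length:
                raise StructureError("sequence/structure length mismatch")
            for i, j in self.pairs:
                if pair_type(code[i - 1], code[j - 1]) == 0:
                    return False
        pairs = self.pairs
        for i, j in pairs:
            if (i + 1, j - 1) not in pairs and (i - 1, j + 1) not in pairs:
                return False
        for loop in self.loops():
            if loop.kind == "hairpin" and loop.size < 3:
                return False
            if loop.kind in ("bulge_left", "bulge_right") and loop.size > 30:
                return False
            if loop.kind == "internal" and (
                len(loop.region5) > 30 or len(loop.region3) > 30
            ):
                return False
        return True

    # -- loop decomposition --------------------------------------------------

    def loops(self) -> List["Loop"]:
        """Decompose into loops (exterior loop first)."""
        return _decompose(self)


@dataclass(frozen=True)
class Loop:
    """One face of the structure tree.

    ``closing`` is the closing pair (None for the exterior loop),
    ``children`` the directly enclosed pairs in 5'->3' order, ``runs`` the
    maximal unpaired intervals ``(start, end)`` inclusive (1-based) in
    order.  ``kind`` is one of exterior/hairpin/stack/bulge_left/
    bulge_right/internal/multiloop.
    """

    closing: Optional[Tuple[int, int]]
    children: tuple
    runs: tuple
    kind: str

    @property
    def size(self) -> int:
        return sum(e - s + 1 for s, e in self.runs)

    @property
    def region5(self) -> Tuple[int, int]:
        """For internal loops: the 5' unpaired interval."""
        return self.runs[0]

    @property
    def region3(self) -> Tuple[int, int]:
        return self.runs[-1]


def _decompose(s: SecondaryStructure) -> List[Loop]:
    n = s.length
    partner = s.partner()
    loops: List[Loop] = []

    def scan(lo: int, hi: int, closing):  # 0-based inclusive interior
        children = []
        runs = []
        k = lo
        run_start = None
        while k <= hi:
            if partner[k] > k:
                if run_start is not None:
                    runs.append((run_start + 1, k))
                    run_start = None
                children.append((k + 1, partner[k] + 1))
                k = partner[k] + 1
            else:
                if run_start is None:
                    run_start = k
                k += 1
        if run_start is not None:
            runs.append((run_start + 1, hi + 1))
        if closing is None:
            kind = "exterior"
        elif not children:
            kind = "hairpin"
        elif len(children) == 1:
            (ci, cj) = children[0]
            i, j = closing
            left = ci - i - 1
            right = j - cj - 1
            if left == 0 and right == 0:
                kind = "stack"
            elif right == 0:
                kind = "bulge_left"
            elif left == 0:
                kind = "bulge_right"
            else:
                kind = "internal"
        else:
            kind = "multiloop"
        loops.append(Loop(closing, tuple(children), tuple(runs), kind))
        for (ci, cj) in children:
            scan(ci, cj - 2, (ci, cj))

    # iterative wrapper to avoid deep recursion on long helices
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        scan(0, n - 1, None)
    finally:
        sys.setrecursionlimit(old)
    return loops


# ---------------------------------------------------------------------------
# parsing / writing


def parse_dotbracket(text: str, length: Optional[int] = None) -> SecondaryStructure:
    """Parse a Vienna dot-bracket string (characters ``().``)."""
    text = text.strip()
    stack = []
    pairs = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    if length is not None and length != len(text):
        raise StructureError("length mismatch")
    return SecondaryStructure.from_pairs(len(text), pairs)


def parse_ct(text: str) -> Tuple[str, SecondaryStructure]:
    """Parse a connect (CT) table: returns (sequence, structure).

    Columns: index, base, previous, next, pair (0 = unpaired), index.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty CT input")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError):
        raise StructureError("CT header must start with the sequence length")
    seq = [""] * n
    pairs = set()
    body = lines[1 : 1 + n]
    if len(body) != n:
        raise StructureError(f"CT body has {len(body)} rows, expected {n}")
    for ln in body:
        f = ln.split()
        idx, base, pairidx = int(f[0]), f[1], int(f[4])
        seq[idx - 1] = base
        if pairidx > idx:
            pairs.add((idx, pairidx))
    return "".join(seq), SecondaryStructure.from_pairs(n, pairs)


def write_ct(seq, s: SecondaryStructure, name: str = "") -> str:
    seq = as_sequence(seq)
    partner = s.partner()
    lines = [f"{s.length} {name}".rstrip()]
    for i in range(s.length):
        lines.append(
            f"{i + 1} {seq.seq[i]} {i} {i + 2 if i + 1 < s.length else 0} "
            f"{partner[i] + 1} {i + 1}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# microstates (explicit dangles)


@dataclass(frozen=True)
class MicroStructure:
    """A secondary structure refined with an explicit dangle assignment.

    ``dangles`` maps 1-based unpaired positions to ``"d"`` (onto the helix
    ending at position-1) or ``"b"`` (onto the helix starting at
    position+1).
    """

    base: SecondaryStructure
    dangles: tuple  # sorted tuple of (pos, 'd'|'b')

    def __post_init__(self):
        sites = dangle_sites(self.base)
        allowed = {pos: opts for pos, opts in sites}
        for pos, sym in self.dangles:
            if sym not in ("d", "b"):
                raise StructureError(f"dangle symbol must be d/b, got {sym!r}")
            if pos not in allowed or sym not in allowed[pos]:
                raise StructureError(
                    f"position {pos} cannot dangle {sym!r} in this structure"
                )

    @property
    def extended(self) -> str:
        out = list(self.base.dotbracket)
        for pos, sym in self.dangles:
            out[pos - 1] = sym
        return "".join(out)

    def __str__(self) -> str:
        return self.extended


def parse_extended(text: str) -> MicroStructure:
    """Parse an extended dot-bracket string over ``().db``."""
    plain = text.replace("d", ".").replace("b", ".")
    base = parse_dotbracket(plain)
    dangles = tuple(
        (pos, ch) for pos, ch in enumerate(text, start=1) if ch in "db"
    )
    return MicroStructure(base=base, dangles=dangles)


def dangle_sites(s: SecondaryStructure) -> List[Tuple[int, str]]:
    """Eligible dangle positions of a structure.

    Returns ``(position, options)`` for every unpaired base in the exterior
    loop or a multiloop that is adjacent to at least one helix end; options
    is a string containing ``d`` and/or ``b``.  Hairpin-, bulge- and
    internal-loop strands are never eligible.
    """
    partner = s.partner()
    sites = []
    for loop in s.loops():
        if loop.kind not in ("exterior", "multiloop"):
            continue
        for (start, end) in loop.runs:
            first, last = start, end
            opts_first = ""
            if first - 2 >= 0 and partner[first - 2] != -1:
                opts_first += "d"
            if first == last:
                if last < s.length and partner[last] != -1:
                    opts_first += "b"
                if opts_first:
                    sites.append((first, opts_first))
            else:
                if opts_first:
                    sites.append((first, opts_first))
                if last < s.length and partner[last] != -1:
                    sites.append((last, "b"))
    return sorted(sites)


def enumerate_dangle_variants(s: SecondaryStructure) -> List[MicroStructure]:
    """All legal dangle assignments of ``s`` (including the all-dots one)."""
    sites = dangle_sites(s)
    options = [("",) + tuple(opts) for _, opts in sites]
    variants = []
    for choice in itertools.product(*options):
        dangles = tuple(
            (pos, sym)
            for (pos, _), sym in zip(sites, choice)
            if sym
        )
        variants.append(MicroStructure(base=s, dangles=dangles))
    return variants


def count_dangle_variants(s: SecondaryStructure) -> int:
    """Number of microstates of ``s`` (product of per-site option counts)."""
    total = 1
    for _, opts in dangle_sites(s):
        total *= 1 + len(opts)
    return total


# ---------------------------------------------------------------------------
# energy evaluation


def _dangle_term(code, partner, pos0, sym, params) -> int:
    """Energy of one explicit dangle (0-based position)."""
    if sym == "d":
        q = pos0 - 1
        mate = partner[q]
        if mate < q:  # helix (mate, q) ends at q: outside 3' dangle
            pt_pair = (code[mate], code[q])
            return en.dangle_energy("dr", pt_pair, None, code[pos0], params)
        # pos is inside closing pair (q, mate): inner left side
        pt_pair = (code[q], code[mate])
        return en.dangle_energy("dli", pt_pair, code[pos0], None, params)
    else:  # 'b'
        q = pos0 + 1
        mate = partner[q]
        if mate > q:  # helix (q, mate) starts at q: outside 5' dangle
            pt_pair = (code[q], code[mate])
            return en.dangle_energy("dl", pt_pair, code[pos0], None, params)
        pt_pair = (code[mate], code[q])
        return en.dangle_energy("dri", pt_pair, None, code[pos0], params)


def _loop_dangle_options(code, loop: Loop, params):
    """Per-run dangle candidate energies for an exterior/multiloop loop.

    Yields (positions_tuple, option_energies) where option_energies maps
    'd'/'b' to centi-kcal values for the run's boundary bases.
    """
    i, j = (None, None) if loop.closing is None else loop.closing
    out = []
    for (start, end) in loop.runs:
        cands = []  # (pos, sym, energy)
        left_stem = None
        right_stem = None
        # helix ending just left of the run?
        p0 = start - 2  # 0-based position left of run
        if loop.closing is not None and start - 1 == i:
            left_stem = ("closing", (i, j))
        else:
            for (a, b) in loop.children:
                if b == start - 1:
                    left_stem = ("stem", (a, b))
                    break
        if loop.closing is not None and end + 1 == j:
            right_stem = ("closing", (i, j))
        else:
            for (a, b) in loop.children:
                if a == end + 1:
                    right_stem = ("stem", (a, b))
                    break
        if left_stem:
            kind, (a, b) = left_stem
            pr = (code[a - 1], code[b - 1])
            if kind == "stem":
                e = en.dangle_energy("dr", pr, None, code[start - 1], params)
            else:
                e = en.dangle_energy("dli", pr, code[start - 1], None, params)
            cands.append((start, "d", e))
        if right_stem:
            kind, (a, b) = right_stem
            pr = (code[a - 1], code[b - 1])
            if kind == "stem":
                e = en.dangle_energy("dl", pr, code[end - 1], None, params)
            else:
                e = en.dangle_energy("dri", pr, None, code[end - 1], params)
            cands.append((end, "b", e))
        out.append(((start, end), cands))
    return out


def _core_energy(code, s: SecondaryStructure, params) -> int:
    """Model-independent loop/stack energy sum (the NoDangle energy)."""
    total = 0
    for loop in s.loops():
        if loop.kind == "exterior":
            for (a, b) in loop.children:
                total += en.termau_energy((code[a - 1], code[b - 1]), params)
        elif loop.kind == "stack":
            i, j = loop.closing
            ci, cj = loop.children[0]
            total += en.sr_energy(
                (code[i - 1], code[j - 1]), (code[ci - 1], code[cj - 1]), params
            )
        elif loop.kind == "hairpin":
            i, j = loop.closing
            total += en.hairpin_energy(
                (code[i - 1], code[j - 1]),
                tuple(code[i : j - 1]),
                params,
            )
        elif loop.kind in ("bulge_left", "bulge_right"):
            i, j = loop.closing
            ci, cj = loop.children[0]
            (rs, re_) = loop.runs[0]
            total += en.bulge_energy(
                "left" if loop.kind == "bulge_left" else "right",
                (code[i - 1], code[j - 1]),
                (code[ci - 1], code[cj - 1]),
                tuple(code[rs - 1 : re_]),
                params,
            )
        elif loop.kind == "internal":
            i, j = loop.closing
            ci, cj = loop.children[0]
            total += en.internal_energy(
                (code[i - 1], code[j - 1]),
                (code[ci - 1], code[cj - 1]),
                tuple(code[i : ci - 1]),
                tuple(code[cj : j - 1]),
                params,
            )
        else:  # multiloop
            i, j = loop.closing
            total += en.multiloop_terms(len(loop.children), params)
            total += en.termau_energy((code[i - 1], code[j - 1]), params)
            for (a, b) in loop.children:
                total += en.termau_energy((code[a - 1], code[b - 1]), params)
            total += params.ss_unpaired * loop.size
    return total


def _overdangle_terms(code, s: SecondaryStructure, params) -> int:
    """OverDangle adds both-side dangle terms for every exterior/multiloop
    helix end, whether or not the neighboring base is free."""
    n = len(code)
    total = 0
    for loop in s.loops():
        if loop.kind == "exterior":
            for (a, b) in loop.children:
                pr = (code[a - 1], code[b - 1])
                if a >= 2:
                    total += en.dangle_energy("dl", pr, code[a - 2], None, params)
                if b <= n - 1:
                    total += en.dangle_energy("dr", pr, None, code[b], params)
        elif loop.kind == "multiloop":
            i, j = loop.closing
            pr = (code[i - 1], code[j - 1])
            total += en.dangle_energy("ml_mismatch", pr, code[i], code[j - 2], params)
            for (a, b) in loop.children:
                spr = (code[a - 1], code[b - 1])
                total += en.dangle_energy("dl", spr, code[a - 2], None, params)
                total += en.dangle_energy("dr", spr, None, code[b], params)
    return total


def _optimal_dangle_terms(code, s: SecondaryStructure, params) -> int:
    """Optimal-dangle contribution (MicroState optimum == MacroState local
    resolution): per unpaired run, the best of the available assignments
    including no dangle at all."""
    total = 0
    for loop in s.loops():
        if loop.kind not in ("exterior", "multiloop"):
            continue
        for (_, cands) in _loop_dangle_options(code, loop, params):
            if not cands:
                continue
            positions = {pos for pos, _, _ in cands}
            if len(positions) == 1 and len(cands) == 2:
                # one shared base between two helix ends: pick one side or none
                total += min(0, cands[0][2], cands[1][2])
            else:
                for (_, _, e) in cands:
                    total += min(0, e)
    return total


def evaluate_structure_energy(seq, s, model: str, params: EnergyParameters):
    """Free energy (kcal/mol) of structure ``s`` for ``seq`` under ``model``.

    ``s`` may be a :class:`SecondaryStructure` or, for MicroState, a
    :class:`MicroStructure` with an explicit dangle assignment.  Given a
    plain structure under MicroState/MacroState, the optimum over its
    dangle variants is returned.
    """
    _check_model(model)
    seq = as_sequence(seq)
    code = seq.code
    micro = None
    if isinstance(s, MicroStructure):
        micro = s
        s = s.base
    if s.length != len(code):
        raise StructureError("sequence/structure length mismatch")
    for i, j in s.pairs:
        if pair_type(code[i - 1], code[j - 1]) == 0:
            raise StructureError(
                f"pair ({i},{j}) = {seq.seq[i - 1]}:{seq.seq[j - 1]} is not canonical"
            )
    total = _core_energy(code, s, params)
    if model == "NoDangle":
        pass
    elif model == "OverDangle":
        total += _overdangle_terms(code, s, params)
    elif micro is not None:
        partner = s.partner()
        for pos, sym in micro.dangles:
            total += _dangle_term(code, partner, pos - 1, sym, params)
    else:  # MicroState / MacroState optimum over dangle assignments
        total += _optimal_dangle_terms(code, s, params)
    return en.to_kcal(total)


def rescore_structures(seq, structures, from_model, to_model, params):
    """Re-evaluate ``structures`` under ``to_model`` and sort ascending.

    The sort is stable, so ties keep the incoming (``from_model``) order.
    Returns a list of ``(structure, energy_kcal)``.
    """
    _check_model(from_model)
    _check_model(to_model)
    scored = [
        (s, evaluate_structure_energy(seq, s, to_model, params))
        for s in structures
    ]
    scored.sort(key=lambda t: t[1])
    return scored


def macrostate_ensemble_energy(seq, s: SecondaryStructure, params) -> float:
    """Per-structure energy (kcal/mol) under the MacroState ensemble
    (partition-function) dangle resolution.

    Exterior-loop dangles are resolved at the per-structure optimum.
    Inside a multiloop, each run between two stems -- or between the last
    stem and the closing pair -- contributes at most one stabilizing
    dangle (the best of no dangle / the left stem's 3' dangle / the right
    stem's 5' dangle), while the run following the closing pair keeps its
    two boundary dangles independent.  This is the energy whose Boltzmann
    weight the MacroState partition function assigns to the structure;
    the MacroState MFE algebra uses the per-structure optimum instead.
    """
    seq = as_sequence(seq)
    code = seq.code
    total = _core_energy(code, s, params)
    for loop in s.loops():
        if loop.kind not in ("exterior", "multiloop"):
            continue
        ml = loop.kind == "multiloop"
        i_cl, j_cl = loop.closing if loop.closing else (None, None)
        for ((rs, re_), cands) in _loop_dangle_options(code, loop, params):
            if not cands:
                continue
            es = [e for _, _, e in cands]
            positions = {p for p, _, _ in cands}
            if len(positions) == 1:
                total += min(0, *es)
            elif ml and not (rs - 1 == i_cl):
                total += min(0, *es)  # one dangle per stem boundary
            else:
                total += sum(min(0, e) for e in es)
    return en.to_kcal(total)
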