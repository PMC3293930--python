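"""Evaluation algebras for the grammar walkers.

Following the grammar-times-algebra methodology, each analysis is one
algebra: the same folding-space recurrences are run with different value
domains and a different choice function ``h``:

* :class:`CountAlgebra` -- exact integer folding-space size;
* :class:`CandidateAlgebra` -- (energy, structure) lists for MFE
  (``delta=0``), suboptimal enumeration (finite ``delta``) or complete
  enumeration (``delta=None``);
* :class:`PartitionAlgebra` -- Boltzmann-weighted sums (the partition
  function);
* :class:`ShapeAlgebra` -- per-shape Boltzmann mass with the minimum-energy
  representative (shrep) of every shape class.

Energies are integer centi-kcal/mol throughout; Boltzmann weights use
``exp(-e / (100 RT))``.
"""

from __future__ import annotations

import math

from .shapes import _merge


class CountAlgebra:
    """Counts derivations (= folding-space members)."""

    needs_energy = False

    def h(self, vals):
        return sum(vals)

    def one(self):
        return 1

    def ad(self, v, e):
        return v

    def ssl(self, v, k):
        return v

    def ssr(self, v, k):
        return v

    def dang(self, v, sym, side):
        return v

    def hl(self, e, size):
        return 1

    def sr(self, v, e):
        return v

    def bl(self, v, e, k):
        return v

    def br(self, v, e, k):
        return v

    def il(self, v, e, k5, k3):
        return v

    def ml(self, v, e, pre="", post=""):
        return v

    def cat(self, v1, v2):
        return v1 * v2


class PartitionAlgebra:
    """Boltzmann-weighted sum over the folding space."""

    needs_energy = True

    def __init__(self, rt_kcal: float):
        self.beta = 1.0 / (100.0 * rt_kcal)

    def w(self, e):
        return math.exp(-e * self.beta)

    def h(self, vals):
        return sum(vals)

    def one(self):
        return 1.0

    def ad(self, v, e):
        return v * self.w(e) if e else v

    def ssl(self, v, k):
        return v

    def ssr(self, v, k):
        return v

    def dang(self, v, sym, side):
        return v

    def hl(self, e, size):
        return self.w(e)

    def sr(self, v, e):
        return v * self.w(e)

    def bl(self, v, e, k):
        return v * self.w(e)

    def br(self, v, e, k):
        return v * self.w(e)

    def il(self, v, e, k5, k3):
        return v * self.w(e)

    def ml(self, v, e, pre="", post=""):
        return v * self.w(e)

    def cat(self, v1, v2):
        return v1 * v2


class CandidateAlgebra:
    """Explicit (energy, structure-string) candidate lists.

    ``delta`` is the local pruning band in centi-kcal/mol relative to the
    cell optimum: 0 keeps all co-optimal candidates (MFE), ``None`` keeps
    everything (complete enumeration).  Local pruning at ``delta`` is safe
    for global enumeration up to ``delta`` because replacing any
    substructure by the locally optimal one can only lower the total
    energy.
    """

    needs_energy = True

    def __init__(self, delta=0):
        self.delta = delta

    def h(self, vals):
        merged = []
        for v in vals:
            merged.extend(v)
        if not merged:
            return merged
        if self.delta is None:
            return merged
        best = min(e for e, _ in merged)
        return [c for c in merged if c[0] <= best + self.delta]

    def one(self):
        return [(0, "")]

    def ad(self, v, e):
        if not e:
            return v
        return [(ce + e, s) for ce, s in v]

    def ssl(self, v, k):
        d = "." * k
        return [(e, d + s) for e, s in v]

    def ssr(self, v, k):
        d = "." * k
        return [(e, s + d) for e, s in v]

    def dang(self, v, sym, side):
        if side == "L":
            return [(e, sym + s) for e, s in v]
        return [(e, s + sym) for e, s in v]

    def hl(self, e, size):
        return [(e, "((" + "." * size + "))")]

    def sr(self, v, e):
        return [(ce + e, "(" + s + ")") for ce, s in v]

    def bl(self, v, e, k):
        d = "." * k
        return [(ce + e, "((" + d + s + "))") for ce, s in v]

    def br(self, v, e, k):
        d = "." * k
        return [(ce + e, "((" + s + d + "))") for ce, s in v]

    def il(self, v, e, k5, k3):
        d5, d3 = "." * k5, "." * k3
        return [(ce + e, "((" + d5 + s + d3 + "))") for ce, s in v]

    def ml(self, v, e, pre="", post=""):
        return [(ce + e, "((" + pre + s + post + "))") for ce, s in v]

    def cat(self, v1, v2):
        return [(e1 + e2, s1 + s2) for e1, s1 in v1 for e2, s2 in v2]


class ShapeAlgebra:
    """Per-shape Boltzmann mass, minimum energy and shrep string.

    Values are dicts ``shape_fragment -> (mass, best_e, best_struct)``.
    """

    needs_energy = True

    def __init__(self, level: int, rt_kcal: float):
        self.level = level
        self.beta = 1.0 / (100.0 * rt_kcal)

    def w(self, e):
        return math.exp(-e * self.beta)

    # -- helpers -----------------------------------------------------------

    def _map(self, v, shape_fn, e, str_fn):
        we = self.w(e) if e else 1.0
        out = {}
        for shp, (q, be, bs) in v.items():
            nshp = shape_fn(shp)
            ent = (q * we, be + e, str_fn(bs))
            old = out.get(nshp)
            if old is None:
                out[nshp] = ent
            else:
                out[nshp] = (
                    old[0] + ent[0],
                    *((ent[1], ent[2]) if ent[1] < old[1] else (old[1], old[2])),
                )
        return out

    def h(self, vals):
        out = {}
        for v in vals:
            for shp, (q, be, bs) in v.items():
                old = out.get(shp)
                if old is None:
                    out[shp] = (q, be, bs)
                else:
                    out[shp] = (
                        old[0] + q,
                        *((be, bs) if be < old[1] else (old[1], old[2])),
                    )
        return out

    def one(self):
        return {"": (1.0, 0, "")}

    def ad(self, v, e):
        if not e:
            return v
        return self._map(v, lambda s: s, e, lambda b: b)

    def _us(self, frag):
        """Underscore for an unpaired stretch (level 1 only)."""
        return "_" if self.level == 1 else ""

    def ssl(self, v, k):
        d = "." * k
        return self._map(v, lambda s: _merge([self._us(s), s]), 0, lambda b: d + b)

    def ssr(self, v, k):
        d = "." * k
        return self._map(v, lambda s: _merge([s, self._us(s)]), 0, lambda b: b + d)

    def dang(self, v, sym, side):
        if side == "L":
            return self._map(
                v, lambda s: _merge([self._us(s), s]), 0, lambda b: sym + b
            )
        return self._map(v, lambda s: _merge([s, self._us(s)]), 0, lambda b: b + sym)

    def hl(self, e, size):
        shp = "[_]" if self.level == 1 else "[]"
        return {shp: (self.w(e), e, "((" + "." * size + "))")}

    def sr(self, v, e):
        return self._map(v, lambda s: s, e, lambda b: "(" + b + ")")

    def bl(self, v, e, k):
        d = "." * k
        lv = self.level
        if lv >= 4:
            fn = lambda s: s
        elif lv == 3:
            fn = lambda s: "[" + s + "]"
        else:
            fn = lambda s: "[_" + s + "]"
        return self._map(v, fn, e, lambda b: "((" + d + b + "))")

    def br(self, v, e, k):
        d = "." * k
        lv = self.level
        if lv >= 4:
            fn = lambda s: s
        elif lv == 3:
            fn = lambda s: "[" + s + "]"
        else:
            fn = lambda s: "[" + s + "_]"
        return self._map(v, fn, e, lambda b: "((" + b + d + "))")

    def il(self, v, e, k5, k3):
        d5, d3 = "." * k5, "." * k3
        lv = self.level
        if lv == 5:
            fn = lambda s: s
        elif lv >= 3:
            fn = lambda s: "[" + s + "]"
        else:
            fn = lambda s: "[_" + s + "_]"
        return self._map(v, fn, e, lambda b: "((" + d5 + b + d3 + "))")

    def ml(self, v, e, pre="", post=""):
        lv = self.level
        upre = "_" if (pre and lv == 1) else ""
        upost = "_" if (post and lv == 1) else ""
        fn = lambda s: "[" + _merge([upre, s, upost]) + "]"
        return self._map(v, fn, e, lambda b: "((" + pre + b + post + "))")

    def cat(self, v1, v2):
        out = {}
        for s1, (q1, e1, b1) in v1.items():
            for s2, (q2, e2, b2) in v2.items():
                shp = _merge([s1, s2])
                ent = (q1 * q2, e1 + e2, b1 + b2)
                old = out.get(shp)
                if old is None:
                    out[shp] = ent
                else:
                    out[shp] = (
                        old[0] + ent[0],
                        *((ent[1], ent[2]) if ent[1] < old[1] else (old[1], old[2])),
                    )
        return out
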