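"""Dynamic-programming walkers for the four folding-space grammars.

Each walker runs one grammar bottom-up over all subwords and evaluates it
under a pluggable algebra (see :mod:`foldspace.algebras`).  The walkers
compute all energies themselves (integer centi-kcal/mol) and hand them to
the algebra, so an algebra is purely a value domain.

Shared filters: canonical pairs only, ``stackpairing`` (every closed
substructure starts with two stacked pairs, i.e. no lonely pairs), hairpin
loops >= 3 nt, bulge/internal strands <= 30 nt.

Positions are 0-based here; the public modules convert at the boundary.

The MacroState walker additionally classifies cell values of
helix-boundary nonterminals by the partner base of the boundary helix,
which is what makes its exact one-weight-per-structure partition function
possible: the dangle energy of a base onto a neighboring helix depends on
that helix's far end, which varies over the ensemble of a cell.
"""

from __future__ import annotations

from . import energy as en
from .params import REVERSE_TYPE, pair_type

MAXLOOP = 30


class Ctx:
    """Per-(sequence, parameters) energy helper with a pair-type matrix."""

    def __init__(self, code, params):
        self.code = code
        self.params = params
        self.n = len(code)
        n = self.n
        self.pt = pt = [[0] * n for _ in range(n)]
        for i in range(n):
            ci = code[i]
            row = pt[i]
            for j in range(i + 1, n):
                row[j] = pair_type(ci, code[j])
        self.min_hairpin = 3

    # all helpers return centi-kcal ints; positions are 0-based
    def stack_e(self, i, j):
        return self.params.stack_table[self.pt[i][j] - 1][
            REVERSE_TYPE[self.pt[i + 1][j - 1]] - 1
        ]

    def hairpin_e(self, i, j):
        c = self.code
        return en.hairpin_energy((c[i], c[j]), c[i + 1 : j], self.params)

    def bulge_e(self, i, j, p, q):
        c = self.code
        if q == j - 1:  # bulge on the left
            return en.bulge_energy(
                "left", (c[i], c[j]), (c[p], c[q]), c[i + 1 : p], self.params
            )
        return en.bulge_energy(
            "right", (c[i], c[j]), (c[p], c[q]), c[q + 1 : j], self.params
        )

    def internal_e(self, i, j, p, q):
        c = self.code
        return en.internal_energy(
            (c[i], c[j]), (c[p], c[q]), c[i + 1 : p], c[q + 1 : j], self.params
        )

    def termau(self, i, j):
        return self.params.terminal_au if self.pt[i][j] > 2 else 0

    def dl(self, i, j, b):
        return self.params.dangle5[self.pt[i][j] - 1][self.code[b] + 1]

    def dr(self, i, j, b):
        return self.params.dangle3[self.pt[i][j] - 1][self.code[b] + 1]

    def dli(self, i, j, b):
        return self.params.dangle3[REVERSE_TYPE[self.pt[i][j]] - 1][self.code[b] + 1]

    def dri(self, i, j, b):
        return self.params.dangle5[REVERSE_TYPE[self.pt[i][j]] - 1][self.code[b] + 1]

    def dl_class(self, start, partner_base, b):
        """5' dangle onto a helix starting at ``start`` whose far-end base is
        ``partner_base`` (ensemble-classified)."""
        t = pair_type(self.code[start], partner_base)
        return self.params.dangle5[t - 1][self.code[b] + 1]

    def dr_class(self, partner_base, end, b):
        t = pair_type(partner_base, self.code[end])
        return self.params.dangle3[t - 1][self.code[b] + 1]


def _closed_candidates(ctx, alg, closed, i, j, ml_candidates):
    """The sr/hl/bl/br/il alternatives shared by all grammars.

    ``ml_candidates(i, j)`` yields the grammar-specific multiloop values.
    """
    pt = ctx.pt
    cands = []
    inner = closed.get((i + 1, j - 1))
    if inner is not None:
        cands.append(alg.sr(inner, ctx.stack_e(i, j)))
    size = j - i - 3
    if size >= ctx.min_hairpin:
        cands.append(alg.hl(ctx.stack_e(i, j) + ctx.hairpin_e(i + 1, j - 1), size))
    # left bulge: region i+2 .. i+1+lb
    for lb in range(1, min(MAXLOOP, j - i - 7) + 1):
        v = closed.get((i + 2 + lb, j - 2))
        if v is not None:
            e = ctx.stack_e(i, j) + ctx.bulge_e(i + 1, j - 1, i + 2 + lb, j - 2)
            cands.append(alg.bl(v, e, lb))
    for rb in range(1, min(MAXLOOP, j - i - 7) + 1):
        v = closed.get((i + 2, j - 2 - rb))
        if v is not None:
            e = ctx.stack_e(i, j) + ctx.bulge_e(i + 1, j - 1, i + 2, j - 2 - rb)
            cands.append(alg.br(v, e, rb))
    for l5 in range(1, min(MAXLOOP, j - i - 8) + 1):
        p = i + 2 + l5
        for l3 in range(1, min(MAXLOOP, j - i - 8 - l5) + 1):
            q = j - 2 - l3
            v = closed.get((p, q))
            if v is not None:
                e = ctx.stack_e(i, j) + ctx.internal_e(i + 1, j - 1, p, q)
                cands.append(alg.il(v, e, l5, l3))
    cands.extend(ml_candidates(i, j))
    return cands


def _pairable(ctx, i, j):
    return j - i >= 6 and ctx.pt[i][j] and ctx.pt[i + 1][j - 1]


# ---------------------------------------------------------------------------
# NoDangle / OverDangle (one grammar, two energy wirings)


def run_shared(ctx, alg, overdangle: bool):
    n = ctx.n
    closed = {}
    mlc = {}
    mlc1 = {}
    off = ctx.params.ml_offset
    br_ = ctx.params.ml_branch

    def drem(i, j, v):
        e = ctx.termau(i, j)
        if overdangle:
            if i > 0:
                e += ctx.dl(i, j, i - 1)
            if j + 1 < n:
                e += ctx.dr(i, j, j + 1)
        return alg.ad(v, e)

    def ml_cands(i, j):
        v = mlc.get((i + 2, j - 2))
        if v is None:
            return []
        e = ctx.stack_e(i, j) + ctx.termau(i + 1, j - 1) + off + br_
        if overdangle:
            e += ctx.dli(i + 1, j - 1, i + 2) + ctx.dri(i + 1, j - 1, j - 2)
        return [alg.ml(v, e)]

    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if _pairable(ctx, i, j):
                cands = _closed_candidates(ctx, alg, closed, i, j, ml_cands)
                if cands:
                    closed[(i, j)] = alg.h(cands)
            # ml_comps1
            cands = []
            up = mlc1.get((i + 1, j))
            if up is not None:
                cands.append(alg.ssl(up, 1))
            for k in range(i + 1, j + 1):
                cv = closed.get((i, k))
                if cv is None:
                    continue
                comp = alg.ad(drem(i, k, cv), br_)
                if k == j:
                    cands.append(comp)
                else:
                    rest = mlc1.get((k + 1, j))
                    if rest is not None:
                        cands.append(alg.cat(comp, rest))
                    cands.append(alg.ssr(comp, j - k))
            if cands:
                mlc1[(i, j)] = alg.h(cands)
            # ml_comps
            cands = []
            up = mlc.get((i + 1, j))
            if up is not None:
                cands.append(alg.ssl(up, 1))
            for k in range(i + 1, j):
                cv = closed.get((i, k))
                if cv is None:
                    continue
                rest = mlc1.get((k + 1, j))
                if rest is not None:
                    cands.append(alg.cat(alg.ad(drem(i, k, cv), br_), rest))
            if cands:
                mlc[(i, j)] = alg.h(cands)

    struct = [None] * (n + 1)
    struct[n] = alg.one()
    for i in range(n - 1, -1, -1):
        cands = [alg.ssl(struct[i + 1], 1)]
        for j in range(i + 6, n):
            cv = closed.get((i, j))
            if cv is not None:
                cands.append(alg.cat(drem(i, j, cv), struct[j + 1]))
        struct[i] = alg.h(cands)
    return struct[0]


# ---------------------------------------------------------------------------
# MicroState


def run_microstate(ctx, alg):
    n = ctx.n
    closed = {}
    dang = {}
    mlc = {}
    mlc1 = {}
    off = ctx.params.ml_offset
    br_ = ctx.params.ml_branch

    def ml_cands(i, j):
        out = []
        base_e = ctx.stack_e(i, j) + ctx.termau(i + 1, j - 1) + off + br_
        v = mlc.get((i + 2, j - 2))
        if v is not None:
            out.append(alg.ml(v, base_e))
        v = mlc.get((i + 3, j - 2))
        if v is not None:
            out.append(alg.ml(v, base_e + ctx.dli(i + 1, j - 1, i + 2), pre="d"))
        v = mlc.get((i + 2, j - 3))
        if v is not None:
            out.append(alg.ml(v, base_e + ctx.dri(i + 1, j - 1, j - 2), post="b"))
        v = mlc.get((i + 3, j - 3))
        if v is not None:
            e = base_e + ctx.dli(i + 1, j - 1, i + 2) + ctx.dri(i + 1, j - 1, j - 2)
            out.append(alg.ml(v, e, pre="d", post="b"))
        return out

    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if _pairable(ctx, i, j):
                cands = _closed_candidates(ctx, alg, closed, i, j, ml_cands)
                if cands:
                    closed[(i, j)] = alg.h(cands)
            # dangle: the four helix-wrapper alternatives on span (i, j)
            cands = []
            v = closed.get((i, j))
            if v is not None:
                cands.append(alg.ad(v, ctx.termau(i, j)))
            v = closed.get((i + 1, j))
            if v is not None:
                e = ctx.termau(i + 1, j) + ctx.dl(i + 1, j, i)
                cands.append(alg.ad(alg.dang(v, "b", "L"), e))
            v = closed.get((i, j - 1))
            if v is not None:
                e = ctx.termau(i, j - 1) + ctx.dr(i, j - 1, j)
                cands.append(alg.ad(alg.dang(v, "d", "R"), e))
            v = closed.get((i + 1, j - 1))
            if v is not None:
                e = (
                    ctx.termau(i + 1, j - 1)
                    + ctx.dl(i + 1, j - 1, i)
                    + ctx.dr(i + 1, j - 1, j)
                )
                cands.append(alg.ad(alg.dang(alg.dang(v, "b", "L"), "d", "R"), e))
            if cands:
                dang[(i, j)] = alg.h(cands)
            # ml_comps1 / ml_comps over dangle components
            cands = []
            up = mlc1.get((i + 1, j))
            if up is not None:
                cands.append(alg.ssl(up, 1))
            for k in range(i + 1, j + 1):
                dv = dang.get((i, k))
                if dv is None:
                    continue
                comp = alg.ad(dv, br_)
                if k == j:
                    cands.append(comp)
                else:
                    rest = mlc1.get((k + 1, j))
                    if rest is not None:
                        cands.append(alg.cat(comp, rest))
                    cands.append(alg.ssr(comp, j - k))
            if cands:
                mlc1[(i, j)] = alg.h(cands)
            cands = []
            up = mlc.get((i + 1, j))
            if up is not None:
                cands.append(alg.ssl(up, 1))
            for k in range(i + 1, j):
                dv = dang.get((i, k))
                if dv is None:
                    continue
                rest = mlc1.get((k + 1, j))
                if rest is not None:
                    cands.append(alg.cat(alg.ad(dv, br_), rest))
            if cands:
                mlc[(i, j)] = alg.h(cands)

    struct = [None] * (n + 1)
    struct[n] = alg.one()
    for i in range(n - 1, -1, -1):
        cands = [alg.ssl(struct[i + 1], 1)]
        for j in range(i + 5, n):
            dv = dang.get((i, j))
            if dv is not None:
                cands.append(alg.cat(dv, struct[j + 1]))
        struct[i] = alg.h(cands)
    return struct[0]


# ---------------------------------------------------------------------------
# MacroState


def _merge_into(bucket, key, val):
    bucket.setdefault(key, []).append(val)


def _finish(alg, bucket):
    return {k: alg.h(vs) for k, vs in bucket.items()} or None


def _merge_all(alg, table_val):
    if table_val is None:
        return None
    return alg.h(list(table_val.values()))


def run_macrostate(ctx, alg):
    n = ctx.n
    code = ctx.code
    closed = {}
    # classified interior tables: value = dict class_key -> algebra value
    mc1 = {}
    mc2 = {}
    mc3 = {}
    mc4 = {}
    mcadd1 = {}
    mcadd2 = {}
    mcadd3 = {}
    mcadd4 = {}
    block_dl = {}
    block_dlr = {}
    off = ctx.params.ml_offset
    brch = ctx.params.ml_branch

    # helix wrappers (span-exact, so both helix ends are known positions)
    def nodg(i, j):
        v = closed.get((i, j))
        if v is None:
            return None
        return alg.ad(v, ctx.termau(i, j))

    def edgl(i, j):
        v = closed.get((i + 1, j))
        if v is None:
            return None
        e = ctx.termau(i + 1, j) + min(0, ctx.dl(i + 1, j, i))
        return alg.ad(alg.dang(v, ".", "L"), e)

    def edgr(i, j):
        v = closed.get((i, j - 1))
        if v is None:
            return None
        e = ctx.termau(i, j - 1) + min(0, ctx.dr(i, j - 1, j))
        return alg.ad(alg.dang(v, ".", "R"), e)

    def edglr(i, j):
        v = closed.get((i + 1, j - 1))
        if v is None:
            return None
        e = (
            ctx.termau(i + 1, j - 1)
            + min(0, ctx.dl(i + 1, j - 1, i))
            + min(0, ctx.dr(i + 1, j - 1, j))
        )
        return alg.ad(alg.dang(alg.dang(v, ".", "L"), ".", "R"), e)

    def ml_cands(i, j):
        """The nine multiloop alternatives of the MacroState grammar."""
        out = []
        a, b = i + 2, j - 2  # interior bounds, inclusive
        base_e = ctx.stack_e(i, j) + ctx.termau(i + 1, j - 1) + off + brch
        dli_e = ctx.dli(i + 1, j - 1, a)
        dri_e = ctx.dri(i + 1, j - 1, b)
        t = mc2.get((a, b))  # ml
        if t:
            out.append(alg.ml(_merge_all(alg, t), base_e))
        t = mc1.get((a + 1, b))  # mldl
        if t:
            out.append(alg.ml(_merge_all(alg, t), base_e + min(0, dli_e), pre="."))
        t = mc2.get((a + 1, b))  # mladl
        if t:
            for (cl, cr), v in t.items():
                e = base_e + min(0, dli_e, ctx.dl_class(a + 1, cl, a))
                out.append(alg.ml(v, e, pre="."))
        t = mc3.get((a, b - 1))  # mldr
        if t:
            out.append(alg.ml(_merge_all(alg, t), base_e + min(0, dri_e), post="."))
        t = mc2.get((a, b - 1))  # mladr
        if t:
            for (cl, cr), v in t.items():
                e = base_e + min(0, dri_e, ctx.dr_class(cr, b - 1, b))
                out.append(alg.ml(v, e, post="."))
        t = mc4.get((a + 1, b - 1))  # mldlr
        if t:
            e = base_e + min(0, dli_e) + min(0, dri_e)
            out.append(alg.ml(_merge_all(alg, t), e, pre=".", post="."))
        t = mc2.get((a + 1, b - 1))  # mladlr
        if t:
            for (cl, cr), v in t.items():
                e = (
                    base_e
                    + min(0, dli_e, ctx.dl_class(a + 1, cl, a))
                    + min(0, dri_e, ctx.dr_class(cr, b - 1, b))
                )
                out.append(alg.ml(v, e, pre=".", post="."))
        t = mc1.get((a + 1, b - 1))  # mldladr
        if t:
            for cr, v in t.items():
                e = (
                    base_e
                    + min(0, dli_e)
                    + min(0, dri_e, ctx.dr_class(cr, b - 1, b))
                )
                out.append(alg.ml(v, e, pre=".", post="."))
        t = mc3.get((a + 1, b - 1))  # mladldr
        if t:
            for cl, v in t.items():
                e = (
                    base_e
                    + min(0, dli_e, ctx.dl_class(a + 1, cl, a))
                    + min(0, dri_e)
                )
                out.append(alg.ml(v, e, pre=".", post="."))
        return out

    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if _pairable(ctx, i, j):
                cands = _closed_candidates(ctx, alg, closed, i, j, ml_cands)
                if cands:
                    closed[(i, j)] = alg.h(cands)
            # block_dl / block_dlr: [region] + dangling base + helix
            bucket = {}
            v = edgl(i, j)
            if v is not None:  # incl(edgl)
                _merge_into(bucket, code[i + 1], alg.ad(v, brch))
            for k in range(i + 1, j):  # ssadd(region i..k-1, edgl(k, j))
                v = edgl(k, j)
                if v is not None:
                    _merge_into(
                        bucket, code[k + 1], alg.ad(alg.ssl(v, k - i), brch)
                    )
            bv = _finish(alg, bucket)
            if bv:
                block_dl[(i, j)] = bv
            bucket = {}
            v = edglr(i, j)
            if v is not None:
                _merge_into(bucket, None, alg.ad(v, brch))
            for k in range(i + 1, j):
                v = edglr(k, j)
                if v is not None:
                    _merge_into(bucket, None, alg.ad(alg.ssl(v, k - i), brch))
            bv = _finish(alg, bucket)
            if bv:
                block_dlr[(i, j)] = bv

            # mcadd1 (starts with helix, ends with helix)
            bucket = {}
            v = nodg(i, j)
            if v is not None:  # incl
                _merge_into(bucket, (code[j], code[i]), alg.ad(v, brch))
            for k in range(i + 1, j):
                first = nodg(i, k)
                if first is not None:
                    fi = alg.ad(first, brch)
                    rest = mcadd1.get((k + 1, j))
                    if rest:
                        for (cl2, cr2), v2 in rest.items():
                            _merge_into(bucket, (code[k], cr2), alg.cat(fi, v2))
                    if k + 2 <= j:  # acomb: shared base at k+1
                        rest = mcadd1.get((k + 2, j))
                        if rest:
                            dr_e = ctx.dr(i, k, k + 1)
                            for (cl2, cr2), v2 in rest.items():
                                e = min(
                                    0, dr_e, ctx.dl_class(k + 2, cl2, k + 1)
                                )
                                val = alg.cat(
                                    alg.ad(alg.dang(fi, ".", "R"), e), v2
                                )
                                _merge_into(bucket, (code[k], cr2), val)
                ev = edgr(i, k)
                if ev is not None:
                    fi = alg.ad(ev, brch)
                    rest = mcadd2.get((k + 1, j))
                    if rest:
                        for cr2, v2 in rest.items():
                            _merge_into(bucket, (code[k - 1], cr2), alg.cat(fi, v2))
            bv = _finish(alg, bucket)
            if bv:
                mcadd1[(i, j)] = bv
            # mc2 = mcadd1 without the single-component form
            bucket = {}
            for k in range(i + 1, j):
                first = nodg(i, k)
                if first is not None:
                    fi = alg.ad(first, brch)
                    rest = mcadd1.get((k + 1, j))
                    if rest:
                        for (cl2, cr2), v2 in rest.items():
                            _merge_into(bucket, (code[k], cr2), alg.cat(fi, v2))
                    if k + 2 <= j:
                        rest = mcadd1.get((k + 2, j))
                        if rest:
                            dr_e = ctx.dr(i, k, k + 1)
                            for (cl2, cr2), v2 in rest.items():
                                e = min(0, dr_e, ctx.dl_class(k + 2, cl2, k + 1))
                                val = alg.cat(
                                    alg.ad(alg.dang(fi, ".", "R"), e), v2
                                )
                                _merge_into(bucket, (code[k], cr2), val)
                ev = edgr(i, k)
                if ev is not None:
                    fi = alg.ad(ev, brch)
                    rest = mcadd2.get((k + 1, j))
                    if rest:
                        for cr2, v2 in rest.items():
                            _merge_into(bucket, (code[k - 1], cr2), alg.cat(fi, v2))
            bv = _finish(alg, bucket)
            if bv:
                mc2[(i, j)] = bv

            # mcadd2 (unpaired prefix, ends with helix)
            bucket = {}
            bd = block_dl.get((i, j))
            if bd:  # terminal single block
                for cb, v in bd.items():
                    _merge_into(bucket, cb, v)
            for k in range(i + 1, j):
                bd = block_dl.get((i, k))
                if bd:
                    rest = mcadd1.get((k + 1, j))
                    if rest:
                        for cb, vb in bd.items():
                            for (cl2, cr2), v2 in rest.items():
                                _merge_into(bucket, cr2, alg.cat(vb, v2))
                    if k + 2 <= j:
                        rest = mcadd1.get((k + 2, j))
                        if rest:
                            for cb, vb in bd.items():
                                dr_e = ctx.dr_class(cb, k, k + 1)
                                for (cl2, cr2), v2 in rest.items():
                                    e = min(
                                        0, dr_e, ctx.dl_class(k + 2, cl2, k + 1)
                                    )
                                    val = alg.cat(
                                        alg.ad(alg.dang(vb, ".", "R"), e), v2
                                    )
                                    _merge_into(bucket, cr2, val)
                bdr = block_dlr.get((i, k))
                if bdr:
                    rest = mcadd2.get((k + 1, j))
                    if rest:
                        for _, vb in bdr.items():
                            for cr2, v2 in rest.items():
                                _merge_into(bucket, cr2, alg.cat(vb, v2))
            bv = _finish(alg, bucket)
            if bv:
                mcadd2[(i, j)] = bv
            # mc1 = mcadd2 without the terminal single block
            bucket = {}
            for k in range(i + 1, j):
                bd = block_dl.get((i, k))
                if bd:
                    rest = mcadd1.get((k + 1, j))
                    if rest:
                        for cb, vb in bd.items():
                            for (cl2, cr2), v2 in rest.items():
                                _merge_into(bucket, cr2, alg.cat(vb, v2))
                    if k + 2 <= j:
                        rest = mcadd1.get((k + 2, j))
                        if rest:
                            for cb, vb in bd.items():
                                dr_e = ctx.dr_class(cb, k, k + 1)
                                for (cl2, cr2), v2 in rest.items():
                                    e = min(
                                        0, dr_e, ctx.dl_class(k + 2, cl2, k + 1)
                                    )
                                    val = alg.cat(
                                        alg.ad(alg.dang(vb, ".", "R"), e), v2
                                    )
                                    _merge_into(bucket, cr2, val)
                bdr = block_dlr.get((i, k))
                if bdr:
                    rest = mcadd2.get((k + 1, j))
                    if rest:
                        for _, vb in bdr.items():
                            for cr2, v2 in rest.items():
                                _merge_into(bucket, cr2, alg.cat(vb, v2))
            bv = _finish(alg, bucket)
            if bv:
                mc1[(i, j)] = bv

            # mcadd4 (starts with helix, unpaired suffix)
            bucket = {}
            v = edgr(i, j)
            if v is not None:  # incl(edgr): helix + one dangling base
                _merge_into(bucket, code[j - 1], alg.ad(v, brch))
            for k in range(i + 1, j):
                v = edgr(i, k)
                if v is not None:  # addss: trailing plain region k+1..j
                    _merge_into(
                        bucket, code[k - 1], alg.ssr(alg.ad(v, brch), j - k)
                    )
                first = nodg(i, k)
                if first is not None:
                    fi = alg.ad(first, brch)
                    rest = mcadd4.get((k + 1, j))
                    if rest:
                        for cl2, v2 in rest.items():
                            _merge_into(bucket, code[k], alg.cat(fi, v2))
                    if k + 2 <= j:
                        rest = mcadd4.get((k + 2, j))
                        if rest:
                            dr_e = ctx.dr(i, k, k + 1)
                            for cl2, v2 in rest.items():
                                e = min(0, dr_e, ctx.dl_class(k + 2, cl2, k + 1))
                                val = alg.cat(
                                    alg.ad(alg.dang(fi, ".", "R"), e), v2
                                )
                                _merge_into(bucket, code[k], val)
                ev = edgr(i, k)
                if ev is not None:
                    rest = mcadd3.get((k + 1, j))
                    if rest is not None:
                        _merge_into(
                            bucket,
                            code[k - 1],
                            alg.cat(alg.ad(ev, brch), rest[None]),
                        )
            bv = _finish(alg, bucket)
            if bv:
                mcadd4[(i, j)] = bv
            # mc3 = mcadd4 without the terminal forms
            bucket = {}
            for k in range(i + 1, j):
                first = nodg(i, k)
                if first is not None:
                    fi = alg.ad(first, brch)
                    rest = mcadd4.get((k + 1, j))
                    if rest:
                        for cl2, v2 in rest.items():
                            _merge_into(bucket, code[k], alg.cat(fi, v2))
                    if k + 2 <= j:
                        rest = mcadd4.get((k + 2, j))
                        if rest:
                            dr_e = ctx.dr(i, k, k + 1)
                            for cl2, v2 in rest.items():
                                e = min(0, dr_e, ctx.dl_class(k + 2, cl2, k + 1))
                                val = alg.cat(
                                    alg.ad(alg.dang(fi, ".", "R"), e), v2
                                )
                                _merge_into(bucket, code[k], val)
                ev = edgr(i, k)
                if ev is not None:
                    rest = mcadd3.get((k + 1, j))
                    if rest is not None:
                        _merge_into(
                            bucket,
                            code[k - 1],
                            alg.cat(alg.ad(ev, brch), rest[None]),
                        )
            bv = _finish(alg, bucket)
            if bv:
                mc3[(i, j)] = bv

            # mcadd3 (unpaired prefix and suffix)
            cands = []
            bdr = block_dlr.get((i, j))
            if bdr:  # terminal
                cands.extend(bdr.values())
            for k in range(i + 1, j):
                bdr = block_dlr.get((i, k))
                if bdr:  # addss
                    for _, vb in bdr.items():
                        cands.append(alg.ssr(vb, j - k))
                    rest = mcadd3.get((k + 1, j))
                    if rest is not None:
                        for _, vb in bdr.items():
                            cands.append(alg.cat(vb, rest[None]))
                bd = block_dl.get((i, k))
                if bd:
                    rest = mcadd4.get((k + 1, j))
                    if rest:
                        for _, vb in bd.items():
                            for cl2, v2 in rest.items():
                                cands.append(alg.cat(vb, v2))
                    if k + 2 <= j:
                        rest = mcadd4.get((k + 2, j))
                        if rest:
                            for cb, vb in bd.items():
                                dr_e = ctx.dr_class(cb, k, k + 1)
                                for cl2, v2 in rest.items():
                                    e = min(
                                        0, dr_e, ctx.dl_class(k + 2, cl2, k + 1)
                                    )
                                    cands.append(
                                        alg.cat(
                                            alg.ad(alg.dang(vb, ".", "R"), e), v2
                                        )
                                    )
            if cands:
                mcadd3[(i, j)] = {None: alg.h(cands)}
            # mc4 = mcadd3 without the terminal forms
            cands = []
            for k in range(i + 1, j):
                bdr = block_dlr.get((i, k))
                if bdr:
                    rest = mcadd3.get((k + 1, j))
                    if rest is not None:
                        for _, vb in bdr.items():
                            cands.append(alg.cat(vb, rest[None]))
                bd = block_dl.get((i, k))
                if bd:
                    rest = mcadd4.get((k + 1, j))
                    if rest:
                        for _, vb in bd.items():
                            for cl2, v2 in rest.items():
                                cands.append(alg.cat(vb, v2))
                    if k + 2 <= j:
                        rest = mcadd4.get((k + 2, j))
                        if rest:
                            for cb, vb in bd.items():
                                dr_e = ctx.dr_class(cb, k, k + 1)
                                for cl2, v2 in rest.items():
                                    e = min(
                                        0, dr_e, ctx.dl_class(k + 2, cl2, k + 1)
                                    )
                                    cands.append(
                                        alg.cat(
                                            alg.ad(alg.dang(vb, ".", "R"), e), v2
                                        )
                                    )
            if cands:
                mc4[(i, j)] = {None: alg.h(cands)}

    # exterior loop
    ld = [None] * (n + 1)  # left_dangle
    nld = [None] * (n + 1)  # noleft_dangle, classified by first-helix partner
    lu = [None] * (n + 1)  # left_unpaired
    ld[n] = alg.one()
    for i in range(n - 1, -1, -1):
        # noleft_dangle
        bucket = {}
        for k in range(i + 1, n):
            # cadd''(edgr(i,k), left_dangle|left_unpaired (k+1))
            ev = edgr(i, k)
            if ev is not None:
                for tail in (ld[k + 1], lu[k + 1]):
                    if tail is not None:
                        _merge_into(bucket, code[k - 1], alg.cat(ev, tail))
            # cadd'''(nodg(i,k), noleft_dangle(k+1) | end)
            nv = nodg(i, k)
            if nv is not None:
                if k + 1 == n:
                    _merge_into(bucket, code[k], nv)
                else:
                    t = nld[k + 1]
                    if t is not None:
                        _merge_into(
                            bucket, code[k], alg.cat(nv, _merge_all(alg, t))
                        )
                    # ambd'(nodg, base, noleft_dangle)
                    t = nld[k + 2] if k + 2 <= n else None
                    if t is not None:
                        dr_e = ctx.dr(i, k, k + 1)
                        parts = []
                        for c2, v2 in t.items():
                            e = min(0, dr_e, ctx.dl_class(k + 2, c2, k + 1))
                            parts.append(alg.cat(alg.ad(alg.dang(nv, ".", "R"), e), v2))
                        for p in parts:
                            _merge_into(bucket, code[k], p)
        nld[i] = _finish(alg, bucket)
        # left_dangle
        cands = []
        for k in range(i + 1, n):
            gv = edgl(i, k)
            if gv is not None:
                if k + 1 == n:
                    cands.append(gv)
                else:
                    t = nld[k + 1]
                    if t is not None:
                        cands.append(alg.cat(gv, _merge_all(alg, t)))
                    t = nld[k + 2] if k + 2 <= n else None
                    if t is not None:  # ambd
                        dr_e = ctx.dr(i + 1, k, k + 1)
                        for c2, v2 in t.items():
                            e = min(0, dr_e, ctx.dl_class(k + 2, c2, k + 1))
                            cands.append(
                                alg.cat(alg.ad(alg.dang(gv, ".", "R"), e), v2)
                            )
            lv = edglr(i, k)
            if lv is not None:
                for tail in (ld[k + 1], lu[k + 1]):
                    if tail is not None:
                        cands.append(alg.cat(lv, tail))
        ld[i] = alg.h(cands) if cands else None
        # left_unpaired
        cands = []
        if lu[i + 1] is not None:
            cands.append(alg.ssl(lu[i + 1], 1))
        if ld[i + 1] is not None:
            cands.append(alg.ssl(ld[i + 1], 1))
        lu[i] = alg.h(cands) if cands else None

    roots = []
    if ld[0] is not None:
        roots.append(ld[0])
    if nld[0] is not None:
        roots.append(_merge_all(alg, nld[0]))
    if lu[0] is not None:
        roots.append(lu[0])
    return alg.h(roots)


# ---------------------------------------------------------------------------
# MacroState ensemble walker (partition function / shape algebras)
#
# The MacroState mfe algebra resolves every dangle site at its per-structure
# optimum.  The ensemble algebras (partition function, shapes) instead
# resolve each stem boundary inside a multiloop -- the run between two
# stems, or between the last stem and the closing pair -- with at most one
# stabilizing dangle, chosen as the best of {none, 3' dangle onto the left
# stem, 5' dangle onto the right stem}.  The run following the closing pair
# keeps its two boundary dangles independent (the closing stem's inner
# dangle and the first stem's 5' dangle act on different bases and are both
# minimised with the no-dangle option).  Exterior-loop dangles are resolved
# at the per-structure optimum.
#
# Implementation: interior nonterminal values are classified not only by
# boundary-helix partner bases but also by the *pending* dangle energy of
# the first/last stem (an integer, few distinct values per cell), so the
# joint boundary decision can be made where both sides are known.


def run_macrostate_ensemble(ctx, alg):
    n = ctx.n
    code = ctx.code
    closed = {}
    mc1 = {}   # {(cr, pdl): v}
    mc2 = {}   # {(cl, cr): v}
    mc3 = {}   # {(cl, pdr): v}
    mc4 = {}   # {(pdl, pdr): v}
    mcadd1 = {}
    mcadd2 = {}
    mcadd3 = {}
    mcadd4 = {}
    block_dl = {}   # {(cb, pdl): v}
    block_dlr = {}  # {(pdl, pdr): v}
    off = ctx.params.ml_offset
    brch = ctx.params.ml_branch

    def nodg(i, j):
        v = closed.get((i, j))
        if v is None:
            return None
        return alg.ad(v, ctx.termau(i, j))

    def edgl(i, j):  # exterior use: dl resolved immediately
        v = closed.get((i + 1, j))
        if v is None:
            return None
        e = ctx.termau(i + 1, j) + min(0, ctx.dl(i + 1, j, i))
        return alg.ad(alg.dang(v, ".", "L"), e)

    def edgl_p(i, j):  # interior use: (value, pending dl energy)
        v = closed.get((i + 1, j))
        if v is None:
            return None
        return (
            alg.ad(alg.dang(v, ".", "L"), ctx.termau(i + 1, j)),
            ctx.dl(i + 1, j, i),
        )

    def edgr(i, j):
        v = closed.get((i, j - 1))
        if v is None:
            return None
        e = ctx.termau(i, j - 1) + min(0, ctx.dr(i, j - 1, j))
        return alg.ad(alg.dang(v, ".", "R"), e)

    def edgr_p(i, j):
        v = closed.get((i, j - 1))
        if v is None:
            return None
        return (
            alg.ad(alg.dang(v, ".", "R"), ctx.termau(i, j - 1)),
            ctx.dr(i, j - 1, j),
        )

    def edglr(i, j):
        v = closed.get((i + 1, j - 1))
        if v is None:
            return None
        e = (
            ctx.termau(i + 1, j - 1)
            + min(0, ctx.dl(i + 1, j - 1, i))
            + min(0, ctx.dr(i + 1, j - 1, j))
        )
        return alg.ad(alg.dang(alg.dang(v, ".", "L"), ".", "R"), e)

    def edglr_p(i, j):  # (value, pending dl, pending dr)
        v = closed.get((i + 1, j - 1))
        if v is None:
            return None
        return (
            alg.ad(
                alg.dang(alg.dang(v, ".", "L"), ".", "R"),
                ctx.termau(i + 1, j - 1),
            ),
            ctx.dl(i + 1, j - 1, i),
            ctx.dr(i + 1, j - 1, j),
        )

    def ml_cands(i, j):
        out = []
        a, b = i + 2, j - 2
        base_e = ctx.stack_e(i, j) + ctx.termau(i + 1, j - 1) + off + brch
        dli_e = ctx.dli(i + 1, j - 1, a)
        dri_e = ctx.dri(i + 1, j - 1, b)
        t = mc2.get((a, b))  # ml
        if t:
            out.append(alg.ml(alg.h(list(t.values())), base_e))
        t = mc1.get((a + 1, b))  # mldl
        if t:
            for (cr, pdl), v in t.items():
                e = base_e + min(0, dli_e) + min(0, pdl)
                out.append(alg.ml(v, e, pre="."))
        t = mc2.get((a + 1, b))  # mladl
        if t:
            for (cl, cr), v in t.items():
                e = base_e + min(0, dli_e, ctx.dl_class(a + 1, cl, a))
                out.append(alg.ml(v, e, pre="."))
        t = mc3.get((a, b - 1))  # mldr: suffix joint
        if t:
            for (cl, pdr), v in t.items():
                e = base_e + min(0, dri_e, pdr)
                out.append(alg.ml(v, e, post="."))
        t = mc2.get((a, b - 1))  # mladr
        if t:
            for (cl, cr), v in t.items():
                e = base_e + min(0, dri_e, ctx.dr_class(cr, b - 1, b))
                out.append(alg.ml(v, e, post="."))
        t = mc4.get((a + 1, b - 1))  # mldlr
        if t:
            for (pdl, pdr), v in t.items():
                e = base_e + min(0, dli_e) + min(0, pdl) + min(0, dri_e, pdr)
                out.append(alg.ml(v, e, pre=".", post="."))
        t = mc2.get((a + 1, b - 1))  # mladlr
        if t:
            for (cl, cr), v in t.items():
                e = (
                    base_e
                    + min(0, dli_e, ctx.dl_class(a + 1, cl, a))
                    + min(0, dri_e, ctx.dr_class(cr, b - 1, b))
                )
                out.append(alg.ml(v, e, pre=".", post="."))
        t = mc1.get((a + 1, b - 1))  # mldladr
        if t:
            for (cr, pdl), v in t.items():
                e = (
                    base_e
                    + min(0, dli_e)
                    + min(0, pdl)
                    + min(0, dri_e, ctx.dr_class(cr, b - 1, b))
                )
                out.append(alg.ml(v, e, pre=".", post="."))
        t = mc3.get((a + 1, b - 1))  # mladldr
        if t:
            for (cl, pdr), v in t.items():
                e = (
                    base_e
                    + min(0, dli_e, ctx.dl_class(a + 1, cl, a))
                    + min(0, dri_e, pdr)
                )
                out.append(alg.ml(v, e, pre=".", post="."))
        return out

    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if _pairable(ctx, i, j):
                cands = _closed_candidates(ctx, alg, closed, i, j, ml_cands)
                if cands:
                    closed[(i, j)] = alg.h(cands)
            # blocks
            bucket = {}
            t = edgl_p(i, j)
            if t is not None:
                v, pdl = t
                _merge_into(bucket, (code[i + 1], pdl), alg.ad(v, brch))
            for k in range(i + 1, j):
                t = edgl_p(k, j)
                if t is not None:
                    v, pdl = t
                    _merge_into(
                        bucket, (code[k + 1], pdl), alg.ad(alg.ssl(v, k - i), brch)
                    )
            bv = _finish(alg, bucket)
            if bv:
                block_dl[(i, j)] = bv
            bucket = {}
            t = edglr_p(i, j)
            if t is not None:
                v, pdl, pdr = t
                _merge_into(bucket, (pdl, pdr), alg.ad(v, brch))
            for k in range(i + 1, j):
                t = edglr_p(k, j)
                if t is not None:
                    v, pdl, pdr = t
                    _merge_into(
                        bucket, (pdl, pdr), alg.ad(alg.ssl(v, k - i), brch)
                    )
            bv = _finish(alg, bucket)
            if bv:
                block_dlr[(i, j)] = bv

            # mcadd1 / mc2  (keys (cl, cr))
            b1 = {}
            b2 = {}
            v = nodg(i, j)
            if v is not None:
                _merge_into(b1, (code[j], code[i]), alg.ad(v, brch))
            for k in range(i + 1, j):
                first = nodg(i, k)
                if first is not None:
                    fi = alg.ad(first, brch)
                    rest = mcadd1.get((k + 1, j))
                    if rest:
                        for (cl2, cr2), v2 in rest.items():
                            val = alg.cat(fi, v2)
                            _merge_into(b1, (code[k], cr2), val)
                            _merge_into(b2, (code[k], cr2), val)
                    if k + 2 <= j:
                        rest = mcadd1.get((k + 2, j))
                        if rest:
                            dr_e = ctx.dr(i, k, k + 1)
                            for (cl2, cr2), v2 in rest.items():
                                e = min(0, dr_e, ctx.dl_class(k + 2, cl2, k + 1))
                                val = alg.cat(alg.ad(alg.dang(fi, ".", "R"), e), v2)
                                _merge_into(b1, (code[k], cr2), val)
                                _merge_into(b2, (code[k], cr2), val)
                t = edgr_p(i, k)
                if t is not None:
                    ev, pdr_first = t
                    fi = alg.ad(ev, brch)
                    rest = mcadd2.get((k + 1, j))
                    if rest:
                        for (cr2, pdl2), v2 in rest.items():
                            e = min(0, pdr_first, pdl2)
                            val = alg.cat(alg.ad(fi, e), v2)
                            _merge_into(b1, (code[k - 1], cr2), val)
                            _merge_into(b2, (code[k - 1], cr2), val)
            bv = _finish(alg, b1)
            if bv:
                mcadd1[(i, j)] = bv
            bv = _finish(alg, b2)
            if bv:
                mc2[(i, j)] = bv

            # mcadd2 / mc1  (keys (cr, pdl-first))
            b1 = {}
            b2 = {}
            bd = block_dl.get((i, j))
            if bd:
                for (cb, pdl), v in bd.items():
                    _merge_into(b1, (cb, pdl), v)
            for k in range(i + 1, j):
                bd = block_dl.get((i, k))
                if bd:
                    rest1 = mcadd1.get((k + 1, j))
                    rest2 = mcadd1.get((k + 2, j)) if k + 2 <= j else None
                    for (cb, pdlb), vb in bd.items():
                        if rest1:
                            for (cl2, cr2), v2 in rest1.items():
                                val = alg.cat(vb, v2)
                                _merge_into(b1, (cr2, pdlb), val)
                                _merge_into(b2, (cr2, pdlb), val)
                        if rest2:
                            dr_e = ctx.dr_class(cb, k, k + 1)
                            for (cl2, cr2), v2 in rest2.items():
                                e = min(0, dr_e, ctx.dl_class(k + 2, cl2, k + 1))
                                val = alg.cat(alg.ad(alg.dang(vb, ".", "R"), e), v2)
                                _merge_into(b1, (cr2, pdlb), val)
                                _merge_into(b2, (cr2, pdlb), val)
                bdr = block_dlr.get((i, k))
                if bdr:
                    rest = mcadd2.get((k + 1, j))
                    if rest:
                        for (pdlb, pdrb), vb in bdr.items():
                            for (cr2, pdl2), v2 in rest.items():
                                e = min(0, pdrb, pdl2)
                                val = alg.cat(alg.ad(vb, e), v2)
                                _merge_into(b1, (cr2, pdlb), val)
                                _merge_into(b2, (cr2, pdlb), val)
            bv = _finish(alg, b1)
            if bv:
                mcadd2[(i, j)] = bv
            bv = _finish(alg, b2)
            if bv:
                mc1[(i, j)] = bv

            # mcadd4 / mc3  (keys (cl, pdr-last))
            b1 = {}
            b2 = {}
            t = edgr_p(i, j)
            if t is not None:
                v, pdr = t
                _merge_into(b1, (code[j - 1], pdr), alg.ad(v, brch))
            for k in range(i + 1, j):
                t = edgr_p(i, k)
                if t is not None:
                    v, pdr = t
                    _merge_into(
                        b1, (code[k - 1], pdr), alg.ssr(alg.ad(v, brch), j - k)
                    )
                first = nodg(i, k)
                if first is not None:
                    fi = alg.ad(first, brch)
                    rest = mcadd4.get((k + 1, j))
                    if rest:
                        for (cl2, pdr2), v2 in rest.items():
                            val = alg.cat(fi, v2)
                            _merge_into(b1, (code[k], pdr2), val)
                            _merge_into(b2, (code[k], pdr2), val)
                    if k + 2 <= j:
                        rest = mcadd4.get((k + 2, j))
                        if rest:
                            dr_e = ctx.dr(i, k, k + 1)
                            for (cl2, pdr2), v2 in rest.items():
                                e = min(0, dr_e, ctx.dl_class(k + 2, cl2, k + 1))
                                val = alg.cat(alg.ad(alg.dang(fi, ".", "R"), e), v2)
                                _merge_into(b1, (code[k], pdr2), val)
                                _merge_into(b2, (code[k], pdr2), val)
                t = edgr_p(i, k)
                if t is not None:
                    ev, pdr_first = t
                    rest = mcadd3.get((k + 1, j))
                    if rest:
                        fi = alg.ad(ev, brch)
                        for (pdl2, pdr2), v2 in rest.items():
                            e = min(0, pdr_first, pdl2)
                            val = alg.cat(alg.ad(fi, e), v2)
                            _merge_into(b1, (code[k - 1], pdr2), val)
                            _merge_into(b2, (code[k - 1], pdr2), val)
            bv = _finish(alg, b1)
            if bv:
                mcadd4[(i, j)] = bv
            bv = _finish(alg, b2)
            if bv:
                mc3[(i, j)] = bv

            # mcadd3 / mc4  (keys (pdl-first, pdr-last))
            b1 = {}
            b2 = {}
            bdr = block_dlr.get((i, j))
            if bdr:
                for (pdl, pdr), v in bdr.items():
                    _merge_into(b1, (pdl, pdr), v)
            for k in range(i + 1, j):
                bdr = block_dlr.get((i, k))
                if bdr:
                    for (pdlb, pdrb), vb in bdr.items():
                        _merge_into(b1, (pdlb, pdrb), alg.ssr(vb, j - k))
                    rest = mcadd3.get((k + 1, j))
                    if rest:
                        for (pdlb, pdrb), vb in bdr.items():
                            for (pdl2, pdr2), v2 in rest.items():
                                e = min(0, pdrb, pdl2)
                                val = alg.cat(alg.ad(vb, e), v2)
                                _merge_into(b1, (pdlb, pdr2), val)
                                _merge_into(b2, (pdlb, pdr2), val)
                bd = block_dl.get((i, k))
                if bd:
                    rest1 = mcadd4.get((k + 1, j))
                    rest2 = mcadd4.get((k + 2, j)) if k + 2 <= j else None
                    for (cb, pdlb), vb in bd.items():
                        if rest1:
                            for (cl2, pdr2), v2 in rest1.items():
                                val = alg.cat(vb, v2)
                                _merge_into(b1, (pdlb, pdr2), val)
                                _merge_into(b2, (pdlb, pdr2), val)
                        if rest2:
                            dr_e = ctx.dr_class(cb, k, k + 1)
                            for (cl2, pdr2), v2 in rest2.items():
                                e = min(0, dr_e, ctx.dl_class(k + 2, cl2, k + 1))
                                val = alg.cat(alg.ad(alg.dang(vb, ".", "R"), e), v2)
                                _merge_into(b1, (pdlb, pdr2), val)
                                _merge_into(b2, (pdlb, pdr2), val)
            bv = _finish(alg, b1)
            if bv:
                mcadd3[(i, j)] = bv
            bv = _finish(alg, b2)
            if bv:
                mc4[(i, j)] = bv

    # exterior: identical to the mfe walker (per-structure optimal dangles)
    ld = [None] * (n + 1)
    nld = [None] * (n + 1)
    lu = [None] * (n + 1)
    ld[n] = alg.one()
    for i in range(n - 1, -1, -1):
        bucket = {}
        for k in range(i + 1, n):
            ev = edgr(i, k)
            if ev is not None:
                for tail in (ld[k + 1], lu[k + 1]):
                    if tail is not None:
                        _merge_into(bucket, code[k - 1], alg.cat(ev, tail))
            nv = nodg(i, k)
            if nv is not None:
                if k + 1 == n:
                    _merge_into(bucket, code[k], nv)
                else:
                    t = nld[k + 1]
                    if t is not None:
                        _merge_into(bucket, code[k], alg.cat(nv, _merge_all(alg, t)))
                    t = nld[k + 2] if k + 2 <= n else None
                    if t is not None:
                        dr_e = ctx.dr(i, k, k + 1)
                        for c2, v2 in t.items():
                            e = min(0, dr_e, ctx.dl_class(k + 2, c2, k + 1))
                            _merge_into(
                                bucket,
                                code[k],
                                alg.cat(alg.ad(alg.dang(nv, ".", "R"), e), v2),
                            )
        nld[i] = _finish(alg, bucket)
        cands = []
        for k in range(i + 1, n):
            gv = edgl(i, k)
            if gv is not None:
                if k + 1 == n:
                    cands.append(gv)
                else:
                    t = nld[k + 1]
                    if t is not None:
                        cands.append(alg.cat(gv, _merge_all(alg, t)))
                    t = nld[k + 2] if k + 2 <= n else None
                    if t is not None:
                        dr_e = ctx.dr(i + 1, k, k + 1)
                        for c2, v2 in t.items():
                            e = min(0, dr_e, ctx.dl_class(k + 2, c2, k + 1))
                            cands.append(
                                alg.cat(alg.ad(alg.dang(gv, ".", "R"), e), v2)
                            )
            lv = edglr(i, k)
            if lv is not None:
                for tail in (ld[k + 1], lu[k + 1]):
                    if tail is not None:
                        cands.append(alg.cat(lv, tail))
        ld[i] = alg.h(cands) if cands else None
        cands = []
        if lu[i + 1] is not None:
            cands.append(alg.ssl(lu[i + 1], 1))
        if ld[i + 1] is not None:
            cands.append(alg.ssl(ld[i + 1], 1))
        lu[i] = alg.h(cands) if cands else None

    roots = []
    if ld[0] is not None:
        roots.append(ld[0])
    if nld[0] is not None:
        roots.append(_merge_all(alg, nld[0]))
    if lu[0] is not None:
        roots.append(lu[0])
    return alg.h(roots)
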