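"""Exact folding-space counters, one per grammar.

These implement the same recurrences as the walkers in
:mod:`foldspace._dp` with plain integer arithmetic and an O(1)
internal-loop summation (row prefix sums over the ``closed`` table), which
makes counting fast enough for the growth experiment.  They are
cross-checked against the generic walkers and the brute-force oracle in
the test suite.
"""

from __future__ import annotations

from typing import List

from .params import pair_type

MAXLOOP = 30


def _pt_matrix(code) -> List[List[int]]:
    n = len(code)
    pt = [[0] * n for _ in range(n)]
    for i in range(n):
        ci = code[i]
        for j in range(i + 1, n):
            pt[i][j] = pair_type(ci, code[j])
    return pt


def _loop_sums(closed, pref, i, j):
    """hairpin + bulges + internal loop counts for closing pairs (i,j),(i+1,j-1)."""
    c = 1 if j - i - 3 >= 3 else 0
    # left bulge: inner closed (i+2+lb, j-2)
    for lb in range(1, min(MAXLOOP, j - i - 7) + 1):
        c += closed[i + 2 + lb][j - 2]
    # right bulge: row i+2, columns j-2-rb
    rbmax = min(MAXLOOP, j - i - 7)
    if rbmax >= 1:
        row = pref[i + 2]
        c += row[j - 3] - row[j - 3 - rbmax]
    # internal loops: rows a = i+3 .. i+32, columns j-2-l3
    amax = min(i + 2 + MAXLOOP, j - 9)
    for a in range(i + 3, amax + 1):
        l5 = a - i - 2
        l3max = min(MAXLOOP, j - i - 8 - l5)
        if l3max < 1:
            break
        row = pref[a]
        c += row[j - 3] - row[j - 3 - l3max]
    return c


def count_nodangle(code) -> int:
    """Classical structures (NoDangle = OverDangle grammar)."""
    n = len(code)
    if n < 7:
        return 1
    pt = _pt_matrix(code)
    closed = [[0] * n for _ in range(n)]
    # pref[a][b] = sum of closed[a][:b+1]; pref[a][-1] treated via index b+1
    pref = [[0] * (n + 1) for _ in range(n)]
    mlc = [[0] * n for _ in range(n)]
    mlc1 = [[0] * n for _ in range(n)]
    for i in range(n - 1, -1, -1):
        rowc = closed[i]
        for j in range(i + 6, n):
            if pt[i][j] and pt[i + 1][j - 1]:
                c = closed[i + 1][j - 1]  # sr
                c += _loop_sums(closed, pref, i, j)
                c += mlc[i + 2][j - 2]  # ml
                rowc[j] = c
        for j in range(i + 1, n):
            # ml_comps1: sadd | cadd(incl, ml_comps1) | incl | addss
            v = mlc1[i + 1][j]
            for k in range(i + 6, j):
                ck = rowc[k]
                if ck:
                    v += ck * (mlc1[k + 1][j] + 1)
            v += rowc[j]
            mlc1[i][j] = v
            # ml_comps: sadd | cadd(incl, ml_comps1)
            w = mlc[i + 1][j]
            for k in range(i + 6, j):
                ck = rowc[k]
                if ck:
                    w += ck * mlc1[k + 1][j]
            mlc[i][j] = w
        p = pref[i]
        acc = 0
        for b in range(n):
            acc += rowc[b]
            p[b] = acc
        p[-1] = 0  # index -1 = empty prefix
    s = [0] * (n + 1)
    s[n] = 1
    for i in range(n - 1, -1, -1):
        v = s[i + 1]
        rowc = closed[i]
        for j in range(i + 6, n):
            if rowc[j]:
                v += rowc[j] * s[j + 1]
        s[i] = v
    return s[0]


def count_microstate(code) -> int:
    """Dangle-refined microstates."""
    n = len(code)
    if n < 7:
        return 1
    pt = _pt_matrix(code)
    closed = [[0] * n for _ in range(n)]
    pref = [[0] * (n + 1) for _ in range(n)]
    dang = [[0] * n for _ in range(n)]
    mlc = [[0] * n for _ in range(n)]
    mlc1 = [[0] * n for _ in range(n)]
    for i in range(n - 1, -1, -1):
        rowc = closed[i]
        rowd = dang[i]
        for j in range(i + 6, n):
            if pt[i][j] and pt[i + 1][j - 1]:
                c = closed[i + 1][j - 1]
                c += _loop_sums(closed, pref, i, j)
                # ml | mldl | mldr | mldlr
                c += (
                    mlc[i + 2][j - 2]
                    + mlc[i + 3][j - 2]
                    + mlc[i + 2][j - 3]
                    + mlc[i + 3][j - 3]
                )
                rowc[j] = c
        for j in range(i + 1, n):
            # dangle = drem | edl | edr | edlr on span (i, j)
            d = rowc[j] + closed[i + 1][j]
            if j >= 1:
                d += rowc[j - 1] + closed[i + 1][j - 1]
            rowd[j] = d
            v = mlc1[i + 1][j]
            for k in range(i + 5, j):
                dk = rowd[k]
                if dk:
                    v += dk * (mlc1[k + 1][j] + 1)
            v += rowd[j]
            mlc1[i][j] = v
            w = mlc[i + 1][j]
            for k in range(i + 5, j):
                dk = rowd[k]
                if dk:
                    w += dk * mlc1[k + 1][j]
            mlc[i][j] = w
        p = pref[i]
        acc = 0
        for b in range(n):
            acc += rowc[b]
            p[b] = acc
        p[-1] = 0
    s = [0] * (n + 1)
    s[n] = 1
    for i in range(n - 1, -1, -1):
        v = s[i + 1]
        rowd = dang[i]
        for j in range(i + 5, n):
            if rowd[j]:
                v += rowd[j] * s[j + 1]
        s[i] = v
    return s[0]


def count_macrostate(code) -> int:
    """Classical structures via the MacroState grammar (must equal
    :func:`count_nodangle` on every sequence; that identity is a test)."""
    n = len(code)
    if n < 7:
        return 1
    pt = _pt_matrix(code)
    Z = [0] * (n + 2)
    closed = [[0] * n for _ in range(n)]
    pref = [[0] * (n + 1) for _ in range(n)]
    bdl = [[0] * n for _ in range(n)]  # block_dl
    bdlr = [[0] * n for _ in range(n)]  # block_dlr
    m1 = [Z[:] for _ in range(n)]
    m2 = [Z[:] for _ in range(n)]
    m3 = [Z[:] for _ in range(n)]
    m4 = [Z[:] for _ in range(n)]
    a1 = [Z[:] for _ in range(n)]
    a2 = [Z[:] for _ in range(n)]
    a3 = [Z[:] for _ in range(n)]
    a4 = [Z[:] for _ in range(n)]

    def cl(i, j):
        if 0 <= i and j < n:
            return closed[i][j]
        return 0

    for i in range(n - 1, -1, -1):
        rowc = closed[i]
        for j in range(i + 6, n):
            if pt[i][j] and pt[i + 1][j - 1]:
                c = closed[i + 1][j - 1]
                c += _loop_sums(closed, pref, i, j)
                a, b = i + 2, j - 2  # multiloop interior
                c += m2[a][b]  # ml
                c += m1[a + 1][b] + m2[a + 1][b]  # mldl | mladl
                c += m3[a][b - 1] + m2[a][b - 1]  # mldr | mladr
                c += (
                    m4[a + 1][b - 1]
                    + m2[a + 1][b - 1]
                    + m1[a + 1][b - 1]
                    + m3[a + 1][b - 1]
                )  # mldlr | mladlr | mldladr | mladldr
                rowc[j] = c
        for j in range(i + 1, n):
            # block_dl(i,j) = sum_k edgl(k,j), edgl(k,j) = closed(k+1,j)
            v = 0
            w = 0
            for k in range(i, j):
                v += cl(k + 1, j)
                w += cl(k + 1, j - 1)
            bdl[i][j] = v
            bdlr[i][j] = w
            # mcadd1 / mc2
            v = 0
            for k in range(i + 6, j):
                ck = rowc[k]
                if ck:
                    v += ck * (a1[k + 1][j] + (a1[k + 2][j] if k + 2 <= j else 0))
                ek = rowc[k - 1]  # edgr(i,k) = closed(i,k-1)
                if ek:
                    v += ek * a2[k + 1][j]
            m2[i][j] = v
            a1[i][j] = v + rowc[j]
            # mcadd2 / mc1
            v = 0
            for k in range(i + 1, j):
                bk = bdl[i][k]
                if bk:
                    v += bk * (a1[k + 1][j] + (a1[k + 2][j] if k + 2 <= j else 0))
                bk = bdlr[i][k]
                if bk:
                    v += bk * a2[k + 1][j]
            m1[i][j] = v
            a2[i][j] = v + bdl[i][j]
            # mcadd4 / mc3
            v = 0
            term = cl(i, j - 1)  # incl(edgr(i,j))
            for k in range(i + 1, j):
                ek = cl(i, k - 1)
                if ek:
                    term += ek  # addss(incl(edgr(i,k)), region k+1..j)
                    v += ek * a3[k + 1][j]
                ck = rowc[k]
                if ck:
                    v += ck * (a4[k + 1][j] + (a4[k + 2][j] if k + 2 <= j else 0))
            m3[i][j] = v
            a4[i][j] = v + term
            # mcadd3 / mc4
            v = 0
            term = bdlr[i][j]
            for k in range(i + 1, j):
                bk = bdlr[i][k]
                if bk:
                    term += bk  # addss(block_dlr, region)
                    v += bk * a3[k + 1][j]
                bk = bdl[i][k]
                if bk:
                    v += bk * (a4[k + 1][j] + (a4[k + 2][j] if k + 2 <= j else 0))
            m4[i][j] = v
            a3[i][j] = v + term
        p = pref[i]
        acc = 0
        for b in range(n):
            acc += rowc[b]
            p[b] = acc
        p[-1] = 0
    # exterior
    ld = [0] * (n + 2)
    nld = [0] * (n + 2)
    lu = [0] * (n + 2)
    ld[n] = 1
    for i in range(n - 1, -1, -1):
        v = 0
        for k in range(i + 1, n):
            ek = cl(i, k - 1)  # edgr(i,k)
            if ek:
                v += ek * (ld[k + 1] + lu[k + 1])
            ck = cl(i, k)  # nodg(i,k)
            if ck:
                tail = nld[k + 1] + (1 if k + 1 == n else 0)
                tail += nld[k + 2] if k + 2 <= n else 0  # ambd'
                v += ck * tail
        nld[i] = v
        v = 0
        for k in range(i + 1, n):
            gk = cl(i + 1, k)  # edgl(i,k)
            if gk:
                tail = nld[k + 1] + (1 if k + 1 == n else 0)
                tail += nld[k + 2] if k + 2 <= n else 0  # ambd
                v += gk * tail
            lk = cl(i + 1, k - 1)  # edglr(i,k)
            if lk:
                v += lk * (ld[k + 1] + lu[k + 1])
        ld[i] = v + (0 if i < n else 1)
        lu[i] = lu[i + 1] + ld[i + 1]
    return ld[0] + nld[0] + lu[0]
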