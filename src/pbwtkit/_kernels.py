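"""Compiled inner loops for the positional prefix-array sweep and matching.

All kernels operate on int32 prefix/divergence arrays and uint8 allele
columns given in current sorted (a_k) order.  They are deliberately tiny
and allocation-free so the surrounding Python code controls buffers and
streaming.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def step_a_d(a, d, col, k, a2, d2):
    """One sweep step k -> k+1 of the prefix and divergence arrays.

    ``col`` holds the alleles of site k in a_k order.  Writes the arrays
    for k+1 into ``a2``/``d2`` and returns c, the number of 0 alleles.

    The divergence update keeps a running maximum of d over the entries
    seen since the previous member of the same allele class (initialised
    to the sentinel k+1), which is exactly the smallest position from
    which the two newly adjacent reversed prefixes agree.
    """
    M = a.shape[0]
    p = k + 1
    nz = 0
    for i in range(M):
        if d[i] > p:
            p = d[i]
        if col[i] == 0:
            a2[nz] = a[i]
            d2[nz] = p
            nz += 1
            p = 0
    c = nz
    q = k + 1
    no = c
    for i in range(M):
        if d[i] > q:
            q = d[i]
        if col[i] == 1:
            a2[no] = a[i]
            d2[no] = q
            no += 1
            q = 0
    return c


@njit(cache=True)
def setmax_stats_step(a, d, col, k, interior, pos, pos_end, acc):
    """Accumulate set-maximal matches ending at k into ``acc``.

    For each sorted index i the nearest-neighbour divergence values
    bound the best possible match start e = min(d[i], d[i+1]); the scan
    walks outward collecting every neighbour tied at e, aborting as soon
    as a tied neighbour carries the same allele (the match then extends
    past k and nothing ending at k is set-maximal for i).  With
    ``interior == 0`` (the final flush at k = N) the allele test is
    skipped.

    Two granularities accumulate side by side: per partner (one count
    per reported Match record) and per interval (tied partner blocks
    collapsed to one event per target).

    acc layout: [0] partner count, [1] partner sites, [2] partner bp,
    [3] interval count, [4] interval sites, [5] interval bp, where bp
    lengths are pos_end - pos[start].
    """
    M = a.shape[0]
    for i in range(M):
        di = d[i]
        if i + 1 < M:
            di1 = d[i + 1]
        else:
            di1 = k
        e = di if di < di1 else di1
        if e >= k:
            continue
        ok = True
        m = i - 1
        n = i + 1
        if di <= di1:
            while m >= 0 and d[m + 1] <= di:
                if interior == 1 and col[m] == col[i]:
                    ok = False
                    break
                m -= 1
        if ok and di >= di1:
            while n < M and d[n] <= di1:
                if interior == 1 and col[n] == col[i]:
                    ok = False
                    break
                n += 1
        if not ok:
            continue
        reported = 0
        if di <= di1:
            cnt = i - 1 - m
            if cnt > 0:
                acc[0] += cnt
                acc[1] += cnt * (k - di)
                acc[2] += cnt * (pos_end - pos[di])
                reported += cnt
        if di1 <= di:
            cnt = n - i - 1
            if cnt > 0:
                acc[0] += cnt
                acc[1] += cnt * (k - di1)
                acc[2] += cnt * (pos_end - pos[di1])
                reported += cnt
        if reported > 0:
            acc[3] += 1
            acc[4] += k - e
            acc[5] += pos_end - pos[e]
    return 0
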