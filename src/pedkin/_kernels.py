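"""Numba kernels for the Meuwissen-Luo inbreeding recursion.

The recursion computes, for individual i with parents s and t,

    F_i = d_i + sum_j L_j^2 d_j - 1

where the sum runs over the ancestors j of i, L_j is the (partial) column of
the unit lower-triangular T of A = T D T', accumulated downward by adding
0.5*L_j to each known parent of j, and d_j is the Mendelian-sampling variance.
Ancestors are processed youngest-first (largest code first) so every L_j is
final before it is consumed; correctness of the scheme depends on that order.

All arrays here are 1-padded: index 0 is the unknown-parent sentinel, so
``f[0] == 0`` and codes run 1..n. The workspace arrays (L, stamp, stack, anc)
are sized n+1 and reused across individuals; a generation counter in ``stamp``
avoids clearing the visited flags between traces.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _trace(sire, dam, d, s, t, L, stamp, stack, anc, cur):
    """Accumulate sum of L_j^2 d_j over ancestors of a (virtual) progeny of s, t.

    Seeds L[s] += 0.5 and L[t] += 0.5, walks the ancestor closure, and leaves
    the workspace clean (L zeroed on the touched entries) on return.
    """
    top = 0
    na = 0
    stamp[s] = cur
    stack[top] = s
    top += 1
    if stamp[t] != cur:
        stamp[t] = cur
        stack[top] = t
        top += 1
    while top > 0:
        top -= 1
        j = stack[top]
        anc[na] = j
        na += 1
        sj = sire[j]
        if sj > 0 and stamp[sj] != cur:
            stamp[sj] = cur
            stack[top] = sj
            top += 1
        dj = dam[j]
        if dj > 0 and stamp[dj] != cur:
            stamp[dj] = cur
            stack[top] = dj
            top += 1
    idx = np.sort(anc[:na])
    L[s] += 0.5
    L[t] += 0.5
    tot = 0.0
    for k in range(na - 1, -1, -1):
        j = idx[k]
        lj = L[j]
        tot += lj * lj * d[j]
        sj = sire[j]
        if sj > 0:
            L[sj] += 0.5 * lj
        dj = dam[j]
        if dj > 0:
            L[dj] += 0.5 * lj
        L[j] = 0.0
    return tot


@njit(cache=True)
def meuwissen_luo(sire, dam, f, d, start):
    """Fill f[start+1..n] and d[start+1..n] in place over an ordered pedigree.

    ``sire``/``dam`` are 1-padded int64 code arrays (0 = unknown); ``f`` and
    ``d`` are 1-padded float64 arrays whose first ``start`` entries (codes
    1..start) are taken as given (the resume prefix).
    """
    n = sire.shape[0] - 1
    L = np.zeros(n + 1, dtype=np.float64)
    stamp = np.zeros(n + 1, dtype=np.int64)
    stack = np.empty(n + 1, dtype=np.int64)
    anc = np.empty(n + 1, dtype=np.int64)
    cur = 0
    for i in range(start + 1, n + 1):
        s = sire[i]
        t = dam[i]
        if s == 0 and t == 0:
            d[i] = 1.0
            f[i] = 0.0
        elif s == 0 or t == 0:
            d[i] = 0.75 - 0.25 * f[s + t]
            f[i] = 0.0
        else:
            d[i] = 0.5 - 0.25 * (f[s] + f[t])
            cur += 1
            f[i] = d[i] + _trace(sire, dam, d, s, t, L, stamp, stack, anc, cur) - 1.0


@njit(cache=True)
def dummy_inbreeding(sire, dam, f, d, pair_sire, pair_dam, out):
    """Inbreeding coefficients of terminal dummy progenies for given pairs.

    Each pair (pair_sire[r], pair_dam[r]) indexes real animals of an ordered,
    1-padded pedigree whose f and d are already complete. The dummy is never
    appended: because it is terminal and unrelated to every other dummy, its
    coefficient F = d_X + trace - 1 is exactly what the full recursion would
    produce on the extended pedigree (bitwise).
    """
    n = sire.shape[0] - 1
    L = np.zeros(n + 1, dtype=np.float64)
    stamp = np.zeros(n + 1, dtype=np.int64)
    stack = np.empty(n + 1, dtype=np.int64)
    anc = np.empty(n + 1, dtype=np.int64)
    cur = 0
    for r in range(pair_sire.shape[0]):
        s = pair_sire[r]
        t = pair_dam[r]
        dx = 0.5 - 0.25 * (f[s] + f[t])
        cur += 1
        out[r] = dx + _trace(sire, dam, d, s, t, L, stamp, stack, anc, cur) - 1.0
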