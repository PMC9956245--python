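"""Numba dynamic-programming kernels for affine-gap alignment.

A gap of length k costs open + k*extend (BLAST convention), so opening a
one-residue gap costs open+extend.  The local kernel supports position
masks used to extract non-overlapping suboptimal HSPs by greedy masking of
the optimal path.  Tracebacks prefer the match state on ties so repeated
runs are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def sw_affine(a, b, scores, gap_open, gap_extend, mask_a, mask_b):
    """Smith-Waterman with affine gaps; returns DP matrices and best cell."""
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)  # gap in a (move along b)
    F = np.full((m + 1, n + 1), NEG, np.int32)  # gap in b (move along a)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_extend
            eo = H[i, j - 1] - gap_open - gap_extend
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            fo = H[i - 1, j] - gap_open - gap_extend
            if fo > f:
                f = fo
            F[i, j] = f
            if mask_a[i - 1] or mask_b[j - 1]:
                s = NEG
            else:
                s = scores[a[i - 1], b[j - 1]]
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def sw_traceback(H, E, F, a, b, scores, gap_open, gap_extend, bi, bj, mask_a, mask_b):
    """Trace the optimal local path back from (bi, bj) until H hits 0.

    Returns (ai, bjx, k): parallel arrays of 0-based positions per alignment
    column, -1 marking a gap on that side, and the number of columns k
    (columns stored in reverse order of the alignment).
    """
    maxlen = H.shape[0] + H.shape[1]
    ai = np.full(maxlen, -2, np.int64)
    bjx = np.full(maxlen, -2, np.int64)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E (gap in a), 2 = F (gap in b)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            if mask_a[i - 1] or mask_b[j - 1]:
                s = NEG
            else:
                s = scores[a[i - 1], b[j - 1]]
            if H[i, j] == H[i - 1, j - 1] + s:
                ai[k] = i - 1
                bjx[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ai[k] = -1
            bjx[k] = j - 1
            k += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
        else:
            ai[k] = i - 1
            bjx[k] = -1
            k += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
    return ai, bjx, k


@njit(cache=True)
def nw_affine(a, b, scores, gap_open, gap_extend):
    """Needleman-Wunsch global alignment with affine gaps, end gaps penalized.

    Returns (score, ai, bjx, k) with the same column encoding as sw_traceback.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.full((m + 1, n + 1), NEG, np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = -gap_open - j * gap_extend
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -gap_open - i * gap_extend
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_extend
            eo = H[i, j - 1] - gap_open - gap_extend
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            fo = H[i - 1, j] - gap_open - gap_extend
            if fo > f:
                f = fo
            F[i, j] = f
            h = H[i - 1, j - 1] + scores[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    # traceback: state says which matrix realizes the path value at (i, j)
    maxlen = m + n
    ai = np.full(maxlen, -2, np.int64)
    bjx = np.full(maxlen, -2, np.int64)
    k = 0
    i = m
    j = n
    state = 0  # 0 = H, 1 = E (gap in a), 2 = F (gap in b)
    while i > 0 or j > 0:
        if state == 0:
            if i == 0:
                state = 1
                continue
            if j == 0:
                state = 2
                continue
            s = scores[a[i - 1], b[j - 1]]
            if H[i, j] == H[i - 1, j - 1] + s:
                ai[k] = i - 1
                bjx[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ai[k] = -1
            bjx[k] = j - 1
            k += 1
            if j > 1 or i > 0:
                if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                    state = 0
            j -= 1
        else:
            ai[k] = i - 1
            bjx[k] = -1
            k += 1
            if i > 1 or j > 0:
                if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                    state = 0
            i -= 1
    return H[m, n], ai, bjx, k
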