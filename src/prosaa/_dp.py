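"""Numba kernels for the Viterbi / forward dynamic programs.

All kernels work in bits on the log-odds arrays of a ScoringModel. The parse
space is local-local: a parse starts in a match state (free entry, score 0),
moves through M/I/D states with source-indexed transitions, and ends in a
match state anywhere. Delete states consume no target residue.

Banding restricts computation to cells with |(i - i0) - (j - j0)| <= d around
the anchor diagonal; a negative band width means "no band".

Recurrences (tie preference M > I > D > fresh start, enforced at traceback):
    M[i,j] = emit_M[i,a_j] + max(0, M[i-1,j-1]+tMM, I[i-1,j-1]+tIM, D[i-1,j-1]+tDM)
    I[i,j] = emit_I[i,a_j] + max(M[i,j-1]+tMI, I[i,j-1]+tII)
    D[i,j] = max(M[i-1,j]+tMD, D[i-1,j]+tDD)
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -np.inf


@njit(cache=True)
def _band_limits(j, i0, j0, d, L):
    if d < 0:
        return 1, L
    c = i0 + (j - j0)
    lo = c - d
    hi = c + d
    if lo < 1:
        lo = 1
    if hi > L:
        hi = L
    return lo, hi


@njit(cache=True)
def viterbi_fill(emit_M, emit_I, tr, tgt, i0, j0, d):
    """Fill M/I/D tables; returns (M, I, D, best score, best i, best j).

    ``tgt`` is an int array of residue indices (-1 = unknown, emission -inf);
    ``i0``/``j0`` are the 1-based anchor coordinates (any in-band point when
    unbanded). Best cell is the maximal M entry, earliest (i, j) on ties.
    """
    L = emit_M.shape[0] - 1
    n = tgt.shape[0]
    M = np.full((L + 1, n + 1), NEG)
    I = np.full((L + 1, n + 1), NEG)
    D = np.full((L + 1, n + 1), NEG)
    best = NEG
    bi = 0
    bj = 0
    for j in range(1, n + 1):
        a = tgt[j - 1]
        lo, hi = _band_limits(j, i0, j0, d, L)
        for i in range(lo, hi + 1):
            # match
            em = emit_M[i, a] if a >= 0 else NEG
            vm = 0.0  # fresh local start
            v = M[i - 1, j - 1] + tr[i - 1, 0]
            if v > vm:
                vm = v
            v = I[i - 1, j - 1] + tr[i - 1, 3]
            if v > vm:
                vm = v
            v = D[i - 1, j - 1] + tr[i - 1, 5]
            if v > vm:
                vm = v
            m = em + vm
            M[i, j] = m
            if m > best:
                best = m
                bi = i
                bj = j
            # insert
            ei = emit_I[i, a] if a >= 0 else NEG
            vi = M[i, j - 1] + tr[i, 1]
            v = I[i, j - 1] + tr[i, 4]
            if v > vi:
                vi = v
            I[i, j] = ei + vi
            # delete (same column, previous row already computed)
            vd = M[i - 1, j] + tr[i - 1, 2]
            v = D[i - 1, j] + tr[i - 1, 6]
            if v > vd:
                vd = v
            D[i, j] = vd
    return M, I, D, best, bi, bj


@njit(cache=True)
def viterbi_score(emit_M, emit_I, tr, tgt, i0, j0, d):
    """Score-only banded Viterbi with O(L) memory; returns (score, bi, bj)."""
    L = emit_M.shape[0] - 1
    n = tgt.shape[0]
    Mp = np.full(L + 1, NEG)
    Ip = np.full(L + 1, NEG)
    Dp = np.full(L + 1, NEG)
    Mc = np.full(L + 1, NEG)
    Ic = np.full(L + 1, NEG)
    Dc = np.full(L + 1, NEG)
    best = NEG
    bi = 0
    bj = 0
    prev_lo = 1
    prev_hi = 0
    for j in range(1, n + 1):
        a = tgt[j - 1]
        lo, hi = _band_limits(j, i0, j0, d, L)
        for i in range(lo, hi + 1):
            Mc[i] = NEG
            Ic[i] = NEG
            Dc[i] = NEG
        for i in range(lo, hi + 1):
            em = emit_M[i, a] if a >= 0 else NEG
            vm = 0.0
            if i - 1 >= prev_lo and i - 1 <= prev_hi:
                v = Mp[i - 1] + tr[i - 1, 0]
                if v > vm:
                    vm = v
                v = Ip[i - 1] + tr[i - 1, 3]
                if v > vm:
                    vm = v
                v = Dp[i - 1] + tr[i - 1, 5]
                if v > vm:
                    vm = v
            m = em + vm
            Mc[i] = m
            if m > best:
                best = m
                bi = i
                bj = j
            ei = emit_I[i, a] if a >= 0 else NEG
            vi = NEG
            if i >= prev_lo and i <= prev_hi:
                vi = Mp[i] + tr[i, 1]
                v = Ip[i] + tr[i, 4]
                if v > vi:
                    vi = v
            Ic[i] = ei + vi
            vd = Mc[i - 1] + tr[i - 1, 2] if i - 1 >= lo else NEG
            v = Dc[i - 1] + tr[i - 1, 6] if i - 1 >= lo else NEG
            if v > vd:
                vd = v
            Dc[i] = vd
        Mp, Mc = Mc, Mp
        Ip, Ic = Ic, Ip
        Dp, Dc = Dc, Dp
        prev_lo = lo
        prev_hi = hi
    return best, bi, bj


@njit(cache=True)
def _lse2(a, b):
    if a == NEG:
        return b
    if b == NEG:
        return a
    if a >= b:
        return a + np.log2(1.0 + 2.0 ** (b - a))
    return b + np.log2(1.0 + 2.0 ** (a - b))


@njit(cache=True)
def forward_score_kernel(emit_M, emit_I, tr, tgt):
    """log2-sum over all local-local parses (each counted once at its final M)."""
    L = emit_M.shape[0] - 1
    n = tgt.shape[0]
    M = np.full((L + 1, n + 1), NEG)
    I = np.full((L + 1, n + 1), NEG)
    D = np.full((L + 1, n + 1), NEG)
    total = NEG
    for j in range(1, n + 1):
        a = tgt[j - 1]
        for i in range(1, L + 1):
            em = emit_M[i, a] if a >= 0 else NEG
            s = 0.0  # fresh start carries weight 1
            s = _lse2(s, M[i - 1, j - 1] + tr[i - 1, 0])
            s = _lse2(s, I[i - 1, j - 1] + tr[i - 1, 3])
            s = _lse2(s, D[i - 1, j - 1] + tr[i - 1, 5])
            M[i, j] = em + s
            total = _lse2(total, M[i, j])
            ei = emit_I[i, a] if a >= 0 else NEG
            si = _lse2(M[i, j - 1] + tr[i, 1], I[i, j - 1] + tr[i, 4])
            I[i, j] = ei + si
            D[i, j] = _lse2(M[i - 1, j] + tr[i - 1, 2], D[i - 1, j] + tr[i - 1, 6])
    return total
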