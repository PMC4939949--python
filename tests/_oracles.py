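"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected result by direct enumeration or
definition-level arithmetic, sharing no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from prosaa._alphabet import AMINO_ACIDS, GBMR4


def enumerate_parse_scores(scoring, tgt_idx) -> np.ndarray:
    """Scores (bits) of every local parse: start in M, walk M/I/D, end in M."""
    L, n = scoring.L, len(tgt_idx)
    tr = scoring.tr
    out: list[float] = []

    def rec(state, i, j, score):
        if state == "M":
            a = tgt_idx[j - 1]
            sc = score + (scoring.emit_M[i, a] if a >= 0 else -np.inf)
            out.append(sc)  # every parse may end at a match
            if i < L and j < n:
                rec("M", i + 1, j + 1, sc + tr[i, 0])
            if j < n:
                rec("I", i, j + 1, sc + tr[i, 1])
            if i < L:
                rec("D", i + 1, j, sc + tr[i, 2])
        elif state == "I":
            a = tgt_idx[j - 1]
            sc = score + (scoring.emit_I[i, a] if a >= 0 else -np.inf)
            if sc == -np.inf:
                return
            if i < L and j < n:
                rec("M", i + 1, j + 1, sc + tr[i, 3])
            if j < n:
                rec("I", i, j + 1, sc + tr[i, 4])
        else:
            if score == -np.inf:
                return
            if i < L and j < n:
                rec("M", i + 1, j + 1, score + tr[i, 5])
            if i < L:
                rec("D", i + 1, j, score + tr[i, 6])

    for i0 in range(1, L + 1):
        for j0 in range(1, n + 1):
            rec("M", i0, j0, 0.0)
    return np.asarray(out)


def brute_force_overlaps(seqs: list[str], min_overlap: int) -> set[tuple[int, int, int]]:
    """All (i, j, o): maximal exact suffix-prefix overlap o >= min_overlap.

    'X' never matches, mirroring the package's overlap semantics.
    """
    out = set()
    for i, a in enumerate(seqs):
        for j, b in enumerate(seqs):
            if i == j:
                continue
            for o in range(min(len(a), len(b)), min_overlap - 1, -1):
                tail = a[len(a) - o:]
                if tail == b[:o] and "X" not in tail:
                    out.add((i, j, o))
                    break
    return out


def brute_force_seeds(scoring, reads: list[str], k: int, theta: float):
    """All-window, all-read-position seed scan under the GBMR4 pre-filter."""
    found = set()
    for i0 in range(1, scoring.L - k + 2):
        window = scoring.emit_M[i0:i0 + k]
        max_sc = float(window.max(axis=1).sum())
        if max_sc <= 0.0:
            continue
        cons_key = "".join(
            str(GBMR4[AMINO_ACIDS[int(np.argmax(window[t]))]]) for t in range(k))
        for h, seq in enumerate(reads):
            for j0 in range(len(seq) - k + 1):
                gram = seq[j0:j0 + k]
                if "".join(str(GBMR4.get(c, 4)) for c in gram) != cons_key:
                    continue
                sc = 0.0
                ok = True
                for t, c in enumerate(gram):
                    if c not in AMINO_ACIDS:
                        ok = False
                        break
                    sc += window[t, AMINO_ACIDS.index(c)]
                if ok and sc >= theta * max_sc:
                    found.add((h, j0, i0))
    return found


def brute_force_best_placement(read: str, contig: str, min_portion: float,
                               max_mismatch: int):
    """Best ungapped placement over every offset, or None."""
    best = None
    for off in range(-(len(read) - 1), len(contig)):
        lo = max(0, -off)
        hi = min(len(read), len(contig) - off)
        ov = hi - lo
        if ov <= 0 or ov / len(read) <= min_portion:
            continue
        mism = sum(1 for p in range(lo, hi)
                   if read[p] != contig[off + p] or read[p] == "X"
                   or contig[off + p] == "X")
        if mism > max_mismatch:
            continue
        cand = (mism, -ov, off)
        if best is None or cand < best:
            best = cand
    return best


def brute_force_n50(lengths) -> int:
    if not lengths:
        return 0
    total = sum(lengths)
    for ln in sorted(lengths, reverse=True):
        covered = sum(x for x in lengths if x >= ln)
        if covered * 2 >= total:
            return ln
    return min(lengths)


def max_kgram_emission(scoring, i0: int, k: int) -> float:
    """Max log-odds over all 20**k emitted k-peptides (exhaustive)."""
    best = -np.inf
    for combo in itertools.product(range(20), repeat=k):
        s = sum(scoring.emit_M[i0 + t, a] for t, a in enumerate(combo))
        best = max(best, s)
    return float(best)
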