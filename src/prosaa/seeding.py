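"""Seeding: anchoring alignments on high-scoring k-gram matches.

For each window of k consecutive match states, the *maximum seed score* is
the highest log-odds any k-residue emission can achieve there (match
emissions only; transitions within conserved windows are near-deterministic
and are deliberately excluded — see docs/methods.md). A score scale theta in
(0, 1] applied to that maximum gives a position-specific seeding cutoff.

Candidate reads are pre-filtered by the window's reduced-alphabet (GBMR4)
consensus k-gram — one index lookup per window — then rescored in the full
alphabet. Windows whose maximum seed score is not positive are skipped: they
carry no anchoring signal and a positive-scale cutoff is meaningless there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alphabet import AMINO_ACIDS, GBMR4
from .hmmio import ScoringModel
from .readdb import KGramIndex


@dataclass(frozen=True)
class SeedMatch:
    """A k-gram anchor between model window [i0, i0+k-1] and a read."""

    read: int  # read handle
    j0: int  # 0-based read offset
    i0: int  # 1-based model match position
    k: int
    seed_score: float  # bits
    max_score: float  # the window's maximum seed score, bits


def max_seed_score(model: ScoringModel, i0: int, k: int) -> float:
    """Highest log-odds of any k-residue emission from match window i0..i0+k-1."""
    if not (1 <= i0 and i0 + k - 1 <= model.L):
        raise ValueError(f"window [{i0}, {i0 + k - 1}] outside [1, {model.L}]")
    return float(np.max(model.emit_M[i0:i0 + k], axis=1).sum())


def find_seeds(model: ScoringModel, index: KGramIndex, theta: float = 0.8) -> list[SeedMatch]:
    """All seeds passing the position-specific cutoff ``theta * max_seed_score``.

    Output is sorted by descending seed score, ties by (read handle, i0, j0).
    """
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must be in (0, 1]")
    k = index.k
    db = index.db
    seeds: list[SeedMatch] = []
    emit = model.emit_M
    for i0 in range(1, model.L - k + 2):
        window = emit[i0:i0 + k]
        max_sc = float(np.max(window, axis=1).sum())
        if max_sc <= 0.0:
            continue
        cutoff = theta * max_sc
        cons = np.argmax(window, axis=1)
        key = "".join(str(GBMR4[AMINO_ACIDS[a]]) for a in cons)
        for handle, j0 in index.table.get(key, ()):
            enc = db.encoded(handle)
            sc = 0.0
            ok = True
            for t in range(k):
                a = enc[j0 + t]
                if a < 0:
                    ok = False
                    break
                sc += window[t, a]
            if ok and sc >= cutoff:
                seeds.append(SeedMatch(handle, j0, i0, k, float(sc), max_sc))
    seeds.sort(key=lambda s: (-s.seed_score, s.read, s.i0, s.j0))
    return seeds
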