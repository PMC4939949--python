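"""Full-model verification of contigs and recruitment of reads onto them.

Verification rescores each candidate contig with the unbanded forward
algorithm (all parses, no seeding/banding constraints) and converts the
score to an E-value via a Gumbel fit to null forward scores of
background-sampled sequences; the effective database size is the number of
candidate contigs of the family. A hook lets callers delegate verification
to an external HMMER-compatible searcher instead.

Recruitment ("mapping") places each read ungapped against every trusted
contig at every offset, including overhangs at contig ends; a read is
recruited iff some placement covers more than ``min_portion`` of the read
(strict) with at most ``max_mismatch`` substitutions ('X' always counts as a
mismatch). Reads recruited by several families keep only the assignment to
the family with the most significant contig E-value.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .banded_align import forward_score
from .hmmio import ScoringModel
from .readdb import ReadDatabase
from .saa_engine import Contig, sample_null_scores


@dataclass
class VerifiedContig:
    """A contig passing full-model significance."""

    contig: Contig
    forward: float  # full-model forward score, bits
    evalue: float
    family: str

    @property
    def seq(self) -> str:
        return self.contig.seq


@dataclass(frozen=True)
class ReadAssignment:
    """A read recruited onto a verified contig."""

    read: int  # handle
    read_id: str
    contig_index: int  # index into the verified-contig list
    family: str
    offset: int  # contig coordinate of the read's first residue (may be < 0)
    mismatches: int
    fraction: float  # mapped fraction of the read
    evalue: float  # the contig's E-value (used for family resolution)


def verify_contigs(contigs: list[Contig], model: ScoringModel,
                   evalue_cutoff: float = 0.01, null_sample_size: int = 200,
                   seed: int = 0, external=None) -> list[VerifiedContig]:
    """Keep contigs whose full-model E-value passes the cutoff.

    ``external``, if given, is a callable ``(contigs, model) -> list of
    E-values`` (e.g. wrapping an HMMER-compatible search) that replaces the
    internal null-calibrated scoring.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    if not contigs:
        return []
    if external is not None:
        evalues = external(contigs, model)
        scores = [float("nan")] * len(contigs)
    else:
        rng = np.random.default_rng(seed)
        lengths = rng.choice([len(c.seq) for c in contigs], size=null_sample_size)
        null = sample_null_scores(model, lengths, rng, scorer="forward")
        null = null[np.isfinite(null)]
        scores = [forward_score(model, c.seq) for c in contigs]
        n_eff = len(contigs)
        if null.size >= 30:
            loc, scale = stats.gumbel_r.fit(null)
            evalues = [n_eff * float(stats.gumbel_r.sf(s, loc=loc, scale=scale))
                       for s in scores]
        else:
            evalues = [n_eff * (1 + np.sum(null >= s)) / (null.size + 1)
                       for s in scores]
    return [VerifiedContig(c, s, e, c.family)
            for c, s, e in zip(contigs, scores, evalues)
            if e <= evalue_cutoff]


def _evaluate_placement(read_seq: str, contig_seq: str, offset: int,
                        min_portion: float, max_mismatch: int):
    """(mismatches, overlap) for an ungapped placement, or None if it fails."""
    lo = max(0, -offset)  # first read position inside the contig
    hi = min(len(read_seq), len(contig_seq) - offset)
    overlap = hi - lo
    if overlap <= 0 or overlap / len(read_seq) <= min_portion:
        return None
    mism = 0
    for p in range(lo, hi):
        rc = read_seq[p]
        cc = contig_seq[offset + p]
        if rc != cc or rc == "X" or cc == "X":
            mism += 1
            if mism > max_mismatch:
                return None
    return mism, overlap


def _best_placement(read_seq: str, contig_seq: str, offsets,
                    min_portion: float, max_mismatch: int):
    best = None
    for off in offsets:
        res = _evaluate_placement(read_seq, contig_seq, off, min_portion, max_mismatch)
        if res is None:
            continue
        mism, overlap = res
        cand = (mism, -overlap, off)
        if best is None or cand < best:
            best = cand
    return best


def map_reads(db: ReadDatabase, verified: list[VerifiedContig],
              max_mismatch: int = 3, min_portion: float = 0.6) -> list[ReadAssignment]:
    """Recruit database reads onto trusted contigs (best placement per contig).

    Candidate placements are found through an exact s-mer prefilter: any
    placement with overlap >= floor(min_portion*len)+1 and <= max_mismatch
    mismatches must contain an exact run of ceil((ov - mm) / (mm + 1))
    residues (pigeonhole), so seeding on runs of that length is lossless.
    Very short reads fall back to scanning every offset.
    """
    if not verified:
        return []
    min_read = min(len(r.seq) for r in db)
    min_ov = int(np.floor(min_portion * min_read)) + 1
    s = int(np.ceil((min_ov - max_mismatch) / (max_mismatch + 1)))
    brute = s < 3
    smer: dict[str, list[tuple[int, int]]] = defaultdict(list)
    if not brute:
        for ci, vc in enumerate(verified):
            cseq = vc.seq
            for p in range(len(cseq) - s + 1):
                win = cseq[p:p + s]
                if "X" not in win:
                    smer[win].append((ci, p))
    out: list[ReadAssignment] = []
    for read in db:
        rseq = read.seq
        if brute:
            cand: dict[int, set[int]] = {
                ci: set(range(-(len(rseq) - 1), len(vc.seq)))
                for ci, vc in enumerate(verified)}
        else:
            cand = defaultdict(set)
            for p in range(len(rseq) - s + 1):
                win = rseq[p:p + s]
                if "X" in win:
                    continue
                for ci, cp in smer.get(win, ()):
                    cand[ci].add(cp - p)
        for ci, offsets in cand.items():
            vc = verified[ci]
            best = _best_placement(rseq, vc.seq, sorted(offsets),
                                   min_portion, max_mismatch)
            if best is not None:
                mism, neg_ov, off = best
                out.append(ReadAssignment(
                    read=read.handle, read_id=read.id, contig_index=ci,
                    family=vc.family, offset=off, mismatches=mism,
                    fraction=-neg_ov / len(rseq), evalue=vc.evalue))
    out.sort(key=lambda a: (a.read, a.family, a.contig_index))
    return out


def resolve_multi_family(assignments: list[ReadAssignment]) -> list[ReadAssignment]:
    """Keep one assignment per read: most significant contig E-value, ties by
    fewer mismatches, then lexicographic family name."""
    best: dict[int, ReadAssignment] = {}
    for a in assignments:
        cur = best.get(a.read)
        if cur is None:
            best[a.read] = a
            continue
        if (a.evalue, a.mismatches, a.family) < (cur.evalue, cur.mismatches, cur.family):
            best[a.read] = a
    return sorted(best.values(), key=lambda a: a.read)
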