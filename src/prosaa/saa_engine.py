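"""The simultaneous alignment and assembly (SAA) loop.

Each seed initialises a single-read contig that is then alternately extended
C- and N-terminally along the pre-built extension links. After every
extension the contig is re-scored with the banded Viterbi DP anchored at the
seed; a branch is abandoned when its score drops more than ``dropoff`` bits
below the branch's best, when the per-direction extension depth exceeds
``max_depth``, or when the (read, model-position) pair was already consumed
by an equal-or-better contig. Every maximal path emits the best-scoring
contig state it passed through.

Significance of a contig score is assessed against an empirical null of
background-sampled sequences via an extreme-value (Gumbel) fit; these
P-values rank candidates (the banded, seeded score is not a calibrated
likelihood) — trusted output is gated later by full-model verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import _dp
from ._alphabet import encode
from .banded_align import DEFAULT_BAND, banded_score
from .hmmio import ScoringModel
from .readdb import ExtensionLinkIndex, KGramIndex, ReadDatabase
from .seeding import SeedMatch, find_seeds


@dataclass
class AssemblyParams:
    """Tuning knobs of the search; defaults are the tool's standard settings."""

    k: int = 6  # seed length (reduced alphabet)
    theta: float = 0.8  # seed score scale
    min_overlap: int = 10  # minimum read overlap for assembly
    band: int = DEFAULT_BAND  # alignment band size
    max_depth: int = 5  # extension depth per direction
    dropoff: float = 10.0  # bits below branch best before abandoning
    pvalue_cutoff: float = 0.05
    evalue_cutoff: float = 0.01
    null_sample_size: int = 200
    redundancy_bucket: int = 10  # model positions per redundancy bin
    max_branches: int = 500  # per-seed guard against pathological branching

    def __post_init__(self):
        if not (0.0 < self.theta <= 1.0):
            raise ValueError("theta must be in (0, 1]")
        for name in ("k", "min_overlap", "band", "pvalue_cutoff", "evalue_cutoff",
                     "dropoff", "null_sample_size", "redundancy_bucket"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


@dataclass
class Contig:
    """An assembled peptide contig and the reads that tile it exactly."""

    seq: str
    reads: list[tuple[int, int]]  # (read handle, offset in contig), sorted
    family: str
    score: float  # best banded Viterbi score, bits
    anchor: tuple[int, int] = (1, 0)  # (model i0, contig offset of seed)
    depth_fwd: int = 0
    depth_rev: int = 0
    pvalue: float | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class _Branch:
    seq: str
    reads: list[tuple[int, int]]
    i0: int  # model anchor (1-based)
    j_anchor: int  # contig offset of seed start
    score: float
    best: float
    snap_seq: str
    snap_reads: list[tuple[int, int]]
    snap_anchor: int
    snap_fwd: int
    snap_rev: int
    depth_fwd: int = 0
    depth_rev: int = 0
    open_fwd: bool = True
    open_rev: bool = True
    turn: str = "fwd"


def _bucket(pos: int, width: int) -> int:
    return int(round(pos / width)) * width


def assemble_family(model: ScoringModel, db: ReadDatabase, kindex: KGramIndex,
                    links: ExtensionLinkIndex, params: AssemblyParams | None = None,
                    seeds: list[SeedMatch] | None = None) -> list[Contig]:
    """Run the SAA loop for one family; returns candidate contigs."""
    params = params or AssemblyParams()
    if seeds is None:
        seeds = find_seeds(model, kindex, params.theta)
    consumed: dict[tuple[int, int], float] = {}
    out: dict[str, Contig] = {}

    for seed in seeds:
        start_pos = seed.i0 - seed.j0  # model position of the read's first residue
        skey = (seed.read, _bucket(start_pos, params.redundancy_bucket))
        if skey in consumed:
            continue
        read = db[seed.read]
        sc = banded_score(model, read.seq, (seed.i0, seed.j0), params.band)
        br = _Branch(
            seq=read.seq, reads=[(seed.read, 0)], i0=seed.i0, j_anchor=seed.j0,
            score=sc, best=sc, snap_seq=read.seq, snap_reads=[(seed.read, 0)],
            snap_anchor=seed.j0, snap_fwd=0, snap_rev=0,
        )
        visited: dict[tuple[int, int], float] = {skey: sc}
        n_branches = 1
        stack = [br]
        while stack:
            b = stack.pop()
            if b.turn == "fwd":
                direction = "fwd" if b.open_fwd else ("rev" if b.open_rev else None)
            else:
                direction = "rev" if b.open_rev else ("fwd" if b.open_fwd else None)
            if direction is None:
                _emit(b, model, params, consumed, out)
                continue
            depth = b.depth_fwd if direction == "fwd" else b.depth_rev
            children: list[_Branch] = []
            if depth < params.max_depth and n_branches < params.max_branches:
                children = _extend(b, direction, model, db, links, params,
                                   consumed, visited)
            if children:
                n_branches += len(children)
                stack.extend(children)
            else:
                if direction == "fwd":
                    b.open_fwd = False
                else:
                    b.open_rev = False
                b.turn = "rev" if direction == "fwd" else "fwd"
                stack.append(b)
    return sorted(out.values(), key=lambda c: (-c.score, c.seq))


def _extend(b: _Branch, direction: str, model: ScoringModel, db: ReadDatabase,
            links: ExtensionLinkIndex, params: AssemblyParams,
            consumed: dict, visited: dict) -> list[_Branch]:
    children: list[_Branch] = []
    if direction == "fwd":
        last_h, last_off = b.reads[-1]
        cands = links.links_fwd.get(last_h, ())
    else:
        first_h, first_off = b.reads[0]
        cands = links.links_rev.get(first_h, ())
    for other_h, o in cands:
        other = db[other_h]
        if direction == "fwd":
            succ_start = last_off + len(db[last_h].seq) - o
            ext = succ_start + len(other.seq) - len(b.seq)
            if ext <= 0:
                continue
            new_seq = b.seq + other.seq[-ext:]
            new_reads = b.reads + [(other_h, succ_start)]
            new_anchor = b.j_anchor
            read_start_model_pos = b.i0 + (succ_start - b.j_anchor)
        else:
            # predecessor ends o residues into the current first read
            pred_start = first_off + o - len(other.seq)
            ext = -pred_start
            if ext <= 0:
                continue
            new_seq = other.seq[:ext] + b.seq
            new_reads = [(other_h, 0)] + [(h, off + ext) for h, off in b.reads]
            new_anchor = b.j_anchor + ext
            read_start_model_pos = b.i0 + (0 - new_anchor)
        key = (other_h, _bucket(read_start_model_pos, params.redundancy_bucket))
        new_score = banded_score(model, new_seq, (b.i0, new_anchor), params.band)
        if consumed.get(key, -np.inf) >= new_score:
            continue
        if visited.get(key, -np.inf) >= new_score:
            continue
        visited[key] = new_score
        new_best = max(b.best, new_score)
        if new_score < new_best - params.dropoff:
            continue
        child = replace(
            b,
            seq=new_seq, reads=new_reads, j_anchor=new_anchor, score=new_score,
            best=new_best,
            depth_fwd=b.depth_fwd + (direction == "fwd"),
            depth_rev=b.depth_rev + (direction == "rev"),
            turn="rev" if direction == "fwd" else "fwd",
        )
        child.reads = list(new_reads)
        if new_score > b.best:
            child.snap_seq = new_seq
            child.snap_reads = list(new_reads)
            child.snap_anchor = new_anchor
            child.snap_fwd = child.depth_fwd
            child.snap_rev = child.depth_rev
        children.append(child)
    return children


def _emit(b: _Branch, model: ScoringModel, params: AssemblyParams,
          consumed: dict, out: dict) -> None:
    contig = Contig(
        seq=b.snap_seq, reads=sorted(b.snap_reads, key=lambda t: (t[1], t[0])),
        family=model.name, score=b.best, anchor=(b.i0, b.snap_anchor),
        depth_fwd=b.snap_fwd, depth_rev=b.snap_rev,
    )
    prev = out.get(contig.seq)
    if prev is None or contig.score > prev.score:
        out[contig.seq] = contig
    for h, off in contig.reads:
        pos = b.i0 + (off - b.snap_anchor)
        key = (h, _bucket(pos, params.redundancy_bucket))
        if consumed.get(key, -np.inf) < contig.score:
            consumed[key] = contig.score


# ---------------------------------------------------------------------------
# recalibration (contig-level merging)


def _max_overlap(a: str, b: str, min_overlap: int) -> int:
    """Maximal o >= min_overlap with suffix(a, o) == prefix(b, o), else 0."""
    for o in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-o:] == b[:o] and "X" not in a[-o:]:
            return o
    return 0


def _overlaps_of(a_idx: int, pool: dict[int, Contig], prefix_map: dict,
                 min_overlap: int) -> list[tuple[int, int, int]]:
    """(overlap, a_idx, b_idx) candidates found via the prefix lookup."""
    a = pool[a_idx]
    seen: set[int] = set()
    found: list[tuple[int, int, int]] = []
    n = len(a.seq)
    for start in range(0, n - min_overlap + 1):  # descending overlap
        key = a.seq[start:start + min_overlap]
        for b_idx in prefix_map.get(key, ()):
            if b_idx == a_idx or b_idx in seen or b_idx not in pool:
                continue
            o = n - start
            b = pool[b_idx]
            tail = a.seq[start:]
            if o <= len(b.seq) and tail == b.seq[:o] and "X" not in tail:
                seen.add(b_idx)
                found.append((o, a_idx, b_idx))
    return found


def _try_merge(a: Contig, b: Contig, o: int) -> Contig | None:
    shift = len(a.seq) - o
    if shift + len(b.seq) <= len(a.seq):
        return None
    seq = a.seq + b.seq[o:]
    reads = dict(a.reads)
    for h, off in b.reads:
        new_off = off + shift
        if h in reads and reads[h] != new_off:
            return None  # inconsistent placement of a shared read
        reads[h] = new_off
    merged = Contig(
        seq=seq, reads=sorted(((h, off) for h, off in reads.items()),
                              key=lambda t: (t[1], t[0])),
        family=a.family, score=max(a.score, b.score), anchor=a.anchor,
        depth_fwd=max(a.depth_fwd, b.depth_fwd), depth_rev=max(a.depth_rev, b.depth_rev),
    )
    return merged


def recalibrate(contigs: list[Contig], min_overlap: int = 10) -> list[Contig]:
    """Greedily merge contigs sharing an exact overlap (longest first).

    Contigs sharing a terminal read merge through that read's placement;
    identical sequences collapse to one survivor with the union of reads; the
    output is substring-free. A merge that would place a shared read
    inconsistently is skipped and both inputs are kept.
    """
    # collapse identical sequences first
    by_seq: dict[str, Contig] = {}
    for c in contigs:
        prev = by_seq.get(c.seq)
        if prev is None:
            by_seq[c.seq] = c
        else:
            reads = dict(prev.reads)
            reads.update(dict(c.reads))
            by_seq[c.seq] = replace(
                prev, reads=sorted(reads.items(), key=lambda t: (t[1], t[0])),
                score=max(prev.score, c.score))
    import heapq

    pool: dict[int, Contig] = dict(enumerate(by_seq.values()))
    next_idx = len(pool)
    prefix_map: dict[str, list[int]] = {}
    for idx, c in pool.items():
        if len(c.seq) >= min_overlap:
            prefix_map.setdefault(c.seq[:min_overlap], []).append(idx)
    heap: list[tuple[int, int, int]] = []
    for idx in list(pool):
        for o, ia, ib in _overlaps_of(idx, pool, prefix_map, min_overlap):
            heapq.heappush(heap, (-o, ia, ib))
    blocked: set[tuple[int, int]] = set()
    # a merge A+B keeps A's prefix, so stale entries targeting A are redirected
    # to the merged contig and revalidated; entries targeting B (whose prefix
    # is now interior) or leaving a consumed contig are dropped.
    alias: dict[int, int] = {}
    while heap:
        no, ia, ib = heapq.heappop(heap)
        o = -no
        while ib in alias:
            ib = alias[ib]
        if ia not in pool or ib not in pool or ia == ib or (ia, ib) in blocked:
            continue
        a, bb = pool[ia], pool[ib]
        if not (o <= min(len(a.seq), len(bb.seq)) and a.seq[-o:] == bb.seq[:o]):
            continue  # stale entry after a redirect
        merged = _try_merge(a, bb, o)
        if merged is None:
            blocked.add((ia, ib))
            continue
        del pool[ia], pool[ib]
        midx = next_idx
        next_idx += 1
        pool[midx] = merged
        alias[ia] = midx
        if len(merged.seq) >= min_overlap:
            prefix_map.setdefault(merged.seq[:min_overlap], []).append(midx)
        for o2, xa, xb in _overlaps_of(midx, pool, prefix_map, min_overlap):
            heapq.heappush(heap, (-o2, xa, xb))
    # substring filter
    ordered = sorted(pool.values(), key=lambda c: (-len(c.seq), c.seq))
    keep: list[Contig] = []
    for c in ordered:
        if not any(c.seq in k.seq for k in keep):
            keep.append(c)
    return sorted(keep, key=lambda c: (-c.score, c.seq))


# ---------------------------------------------------------------------------
# score significance


def sample_null_scores(model: ScoringModel, lengths, rng: np.random.Generator,
                       scorer: str = "viterbi") -> np.ndarray:
    """Scores of background-sampled random peptides (the calibration sample)."""
    bg = model.background
    out = np.empty(len(lengths))
    for idx, n in enumerate(lengths):
        tgt = rng.choice(20, size=int(n), p=bg).astype(np.int64)
        if scorer == "viterbi":
            s, _, _ = _dp.viterbi_score(model.emit_M, model.emit_I, model.tr,
                                        tgt, 1, 1, -1)
        elif scorer == "forward":
            s = _dp.forward_score_kernel(model.emit_M, model.emit_I, model.tr, tgt)
        else:
            raise ValueError(f"unknown scorer {scorer!r}")
        out[idx] = s
    return out


def score_pvalue(model: ScoringModel, score: float, calibration: np.ndarray) -> float:
    """P-value of ``score`` under a Gumbel fit to the calibration sample.

    With fewer than 30 calibration scores the fit is refused and an empirical
    rank P-value ``(1 + #{null >= score}) / (N + 1)`` is returned instead.
    P is monotone non-increasing in the score either way.
    """
    calibration = np.asarray(calibration, dtype=float)
    calibration = calibration[np.isfinite(calibration)]
    n = calibration.size
    if n < 30:
        if n == 0:
            return 1.0
        return float((1 + np.sum(calibration >= score)) / (n + 1))
    loc, scale = stats.gumbel_r.fit(calibration)
    return float(stats.gumbel_r.sf(score, loc=loc, scale=scale))
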