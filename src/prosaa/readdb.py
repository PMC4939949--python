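"""The short-peptide read database and its two search indexes.

The SAA loop needs (a) a reduced-alphabet k-gram index to anchor seeds and
(b) the suffix-prefix "extension links" between reads — conceptually the
edge set of the overlap graph. Links record only the *maximal* exact overlap
per ordered read pair, built via a prefix-keyed lookup rather than an
all-pairs scan.
"""

from __future__ import annotations

import pickle
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._alphabet import AA_TO_INDEX, encode, is_valid_peptide, reduce_gbmr4

INDEX_FORMAT_VERSION = 1


class ReadLoadError(ValueError):
    pass


@dataclass
class PeptideRead:
    id: str
    seq: str  # uppercase, 20 amino acids plus 'X'
    handle: int  # stable integer handle within the database


class ReadDatabase:
    """An ordered collection of peptide reads with stable integer handles."""

    def __init__(self, reads: list[PeptideRead]):
        self.reads = reads
        self.total_residues = sum(len(r.seq) for r in reads)
        self._encoded: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.reads)

    def __getitem__(self, handle: int) -> PeptideRead:
        return self.reads[handle]

    def __iter__(self):
        return iter(self.reads)

    def encoded(self, handle: int) -> np.ndarray:
        arr = self._encoded.get(handle)
        if arr is None:
            arr = encode(self.reads[handle].seq)
            self._encoded[handle] = arr
        return arr


def load_reads(path: str | Path) -> ReadDatabase:
    """Load a peptide FASTA into a :class:`ReadDatabase`.

    Duplicate ids are deduplicated by suffixing ``_2``, ``_3``, ...; an
    apparently nucleotide file (>=95% ACGTN residues) is rejected.
    """
    reads: list[PeptideRead] = []
    seen: dict[str, int] = {}
    nuc = 0
    total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ReadLoadError(f"record {rec.id!r} is empty")
        if not is_valid_peptide(seq):
            bad = sorted({c for c in seq if c not in AA_TO_INDEX and c != "X"})
            raise ReadLoadError(
                f"record {rec.id!r} contains non-amino-acid characters {bad}"
            )
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            rid = f"{rid}_{seen[rec.id]}"
        else:
            seen[rid] = 1
        nuc += sum(seq.count(c) for c in "ACGTN")
        total += len(seq)
        reads.append(PeptideRead(rid, seq, len(reads)))
    if not reads:
        raise ReadLoadError(f"{path}: no FASTA records found")
    if total > 0 and nuc / total >= 0.95:
        raise ReadLoadError(
            f"{path}: >=95% of residues are ACGTN — input looks like nucleotide "
            "sequence, expected peptides"
        )
    return ReadDatabase(reads)


@dataclass
class KGramIndex:
    """Reduced-alphabet k-gram -> (read handle, offset) posting lists."""

    k: int
    db: ReadDatabase
    table: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def n_entries(self) -> int:
        return sum(len(v) for v in self.table.values())


def build_kgram_index(db: ReadDatabase, k: int = 6) -> KGramIndex:
    """Index every length-k window of every read under its GBMR4 class string.

    Reads shorter than k simply contribute no entries. Windows containing 'X'
    are stored (class '4') but can never match a model-consensus key.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    table: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for read in db:
        red = reduce_gbmr4(read.seq)
        for off in range(0, len(red) - k + 1):
            table[red[off:off + k]].append((read.handle, off))
    return KGramIndex(k=k, db=db, table=dict(table))


@dataclass
class ExtensionLinkIndex:
    """Maximal exact suffix-prefix overlaps of length >= min_overlap.

    ``links_fwd[h]`` lists ``(successor handle, overlap)`` pairs: the last
    ``overlap`` residues of read ``h`` equal the first ``overlap`` residues of
    the successor. ``links_rev`` is the exact transpose.
    """

    min_overlap: int
    links_fwd: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    links_rev: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def n_links(self) -> int:
        return sum(len(v) for v in self.links_fwd.values())


def build_extension_links(db: ReadDatabase, min_overlap: int = 10) -> ExtensionLinkIndex:
    """Build the overlap-graph edges via a prefix-keyed candidate lookup.

    For each suffix position of each read, candidate successors are fetched by
    their first ``min_overlap`` residues; the full overlap is then verified
    exactly. Overlap regions containing 'X' never match. Scanning suffix
    positions left to right yields the maximal overlap per ordered pair first;
    shorter sub-overlaps are discarded. Self-links are excluded.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    prefix_map: dict[str, list[int]] = defaultdict(list)
    for read in db:
        if len(read.seq) >= min_overlap:
            key = read.seq[:min_overlap]
            if "X" not in key:
                prefix_map[key].append(read.handle)
    links_fwd: dict[int, list[tuple[int, int]]] = defaultdict(list)
    links_rev: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for r1 in db:
        seen: set[int] = set()
        n1 = len(r1.seq)
        for start in range(0, n1 - min_overlap + 1):
            o = n1 - start
            key = r1.seq[start:start + min_overlap]
            for h2 in prefix_map.get(key, ()):
                if h2 == r1.handle or h2 in seen:
                    continue
                r2 = db[h2]
                if o > len(r2.seq):
                    continue
                tail = r1.seq[start:]
                if tail == r2.seq[:o] and "X" not in tail:
                    links_fwd[r1.handle].append((h2, o))
                    links_rev[h2].append((r1.handle, o))
                    seen.add(h2)
    for d in (links_fwd, links_rev):
        for v in d.values():
            v.sort(key=lambda t: (-t[1], t[0]))
    return ExtensionLinkIndex(min_overlap, dict(links_fwd), dict(links_rev))


# ---------------------------------------------------------------------------
# persistence (CLI `build-index` sidecar)


def save_indexes(path: str | Path, db: ReadDatabase, kindex: KGramIndex,
                 links: ExtensionLinkIndex) -> None:
    payload = {
        "version": INDEX_FORMAT_VERSION,
        "reads": [(r.id, r.seq) for r in db],
        "k": kindex.k,
        "table": kindex.table,
        "min_overlap": links.min_overlap,
        "links_fwd": links.links_fwd,
        "links_rev": links.links_rev,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=4)


def load_indexes(path: str | Path) -> tuple[ReadDatabase, KGramIndex, ExtensionLinkIndex]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index version {payload.get('version')!r}")
    db = ReadDatabase([PeptideRead(i, s, h) for h, (i, s) in enumerate(payload["reads"])])
    kindex = KGramIndex(payload["k"], db, payload["table"])
    links = ExtensionLinkIndex(payload["min_overlap"], payload["links_fwd"], payload["links_rev"])
    return db, kindex, links
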