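"""Evaluation and abundance mathematics.

Recall = TP/(TP+FN), Precision = TP/(TP+FP) and the F-measure (their
harmonic mean) over predicted vs ground-truth homologous read sets; read-
and contig-level precision (r.P., c.P.) against a verifier; N50 and N50
normalised by query model length (x3 for nucleotide contigs); and per-family
abundance as Reads Per Kilobase per Million (RPKM), with the model length
converted to its nucleotide-equivalent kilobases by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class EvalReport:
    """Read-level confusion counts and derived rates (fractions in [0, 1])."""

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f_measure: float
    undefined_recall: bool = False
    undefined_precision: bool = False
    per_family: dict = field(default_factory=dict)

    def as_percentages(self) -> tuple[float, float, float]:
        """(recall, precision, F) as percentages rounded to 0.1."""
        return (round(self.recall * 100, 1), round(self.precision * 100, 1),
                round(self.f_measure * 100, 1))


@dataclass
class AbundanceRecord:
    family: str
    count: int
    model_len: int  # match states
    rpkm: float


@dataclass
class AssemblyStats:
    lengths: list[int]
    n50: int
    normalized_n50: float
    true_contigs: int
    total_contigs: int
    true_reads: int
    total_reads: int
    contig_precision: float
    read_precision: float
    empty: bool = False


def f_measure(recall: float, precision: float) -> float:
    if recall + precision == 0 or math.isnan(recall) or math.isnan(precision):
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def recall_precision_f(predicted: set, truth: set) -> EvalReport:
    """Exact set arithmetic over a common read universe.

    TP are predicted homologous reads, FP predicted non-homologous reads,
    FN unpredicted homologous reads. An empty truth set leaves recall
    undefined (NaN, flagged); an empty prediction leaves precision undefined.
    """
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    undef_r = (tp + fn) == 0
    undef_p = (tp + fp) == 0
    recall = float("nan") if undef_r else tp / (tp + fn)
    precision = float("nan") if undef_p else tp / (tp + fp)
    f = 0.0 if (undef_r or undef_p) else f_measure(recall, precision)
    return EvalReport(tp, fp, fn, recall, precision, f, undef_r, undef_p)


def rpkm(count: int, model_len: int, total_reads: int, basis: str = "nt") -> float:
    """Reads per kilobase (of model length) per million database reads.

    ``basis='nt'`` (default) converts the match-state count to nucleotide
    kilobases (aa x 3 / 1000); ``basis='aa'`` uses amino-acid "kilobases".
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if model_len <= 0:
        raise ValueError("model_len must be positive")
    if basis == "nt":
        kb = model_len * 3 / 1000.0
    elif basis == "aa":
        kb = model_len / 1000.0
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return count / kb / (total_reads / 1e6)


def n50(lengths) -> int:
    """Smallest length l such that contigs of length >= l hold >= half the total.

    Empty input is defined as 0 (flagged by callers via AssemblyStats.empty).
    """
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        return 0
    half = sum(lengths) / 2.0
    acc = 0
    for ln in lengths:
        acc += ln
        if acc >= half:
            return ln
    return lengths[-1]


def normalized_n50(lengths, model_len: int, space: str = "protein") -> float:
    """N50 over the query model length; nucleotide contigs use 3x the length."""
    if model_len <= 0:
        raise ValueError("model_len must be positive")
    if space == "protein":
        denom = model_len
    elif space == "nucleotide":
        denom = 3 * model_len
    else:
        raise ValueError(f"unknown space {space!r}")
    return n50(lengths) / denom


def contig_read_precision(contigs, truth_verifier, assignments,
                          model_len: int | None = None,
                          min_len: int | None = None,
                          space: str = "protein") -> AssemblyStats:
    """r.P. / c.P. and N50 statistics for a contig set.

    ``truth_verifier`` is a callable ``contig -> bool`` (e.g. full-model
    verification at the trusted E-value cutoff); true reads are the
    assignments landing on true contigs. ``min_len`` applies the strict
    "longer than" length filter (60 aa / 180 nt in the benchmark protocol)
    before any counting.
    """
    idx = list(range(len(contigs)))
    if min_len is not None:
        idx = [i for i in idx if len(contigs[i].seq) > min_len]
    kept = {i: contigs[i] for i in idx}
    truth_flags = {i: bool(truth_verifier(c)) for i, c in kept.items()}
    true_idx = {i for i, ok in truth_flags.items() if ok}
    lengths = [len(kept[i].seq) for i in idx]
    total_reads_set = set()
    true_reads_set = set()
    for a in assignments:
        if a.contig_index in kept:
            total_reads_set.add(a.read)
            if a.contig_index in true_idx:
                true_reads_set.add(a.read)
    n_total_c = len(idx)
    n_true_c = len(true_idx)
    stats = AssemblyStats(
        lengths=lengths,
        n50=n50(lengths),
        normalized_n50=(normalized_n50(lengths, model_len, space)
                        if model_len else 0.0),
        true_contigs=n_true_c,
        total_contigs=n_total_c,
        true_reads=len(true_reads_set),
        total_reads=len(total_reads_set),
        contig_precision=(n_true_c / n_total_c) if n_total_c else 0.0,
        read_precision=(len(true_reads_set) / len(total_reads_set))
        if total_reads_set else 0.0,
        empty=(n_total_c == 0),
    )
    return stats


def abundance_table(assignments, model_lens: dict[str, int], total_reads: int,
                    basis: str = "nt") -> list[AbundanceRecord]:
    """Per-family read counts and RPKM from resolved read assignments."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.family] = counts.get(a.family, 0) + 1
    out = []
    for fam in sorted(model_lens):
        c = counts.get(fam, 0)
        out.append(AbundanceRecord(
            fam, c, model_lens[fam],
            rpkm(c, model_lens[fam], total_reads, basis) if c else 0.0))
    return out
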