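"""End-to-end search pipeline: seed, assemble, recalibrate, verify, map.

This is the library-level composition of the individual modules; the CLI is
a thin wrapper around it. For multi-family queries the read database and its
indexes are shared; assembly, significance filtering and verification run
per family, after which read recruitment is resolved across families by
most-significant contig E-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .banded_align import full_viterbi_score
from .hmmio import ProfileHMM, ScoringModel, to_scoring
from .metrics import AbundanceRecord, EvalReport, abundance_table, recall_precision_f
from .readdb import ReadDatabase, build_extension_links, build_kgram_index
from .saa_engine import (AssemblyParams, Contig, assemble_family, recalibrate,
                         sample_null_scores, score_pvalue)
from .verify_map import (ReadAssignment, VerifiedContig, map_reads,
                         resolve_multi_family, verify_contigs)

logger = logging.getLogger("prosaa")


@dataclass
class FamilyResult:
    family: str
    model_len: int
    contigs: list[Contig]  # candidates surviving the P-value filter
    verified: list[VerifiedContig]
    n_seeds: int
    n_candidates: int  # contigs before the P-value filter


@dataclass
class SearchResult:
    families: dict[str, FamilyResult]
    assignments: list[ReadAssignment]  # resolved: one family per read
    total_reads: int

    def recruited(self, family: str) -> set[str]:
        return {a.read_id for a in self.assignments if a.family == family}

    def abundance(self, basis: str = "nt") -> list[AbundanceRecord]:
        lens = {f: r.model_len for f, r in self.families.items()}
        return abundance_table(self.assignments, lens, self.total_reads, basis)


def search(models: dict[str, ProfileHMM] | list[ProfileHMM], db: ReadDatabase,
           params: AssemblyParams | None = None, seed: int = 0,
           kindex=None, links=None, external_verifier=None) -> SearchResult:
    """Search one or more family models against a peptide read database."""
    params = params or AssemblyParams()
    if isinstance(models, list):
        models = {m.name: m for m in models}
    if kindex is None:
        kindex = build_kgram_index(db, params.k)
    if links is None:
        links = build_extension_links(db, params.min_overlap)

    fam_results: dict[str, FamilyResult] = {}
    all_assignments: list[ReadAssignment] = []
    for fi, fam in enumerate(sorted(models)):
        scoring = to_scoring(models[fam])
        fam_seed = (seed * 9973 + fi) % (2**31 - 1)
        result = search_family(scoring, db, kindex, links, params, fam_seed,
                               external_verifier=external_verifier)
        fam_results[fam] = result
        assignments = map_reads(db, result.verified)
        all_assignments.extend(assignments)
        logger.info(
            "family %s: %d seeds, %d candidate contigs, %d past P-filter, "
            "%d verified, %d read placements", fam, result.n_seeds,
            result.n_candidates, len(result.contigs), len(result.verified),
            len(assignments))
    resolved = resolve_multi_family(all_assignments)
    return SearchResult(fam_results, resolved, len(db))


def search_family(scoring: ScoringModel, db: ReadDatabase, kindex, links,
                  params: AssemblyParams, seed: int = 0,
                  external_verifier=None) -> FamilyResult:
    """Assemble, P-filter and verify contigs for a single family."""
    from .seeding import find_seeds

    seeds = find_seeds(scoring, kindex, params.theta)
    contigs = assemble_family(scoring, db, kindex, links, params, seeds=seeds)
    contigs = recalibrate(contigs, params.min_overlap)
    n_candidates = len(contigs)
    kept: list[Contig] = []
    if contigs:
        rng = np.random.default_rng(seed)
        lengths = rng.choice([len(c.seq) for c in contigs],
                             size=params.null_sample_size)
        null = sample_null_scores(scoring, lengths, rng, scorer="viterbi")
        for c in contigs:
            s = full_viterbi_score(scoring, c.seq)
            c.pvalue = score_pvalue(scoring, s, null)
            if c.pvalue <= params.pvalue_cutoff:
                kept.append(c)
    verified = verify_contigs(kept, scoring, params.evalue_cutoff,
                              params.null_sample_size, seed=seed + 1,
                              external=external_verifier)
    return FamilyResult(scoring.name, scoring.L, kept, verified,
                        len(seeds), n_candidates)


def evaluate(result: SearchResult, truth: dict[str, set[str]]) -> dict[str, EvalReport]:
    """Per-family and pooled recall/precision/F against ground-truth labels.

    The pooled report (key ``__overall__``) counts (read, family) pairs.
    """
    out: dict[str, EvalReport] = {}
    pred_pairs = set()
    truth_pairs = set()
    for fam in result.families:
        pred = result.recruited(fam)
        tru = truth.get(fam, set())
        out[fam] = recall_precision_f(pred, tru)
        pred_pairs |= {(r, fam) for r in pred}
        truth_pairs |= {(r, fam) for r in tru}
    out["__overall__"] = recall_precision_f(pred_pairs, truth_pairs)
    return out
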