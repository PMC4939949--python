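"""Assembly loop, contig recalibration and score significance."""

import numpy as np
import pytest

from conftest import db_from_seqs
from prosaa.banded_align import full_viterbi_score
from prosaa.hmmio import to_scoring
from prosaa.readdb import build_extension_links, build_kgram_index
from prosaa.saa_engine import (AssemblyParams, Contig, assemble_family,
                               recalibrate, sample_null_scores, score_pvalue)
from prosaa.synthetic import random_profile_hmm, sample_from_hmm


def _tiled_db(protein, read_len=20, step=5):
    reads = [protein[s:s + read_len]
             for s in range(0, len(protein) - read_len + 1, step)]
    if (len(protein) - read_len) % step:
        reads.append(protein[-read_len:])
    return db_from_seqs(reads)


class TestParams:
    def test_defaults_valid(self):
        p = AssemblyParams()
        assert p.k == 6 and p.band == 20 and p.max_depth == 5

    @pytest.mark.parametrize("kw", [
        {"theta": 0.0}, {"theta": 1.5}, {"k": 0}, {"min_overlap": -1},
        {"band": 0}, {"dropoff": 0.0}, {"pvalue_cutoff": 0.0},
        {"max_depth": -1},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            AssemblyParams(**kw)


@pytest.fixture(scope="module")
def family():
    model = random_profile_hmm(60, seed=21, name="FAM")
    protein, _ = sample_from_hmm(model, np.random.default_rng(4))
    return model, protein


class TestAssembly:
    def test_error_free_tiling_reassembles_protein(self, family):
        model, protein = family
        db = _tiled_db(protein)
        scoring = to_scoring(model)
        contigs = assemble_family(
            scoring, db, build_kgram_index(db, 6), build_extension_links(db, 10))
        contigs = recalibrate(contigs, 10)
        assert contigs
        best = max(contigs, key=len)
        assert best.seq in protein
        assert len(best) >= 0.9 * len(protein)

    def test_contig_reads_tile_exactly(self, family):
        model, protein = family
        db = _tiled_db(protein)
        scoring = to_scoring(model)
        contigs = assemble_family(
            scoring, db, build_kgram_index(db, 6), build_extension_links(db, 10))
        for c in recalibrate(contigs, 10):
            for h, off in c.reads:
                assert c.seq[off:off + len(db[h].seq)] == db[h].seq

    def test_contig_score_is_banded_lower_bound(self, family):
        model, protein = family
        db = _tiled_db(protein)
        scoring = to_scoring(model)
        contigs = assemble_family(
            scoring, db, build_kgram_index(db, 6), build_extension_links(db, 10))
        for c in contigs:
            assert c.score <= full_viterbi_score(scoring, c.seq) + 1e-6

    def test_no_links_yields_single_read_contigs(self, family):
        model, protein = family
        db = _tiled_db(protein, read_len=20, step=15)  # overlaps of 5 < 10
        scoring = to_scoring(model)
        links = build_extension_links(db, 10)
        assert links.n_links() == 0
        contigs = assemble_family(scoring, db, build_kgram_index(db, 6), links)
        assert contigs
        assert all(len(c.reads) == 1 for c in contigs)

    def test_unrelated_reads_yield_nothing(self, family):
        model, _ = family
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25))
                for _ in range(30)]
        db = db_from_seqs(seqs)
        contigs = assemble_family(
            to_scoring(model), db, build_kgram_index(db, 6),
            build_extension_links(db, 10))
        # random reads very rarely seed at theta=0.8; any survivor is 1-read
        assert all(len(c.reads) <= 2 for c in contigs)

    def test_deterministic(self, family):
        model, protein = family
        db = _tiled_db(protein)
        scoring = to_scoring(model)
        kin, links = build_kgram_index(db, 6), build_extension_links(db, 10)
        a = assemble_family(scoring, db, kin, links)
        b = assemble_family(scoring, db, kin, links)
        assert [(c.seq, c.score) for c in a] == [(c.seq, c.score) for c in b]


class TestRecalibrate:
    S = "ACDEFGHIKLMNPQRSTVWY"

    def _contig(self, seq, reads, score=1.0):
        return Contig(seq=seq, reads=reads, family="F", score=score)

    def test_overlap_merge(self):
        c1 = self._contig(self.S[:15], [(0, 0)])
        c2 = self._contig(self.S[5:], [(1, 0)])
        out = recalibrate([c1, c2], 10)
        assert len(out) == 1
        assert out[0].seq == self.S
        assert out[0].reads == [(0, 0), (1, 5)]

    def test_identical_sequences_collapse_with_read_union(self):
        c1 = self._contig(self.S, [(0, 0)], score=3.0)
        c2 = self._contig(self.S, [(1, 2)], score=5.0)
        out = recalibrate([c1, c2], 10)
        assert len(out) == 1
        assert out[0].reads == [(0, 0), (1, 2)]
        assert out[0].score == 5.0

    def test_inconsistent_shared_read_blocks_merge(self):
        c1 = self._contig(self.S[:15], [(0, 0)])
        c2 = self._contig(self.S[5:], [(0, 0)])  # read 0 placed differently
        out = recalibrate([c1, c2], 10)
        assert sorted(c.seq for c in out) == sorted([self.S[:15], self.S[5:]])

    def test_substring_contigs_removed(self):
        c1 = self._contig(self.S, [(0, 0)])
        c2 = self._contig(self.S[3:12], [(1, 0)])
        out = recalibrate([c1, c2], 10)
        assert [c.seq for c in out] == [self.S]

    def test_chain_of_three_merges(self):
        longer = self.S + self.S[::-1]
        c = [self._contig(longer[i:i + 16], [(i, 0)]) for i in (0, 6, 12, 18)]
        out = recalibrate(c, 10)
        assert len(out) == 1
        assert out[0].seq == longer[:34]

    def test_x_in_overlap_blocks_merge(self):
        a = "ACDEFXHIKLMNPQ"
        b = "EFXHIKLMNPQRST"
        out = recalibrate([self._contig(a, [(0, 0)]),
                           self._contig(b, [(1, 0)])], 10)
        assert len(out) == 2

    def test_empty_input(self):
        assert recalibrate([], 10) == []


class TestSignificance:
    def test_null_sampling_deterministic(self, small_model):
        s = to_scoring(small_model)
        a = sample_null_scores(s, [25] * 40, np.random.default_rng(1))
        b = sample_null_scores(s, [25] * 40, np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_forward_null_exceeds_viterbi_null(self, small_model):
        s = to_scoring(small_model)
        v = sample_null_scores(s, [30] * 20, np.random.default_rng(2), "viterbi")
        f = sample_null_scores(s, [30] * 20, np.random.default_rng(2), "forward")
        assert np.all(f >= v - 1e-9)

    def test_unknown_scorer_raises(self, small_model):
        with pytest.raises(ValueError, match="scorer"):
            sample_null_scores(to_scoring(small_model), [10],
                               np.random.default_rng(0), "posterior")

    def test_pvalue_monotone_gumbel(self, small_model):
        s = to_scoring(small_model)
        null = sample_null_scores(s, [30] * 200, np.random.default_rng(3))
        ps = [score_pvalue(s, x, null) for x in np.linspace(-20, 120, 30)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        assert score_pvalue(s, 1000.0, null) < 1e-6
        assert score_pvalue(s, float(null.min()) - 50, null) > 0.5

    def test_rank_fallback_exact(self, small_model):
        s = to_scoring(small_model)
        assert score_pvalue(s, 2.5, np.array([1.0, 2.0, 3.0])) == 0.5
        assert score_pvalue(s, 0.0, np.array([1.0, 2.0, 3.0])) == 1.0

    def test_empty_calibration_gives_one(self, small_model):
        assert score_pvalue(to_scoring(small_model), 5.0, np.array([])) == 1.0

    def test_real_contig_beats_null(self, small_model):
        s = to_scoring(small_model)
        null = sample_null_scores(s, [30] * 200, np.random.default_rng(5))
        cons_score = full_viterbi_score(s, s.consensus())
        assert score_pvalue(s, cons_score, null) < 0.001
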