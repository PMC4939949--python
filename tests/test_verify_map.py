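"""Full-model contig verification and ungapped read recruitment."""

import numpy as np
import pytest

from _oracles import brute_force_best_placement
from conftest import db_from_seqs
from prosaa.hmmio import to_scoring
from prosaa.saa_engine import Contig
from prosaa.synthetic import random_profile_hmm, sample_from_hmm
from prosaa.verify_map import (VerifiedContig, map_reads, resolve_multi_family,
                               verify_contigs)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _vc(seq, family="F", evalue=1e-6):
    return VerifiedContig(Contig(seq, [], family, 0.0), 0.0, evalue, family)


class TestVerify:
    def test_true_contig_passes_decoy_fails(self):
        model = random_profile_hmm(50, seed=31, name="V")
        scoring = to_scoring(model)
        rng = np.random.default_rng(1)
        true_seq, _ = sample_from_hmm(model, rng)
        decoy = "".join(rng.choice(AA, size=len(true_seq)))
        contigs = [Contig(true_seq, [], "V", 0.0), Contig(decoy, [], "V", 0.0)]
        out = verify_contigs(contigs, scoring, evalue_cutoff=0.01, seed=3)
        assert [v.seq for v in out] == [true_seq]
        assert out[0].evalue < 0.01

    def test_empty_input(self, small_model):
        assert verify_contigs([], to_scoring(small_model)) == []

    def test_nonpositive_cutoff_raises(self, small_model):
        with pytest.raises(ValueError, match="cutoff"):
            verify_contigs([Contig("ACDEF", [], "F", 0.0)],
                           to_scoring(small_model), evalue_cutoff=0.0)

    def test_external_hook_replaces_internal_scoring(self, small_model):
        contigs = [Contig("ACDEF", [], "F", 0.0),
                   Contig("GHIKL", [], "F", 0.0)]

        def external(cs, model):
            return [1e-9, 0.5]

        out = verify_contigs(contigs, to_scoring(small_model),
                             evalue_cutoff=0.01, external=external)
        assert [v.seq for v in out] == ["ACDEF"]
        assert np.isnan(out[0].forward)

    def test_deterministic_given_seed(self):
        model = random_profile_hmm(40, seed=8, name="D")
        scoring = to_scoring(model)
        seq, _ = sample_from_hmm(model, np.random.default_rng(2))
        contigs = [Contig(seq, [], "D", 0.0)]
        a = verify_contigs(contigs, scoring, seed=5)
        b = verify_contigs(contigs, scoring, seed=5)
        assert [(v.seq, v.evalue) for v in a] == [(v.seq, v.evalue) for v in b]


class TestMapContract:
    """The three canonical recruitment threshold cases."""

    CONTIG = "".join(
        np.random.default_rng(12).choice(AA, size=120))

    def test_exact_read_accepted_zero_mismatches(self):
        read = self.CONTIG[40:73]  # 33 aa, exact
        out = map_reads(db_from_seqs([read]), [_vc(self.CONTIG)])
        assert len(out) == 1
        a = out[0]
        assert a.mismatches == 0
        assert a.offset == 40
        assert a.fraction == 1.0

    def test_four_mismatches_rejected(self):
        read = list(self.CONTIG[40:73])
        for p in (2, 10, 20, 30):
            read[p] = "A" if read[p] != "A" else "C"
        out = map_reads(db_from_seqs(["".join(read)]), [_vc(self.CONTIG)])
        assert out == []

    def test_three_mismatches_accepted(self):
        read = list(self.CONTIG[40:73])
        for p in (2, 10, 20):
            read[p] = "A" if read[p] != "A" else "C"
        out = map_reads(db_from_seqs(["".join(read)]), [_vc(self.CONTIG)])
        assert len(out) == 1 and out[0].mismatches == 3

    def test_sub_sixty_percent_overlap_rejected(self):
        # a 33-aa read hanging off the contig end with 19 residues inside:
        # 19/33 = 57.6% <= 60%, rejected despite zero mismatches
        tail = self.CONTIG[-19:]
        read = tail + "".join(np.random.default_rng(9).choice(AA, size=14))
        assert len(read) == 33
        out = map_reads(db_from_seqs([read]), [_vc(self.CONTIG)])
        assert out == []

    def test_just_over_sixty_percent_overlap_accepted(self):
        # 20/33 = 60.6% > 60% passes the strict threshold
        tail = self.CONTIG[-20:]
        read = tail + "".join(np.random.default_rng(9).choice(AA, size=13))
        out = map_reads(db_from_seqs([read]), [_vc(self.CONTIG)])
        assert len(out) == 1
        assert out[0].offset == len(self.CONTIG) - 20
        assert out[0].fraction == pytest.approx(20 / 33)


class TestMapGeneral:
    def test_matches_brute_force_placement(self):
        rng = np.random.default_rng(17)
        contig = "".join(rng.choice(AA, size=80))
        reads = []
        for _ in range(60):
            start = int(rng.integers(-10, 75))
            lo, hi = max(0, start), min(80, start + 25)
            core = contig[lo:hi]
            pad_l = "".join(rng.choice(AA, size=lo - start)) if start < 0 else ""
            pad_r = "".join(rng.choice(AA, size=start + 25 - hi))
            read = list(pad_l + core + pad_r)
            for _ in range(int(rng.integers(0, 5))):
                p = int(rng.integers(0, len(read)))
                read[p] = AA[int(rng.integers(0, 20))]
            reads.append("".join(read))
        db = db_from_seqs(reads)
        got = {(a.read, a.mismatches, a.offset)
               for a in map_reads(db, [_vc(contig)])}
        expect = set()
        for h, r in enumerate(reads):
            best = brute_force_best_placement(r, contig, 0.6, 3)
            if best is not None:
                expect.add((h, best[0], best[2]))
        assert got == expect

    def test_x_counts_as_mismatch(self):
        contig = "".join(np.random.default_rng(3).choice(AA, size=40))
        read = "X" * 4 + contig[4:20]
        out = map_reads(db_from_seqs([read]), [_vc(contig)])
        assert out == []  # 4 X-mismatches exceed the limit
        read2 = "X" * 3 + contig[3:20]
        out2 = map_reads(db_from_seqs([read2]), [_vc(contig)])
        assert len(out2) == 1 and out2[0].mismatches == 3

    def test_no_verified_contigs(self):
        assert map_reads(db_from_seqs(["ACDEFGHIKL"]), []) == []

    def test_short_read_brute_fallback(self):
        contig = "ACDEFGHIKLMNPQRSTVWY"
        out = map_reads(db_from_seqs(["CDEFG"]), [_vc(contig)])
        assert len(out) == 1 and out[0].offset == 1 and out[0].mismatches == 0


class TestResolve:
    def _a(self, read, family, evalue, mism=0):
        from prosaa.verify_map import ReadAssignment
        return ReadAssignment(read, f"r{read}", 0, family, 0, mism, 1.0, evalue)

    def test_lowest_evalue_wins(self):
        out = resolve_multi_family(
            [self._a(0, "B", 1e-3), self._a(0, "A", 1e-9)])
        assert len(out) == 1 and out[0].family == "A"

    def test_tie_broken_by_mismatches_then_family(self):
        out = resolve_multi_family(
            [self._a(0, "B", 1e-3, mism=2), self._a(0, "A", 1e-3, mism=3)])
        assert out[0].family == "B"
        out = resolve_multi_family(
            [self._a(0, "B", 1e-3, mism=2), self._a(0, "A", 1e-3, mism=2)])
        assert out[0].family == "A"

    def test_distinct_reads_all_kept(self):
        out = resolve_multi_family([self._a(0, "A", 1e-3),
                                    self._a(1, "B", 1e-3)])
        assert [a.read for a in out] == [0, 1]
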