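"""PFM construction and additive position-energy scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replift import (
    PEM,
    PFM,
    build_pfm,
    predict_energy,
    read_matrix,
    revcomp,
    scan_consensus,
    score_siteset,
    write_matrix,
)
from replift.binding import BindingError

from conftest import random_consensus
from oracles import brute_force_scan

BASES = "ACGT"


@pytest.fixture()
def ladder_pem():
    # eps(A)=0, eps(C)=1, eps(G)=2, eps(T)=3 at both positions
    return PEM(np.tile(np.array([[0.0], [1.0], [2.0], [3.0]]), (1, 2)))


class TestBuildPfm:
    def test_count_frequencies(self):
        pfm = build_pfm(["AC", "AC", "AG", "AT"], beta=0.0)
        assert pfm.matrix[0, 0] == 1.0  # f(A, 0)
        assert pfm.matrix[1, 1] == 0.5  # f(C, 1)
        assert pfm.matrix[2, 1] == 0.25 and pfm.matrix[3, 1] == 0.25

    def test_pseudocount_formula(self):
        pfm = build_pfm(["A"], beta=1.0)
        assert pfm.matrix[0, 0] == pytest.approx(2 / 5)

    def test_n_excluded_from_position_counts(self):
        pfm = build_pfm(["AN", "AC", "AC"], beta=0.0)
        assert pfm.matrix[1, 1] == 1.0  # N removed from numerator & denominator

    def test_gapped_sites_rejected(self):
        with pytest.raises(BindingError, match="allow_indel"):
            build_pfm(["A-"], beta=0.0)

    def test_uniform_sites_have_no_information(self):
        rng = np.random.default_rng(17)
        seqs = ["".join(BASES[i] for i in rng.integers(0, 4, 12))
                for _ in range(4000)]
        ic = build_pfm(seqs, beta=0.0).information_content()
        assert np.all(ic < 0.01)

    @given(beta1=st.floats(0.01, 5), beta2=st.floats(5.01, 50))
    @settings(max_examples=25, deadline=None)
    def test_beta_shrinks_toward_uniform_order_preserving(self, beta1, beta2):
        sites = ["AC", "AC", "AG", "AT", "CC"]
        small = build_pfm(sites, beta=beta1).matrix
        large = build_pfm(sites, beta=beta2).matrix
        assert np.all(np.abs(large - 0.25) <= np.abs(small - 0.25) + 1e-12)
        for i in range(small.shape[1]):
            assert np.array_equal(np.argsort(small[:, i], kind="stable"),
                                  np.argsort(large[:, i], kind="stable"))


class TestPredictEnergy:
    def test_minimum_energy_sequence(self, ladder_pem):
        assert predict_energy(ladder_pem, "AA") == 0.0

    def test_additive_sum(self, ladder_pem):
        assert predict_energy(ladder_pem, "CT") == 4.0

    def test_exhaustive_dinucleotides(self, ladder_pem):
        per_base = {"A": 0, "C": 1, "G": 2, "T": 3}
        low = 0
        for s in itertools.product(BASES, repeat=2):
            seq = "".join(s)
            naive = sum(per_base[c] for c in seq)
            assert predict_energy(ladder_pem, seq) == naive
            low += naive < 2
        assert low == 3  # AA, AC, CA

    def test_length_and_n_rejected(self, ladder_pem):
        with pytest.raises(BindingError):
            predict_energy(ladder_pem, "AAA")
        with pytest.raises(BindingError):
            predict_energy(ladder_pem, "AN")

    def test_additivity_relative_to_consensus(self):
        rng = np.random.default_rng(3)
        pem = PEM(rng.normal(0, 1, size=(4, 12)))
        consensus = pem.minimum_energy_sequence()
        e_cons = predict_energy(pem, consensus)
        for _ in range(50):
            s = "".join(BASES[i] for i in rng.integers(0, 4, 12))
            delta = sum(
                pem.matrix[BASES.index(a), i] - pem.matrix[BASES.index(c), i]
                for i, (a, c) in enumerate(zip(s, consensus)) if a != c
            )
            assert predict_energy(pem, s) - e_cons == pytest.approx(delta, abs=1e-12)

    def test_single_mismatch_monotonicity(self):
        rng = np.random.default_rng(5)
        pem = PEM(rng.normal(0, 1, size=(4, 8)))
        s = "ACGTACGT"
        e0 = predict_energy(pem, s)
        for i in range(8):
            for b in BASES:
                if pem.matrix[BASES.index(b), i] >= pem.matrix[BASES.index(s[i]), i]:
                    s2 = s[:i] + b + s[i + 1:]
                    assert predict_energy(pem, s2) >= e0 - 1e-12


class TestScoreSiteset:
    def test_fraction_below_counting(self, ladder_pem):
        # energies 0, 1, 3, 6 with theta=2 -> 2/4
        sites = ["AA", "AC", "AT", "TT"]
        summary = score_siteset(ladder_pem, sites, threshold=2.0)
        assert summary.fraction_below == 0.5
        assert summary.energies == [0.0, 1.0, 3.0, 6.0]

    def test_threshold_infinity(self, ladder_pem):
        assert score_siteset(ladder_pem, ["AA", "TT"], math.inf).fraction_below == 1.0

    def test_strictly_below(self, ladder_pem):
        # E("AC") == 1 is not < 1
        assert score_siteset(ladder_pem, ["AC"], 1.0).fraction_below == 0.0

    def test_n_sites_excluded_and_counted(self, ladder_pem):
        summary = score_siteset(ladder_pem, ["AA", "NN", "AN"], 10.0)
        assert summary.n == 1 and summary.n_excluded == 2

    def test_zero_scoreable_rejected(self, ladder_pem):
        with pytest.raises(BindingError):
            score_siteset(ladder_pem, ["NN"], 0.0)

    def test_planted_mismatch_shifts_energy_exactly(self, fixture,
                                                    genome_source,
                                                    planted_locus):
        from replift import lift_out
        rng = np.random.default_rng(11)
        pem = PEM(rng.normal(0, 1.5, size=(4, planted_locus.length)))
        sites = lift_out(fixture.align_records, planted_locus, genome_source,
                         fixture.consensus["L1toy"])
        ref = sites.consensus_sequence
        e_ref = predict_energy(pem, ref)
        for entry in sites.entries:
            expected = e_ref + sum(
                pem.matrix[BASES.index(a), i] - pem.matrix[BASES.index(c), i]
                for i, (a, c) in enumerate(zip(entry.sequence, ref)) if a != c
            )
            assert predict_energy(pem, entry.sequence) == pytest.approx(expected)


class TestScanConsensus:
    def test_planted_minimum_found(self):
        rng = np.random.default_rng(23)
        pem = PEM(rng.normal(0, 2, size=(4, 7)))
        best = pem.minimum_energy_sequence()
        consensus = random_consensus(100, seed=2).replace(best, "")
        consensus = consensus[:40] + best + consensus[40:]
        off, strand, e = scan_consensus(pem, consensus)
        assert consensus[off:off + 7] == best or strand == "-"
        assert e == pytest.approx(pem.minimum_energy())

    def test_reverse_complement_planted(self):
        rng = np.random.default_rng(29)
        pem = PEM(rng.normal(0, 3, size=(4, 8)))
        best = pem.minimum_energy_sequence()
        consensus = "A" * 30 + revcomp(best) + "A" * 30
        off, strand, e = scan_consensus(pem, consensus)
        if pem.minimum_energy() < predict_energy(pem, "A" * 8):
            assert (off, strand) == (30, "-")
            assert e == pytest.approx(pem.minimum_energy())

    def test_equals_brute_force(self):
        rng = np.random.default_rng(31)
        pem = PEM(rng.normal(0, 1, size=(4, 6)))
        consensus = random_consensus(300, seed=6)
        off, strand, e = scan_consensus(pem, consensus)
        b_off, b_strand, b_e = brute_force_scan(pem.matrix, consensus)
        assert (off, strand) == (b_off, b_strand)
        assert e == pytest.approx(b_e)

    def test_tie_breaks_smallest_offset_then_plus(self):
        pem = PEM(np.zeros((4, 3)))  # every window ties at E=0
        assert scan_consensus(pem, "ACGTACGT") == (0, "+", 0.0)


class TestMatrixIO:
    def test_roundtrip(self):
        rng = np.random.default_rng(41)
        mat = rng.normal(0, 1, size=(4, 9))
        again = read_matrix(write_matrix(mat))
        assert np.allclose(mat, again, atol=1e-9)

    def test_pfm_column_sums_on_read(self):
        pfm = build_pfm(["ACGT", "AGGT", "ACGA"], beta=0.5)
        again = PFM.from_tsv(pfm.to_tsv(), n_sites=3, beta=0.5)
        assert np.allclose(again.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_three_row_file_rejected(self):
        text = write_matrix(np.zeros((4, 5)))
        lines = text.splitlines()
        with pytest.raises(BindingError):
            read_matrix("\n".join(lines[:4]))  # header + only 3 base rows

    def test_anchored_pem_zero_minimum(self):
        pem = PEM(np.array([[1.0, -2.0], [3.0, 0.0], [0.5, 4.0], [2.0, 1.0]]))
        anch = pem.anchored()
        assert np.allclose(anch.matrix.min(axis=0), 0.0)
        # anchoring is an explicit utility: relative energies preserved
        assert np.allclose(np.diff(anch.matrix, axis=0),
                           np.diff(pem.matrix, axis=0))
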