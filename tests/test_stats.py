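"""Compactness, decay-curve, and trans-decomposition statistics."""

import numpy as np
import pytest
import scipy.sparse as sp

from nucleoform.binning import bin_genome
from nucleoform.contacts import ContactMatrix, balance_ice, mask_bins, matrix_from_triplets
from nucleoform.simulate import HiCSimParams, simulate_contact_map
from nucleoform.stats import (
    DecayCurve,
    compactness_profile,
    compare_genotypes,
    expected_contact_curve,
    fit_decay_exponent,
    trans_contact_profile,
)

from conftest import random_raw_matrix


def balanced_from_dense(binning, dense, masked=()):
    """Wrap a symmetric dense array as an already-'normalized' matrix."""
    upper = sp.csr_matrix(np.triu(dense))
    biases = np.ones(binning.n_bins)
    biases[list(masked)] = np.nan
    return ContactMatrix(binning, upper, frozenset(masked), True, biases)


class TestCompactness:
    def test_uniform_matrix_interior_and_edge_bins(self):
        # 10-kb bins, 200-kb window: interior bin sums 20 neighbours each side
        n, c = 100, 0.7
        binning = bin_genome({"c": n * 10_000}, 10_000)
        dense = np.full((n, n), c)
        np.fill_diagonal(dense, 0.0)
        prof = compactness_profile(balanced_from_dense(binning, dense))
        assert prof.values[50] == pytest.approx(40 * c)
        assert prof.values[0] == pytest.approx(20 * c)
        assert prof.values[n - 1] == pytest.approx(20 * c)

    def test_matches_brute_force_double_loop(self, rng):
        n = 300
        binning = bin_genome({"c": n * 10_000}, 10_000)
        dense = rng.random((n, n))
        dense = dense + dense.T
        np.fill_diagonal(dense, 0.0)
        masked = {17, 200}
        dense[list(masked), :] = 0.0
        dense[:, list(masked)] = 0.0
        prof = compactness_profile(balanced_from_dense(binning, dense, masked))
        kmax = 20
        for i in range(n):
            if i in masked:
                assert np.isnan(prof.values[i])
                continue
            expected = sum(
                dense[i, j]
                for j in range(max(0, i - kmax), min(n, i + kmax + 1))
                if j != i and j not in masked
            )
            assert prof.values[i] == pytest.approx(expected, abs=1e-12)

    def test_linearity_in_the_matrix(self, rng):
        n = 40
        binning = bin_genome({"c": n * 10_000}, 10_000)
        dense = rng.random((n, n))
        dense = dense + dense.T
        np.fill_diagonal(dense, 0.0)
        p1 = compactness_profile(balanced_from_dense(binning, dense))
        p3 = compactness_profile(balanced_from_dense(binning, 3.0 * dense))
        assert np.allclose(p3.values, 3.0 * p1.values)

    def test_raw_matrix_and_bad_window_rejected(self, two_chrom_binning, rng):
        raw = random_raw_matrix(two_chrom_binning, rng)
        with pytest.raises(ValueError, match="normalized"):
            compactness_profile(raw)
        bal = balance_ice(raw)
        with pytest.raises(ValueError, match="window"):
            compactness_profile(bal, window=5_000)


class TestDecayCurve:
    def test_exact_inverse_separation(self):
        n = 60
        binning = bin_genome({"c": n * 10_000}, 10_000)
        dense = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dense[i, j] = dense[j, i] = 1.0 / (j - i)
        curve = expected_contact_curve(balanced_from_dense(binning, dense),
                                       s_max=300_000)
        for k in range(1, 31):
            assert curve.p[k - 1] == pytest.approx(1.0 / k)
            assert curve.n_pairs[k - 1] == n - k

    def test_masked_bin_reduces_pair_counts_and_matches_brute_force(self, rng):
        n = 50
        binning = bin_genome({"c": n * 10_000}, 10_000)
        dense = rng.random((n, n))
        dense = dense + dense.T
        np.fill_diagonal(dense, 0.0)
        masked = {20}
        dense[20, :] = 0.0
        dense[:, 20] = 0.0
        full = expected_contact_curve(
            balanced_from_dense(binning, dense, masked), s_max=200_000
        )
        for idx, k in enumerate(range(1, 21)):
            pairs = [
                (i, i + k) for i in range(n - k) if i != 20 and i + k != 20
            ]
            assert full.n_pairs[idx] == len(pairs) == (n - k) - (2 if k <= 20 else 1)
            expected = np.mean([dense[i, j] for i, j in pairs])
            assert full.p[idx] == pytest.approx(expected)

    def test_s_max_below_bin_size_rejected(self, two_chrom_binning, rng):
        bal = balance_ice(random_raw_matrix(two_chrom_binning, rng))
        with pytest.raises(ValueError, match="s_max"):
            expected_contact_curve(bal, s_max=5_000)


class TestDecayExponent:
    def test_exact_power_law_slope(self):
        s = np.arange(1, 51) * 10_000
        curve = DecayCurve(s, (s / 10_000.0) ** -1.0, np.ones(50, int), 10_000)
        assert fit_decay_exponent(curve) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_curve_slope_zero(self):
        s = np.arange(1, 51) * 10_000
        curve = DecayCurve(s, np.full(50, 0.3), np.ones(50, int), 10_000)
        assert fit_decay_exponent(curve) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_positive_scaling(self):
        s = np.arange(1, 51) * 10_000
        p = (s / 10_000.0) ** -1.3
        c1 = DecayCurve(s, p, np.ones(50, int), 10_000)
        c2 = DecayCurve(s, 7.5 * p, np.ones(50, int), 10_000)
        assert fit_decay_exponent(c1) == pytest.approx(fit_decay_exponent(c2))

    def test_too_few_points_rejected(self):
        s = np.arange(1, 5) * 10_000
        curve = DecayCurve(s, np.array([1.0, 0.5, 0.0, 0.0]), np.ones(4, int), 10_000)
        with pytest.raises(ValueError, match=">=3"):
            fit_decay_exponent(curve, s_min=10_000, s_max=40_000)

    def test_recovers_simulated_exponent(self):
        exps = []
        for seed in range(3):
            params = HiCSimParams(
                chrom_lengths={"chr1": 5_000_000}, bin_size=10_000, alpha=1.2,
                territory_strength=0.0, depth=2e6, seed=seed,
            )
            bal = balance_ice(simulate_contact_map(params))
            curve = expected_contact_curve(bal, s_max=2_500_000)
            exps.append(fit_decay_exponent(curve, s_min=20_000))
        assert np.mean(exps) == pytest.approx(-1.2, abs=0.05)


class TestTransProfile:
    def test_all_cis_gives_zero_fractions(self, two_chrom_binning):
        mat = matrix_from_triplets(two_chrom_binning, [0, 5], [1, 6], [4, 4])
        tp = trans_contact_profile(mat)
        defined = ~np.isnan(tp.fraction)
        assert np.all(tp.fraction[defined] == 0.0)

    def test_all_trans_gives_unit_fractions(self, two_chrom_binning):
        mat = matrix_from_triplets(two_chrom_binning, [0, 1], [5, 6], [4, 4])
        tp = trans_contact_profile(mat)
        defined = ~np.isnan(tp.fraction)
        assert np.all(tp.fraction[defined] == 1.0)

    def test_cis_plus_trans_equals_offdiagonal_marginal(self, two_chrom_binning, rng):
        mat = random_raw_matrix(two_chrom_binning, rng)
        tp = trans_contact_profile(mat)
        marg = mat.marginals() - mat.symmetric().diagonal()
        total = np.nan_to_num(tp.cis) + np.nan_to_num(tp.trans)
        assert np.array_equal(total.astype(int), marg.astype(int))

    def test_single_chromosome_rejected(self, rng):
        binning = bin_genome({"c": 50_000}, 10_000)
        mat = random_raw_matrix(binning, rng)
        with pytest.raises(ValueError, match="single-chromosome"):
            trans_contact_profile(mat)


class TestCompareGenotypes:
    def test_identical_profiles_give_zero_diff_and_p_one(self, rng):
        n = 30
        binning = bin_genome({"c": n * 10_000}, 10_000)
        dense = rng.random((n, n))
        dense = dense + dense.T
        np.fill_diagonal(dense, 0)
        prof = compactness_profile(balanced_from_dense(binning, dense))
        comp = compare_genotypes(prof, prof)
        row = comp.table.iloc[0]
        assert row["median_diff"] == 0.0
        assert row["p"] > 0.9

    def test_uniform_shrinkage_detected(self, rng):
        n = 500
        binning = bin_genome({"c": n * 10_000}, 10_000)
        dense = rng.random((n, n)) + 0.5
        dense = dense + dense.T
        np.fill_diagonal(dense, 0)
        pa = compactness_profile(balanced_from_dense(binning, dense))
        pb = compactness_profile(balanced_from_dense(binning, 0.8 * dense))
        comp = compare_genotypes(pa, pb)
        row = comp.table.iloc[0]
        assert row["median_diff"] < 0
        assert row["p"] < 1e-6

    def test_binning_mismatch_rejected(self, rng):
        b1 = bin_genome({"c": 300_000}, 10_000)
        b2 = bin_genome({"c": 400_000}, 10_000)
        d1 = np.ones((30, 30)) - np.eye(30)
        d2 = np.ones((40, 40)) - np.eye(40)
        p1 = compactness_profile(balanced_from_dense(b1, d1))
        p2 = compactness_profile(balanced_from_dense(b2, d2))
        with pytest.raises(ValueError, match="grid"):
            compare_genotypes(p1, p2)
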