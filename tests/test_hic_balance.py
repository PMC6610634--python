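"""Masking, down-sampling, ICE balancing, O/E and Pearson maps."""

import numpy as np
import pytest
from scipy import stats

from xi_origami import (ContactMatrix, GenomeBinning, downsample, ice_balance,
                        mask_low_coverage, observed_over_expected, pearson_map)
from conftest import random_contact_matrix


class TestMaskLowCoverage:
    def test_quantile_zero_masks_only_empty_rows(self):
        m = random_contact_matrix(10, seed=1)
        m.values[3, :] = 0
        m.values[:, 3] = 0
        out = mask_low_coverage(m, 0.0)
        assert out.mask.tolist() == [i == 3 for i in range(10)]

    def test_exact_count_with_index_tie_break(self):
        n = 100
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 5, (n, n))
        vals = (vals + vals.T) / 2
        m = ContactMatrix(GenomeBinning("chrX", n * 100_000, 100_000), vals)
        out = mask_low_coverage(m, 0.14)
        assert out.mask.sum() == 14  # ceil(0.14 * 100)
        # sort-based oracle: the 14 lowest marginals, ties to lower index
        marg = vals.sum(axis=1)
        expect = np.lexsort((np.arange(n), marg))[:14]
        assert sorted(np.flatnonzero(out.mask)) == sorted(expect)

    def test_idempotent(self):
        m = random_contact_matrix(50, seed=3)
        once = mask_low_coverage(m, 0.14)
        twice = mask_low_coverage(once, 0.14)
        assert (once.mask == twice.mask).all()

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            mask_low_coverage(random_contact_matrix(5), 1.0)


class TestDownsample:
    def test_target_equal_total_is_identity(self):
        m = random_contact_matrix(8, seed=4, integer=True)
        out = downsample(m, int(m.total()), seed=0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_target_zero(self):
        m = random_contact_matrix(8, seed=4, integer=True)
        assert downsample(m, 0, seed=0).values.sum() == 0

    def test_total_exact_and_deterministic(self):
        m = random_contact_matrix(10, seed=5, integer=True)
        target = int(m.total() // 3)
        a = downsample(m, target, seed=9)
        b = downsample(m, target, seed=9)
        assert np.triu(a.values).sum() == target
        np.testing.assert_array_equal(a.values, b.values)

    def test_expectation_matches_hypergeometric_oracle(self):
        # 5x5 matrix, half the total: E[cell] = cell/2 under the multivariate
        # hypergeometric; check the empirical mean over seeds against 3 SE,
        # with the exact variance n*(K/N)*(1-K/N)*(N-n)/(N-1).
        vals = np.array([
            [4, 6, 2, 0, 8],
            [6, 10, 4, 2, 0],
            [2, 4, 6, 8, 2],
            [0, 2, 8, 4, 6],
            [8, 0, 2, 6, 12],
        ], dtype=float)
        m = ContactMatrix(GenomeBinning("chrX", 500_000, 100_000), vals)
        N = int(np.triu(vals).sum())
        n_draw = N // 2
        reps = 1000
        iu, ju = np.triu_indices(5)
        sums = np.zeros(len(iu))
        for s in range(reps):
            out = downsample(m, n_draw, seed=s)
            sums += out.values[iu, ju]
        emp_mean = sums / reps
        K = vals[iu, ju]
        exp_mean = n_draw * K / N
        var = n_draw * (K / N) * (1 - K / N) * (N - n_draw) / (N - 1)
        se = np.sqrt(var / reps)
        assert np.all(np.abs(emp_mean - exp_mean) <= 3 * np.maximum(se, 1e-12))

    def test_proportionality_chi2_not_rejected(self):
        m = random_contact_matrix(6, seed=6, integer=True)
        target = int(m.total() // 2)
        iu, ju = np.triu_indices(6)
        totals = np.zeros(len(iu))
        reps = 1000
        for s in range(reps):
            totals += downsample(m, target, seed=1000 + s).values[iu, ju]
        expected = m.values[iu, ju] * target / m.total() * reps
        keep = expected > 5
        chi2 = ((totals[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_target_above_total_fatal(self):
        m = random_contact_matrix(5, seed=7, integer=True)
        with pytest.raises(ValueError):
            downsample(m, int(m.total()) + 1, seed=0)


def naive_ice(vals, max_iter=2000, tol=1e-10):
    """Textbook ICE oracle: explicit bias-vector iteration."""
    w = vals.astype(float).copy()
    for _ in range(max_iter):
        marg = w.sum(axis=1)
        s = marg / marg.mean()
        w = w / np.outer(s, s)
        marg = w.sum(axis=1)
        if marg.std() / marg.mean() < tol:
            break
    return w * vals.mean() / w.mean()


class TestIceBalance:
    def test_equal_marginals_fixed_point(self):
        n = 12
        vals = np.full((n, n), 3.0)
        m = ContactMatrix(GenomeBinning("chrX", n * 100_000, 100_000), vals)
        out = ice_balance(m)
        np.testing.assert_allclose(out.values, vals, rtol=1e-9)

    def test_matches_naive_iteration(self):
        vals = np.array([[0, 2, 4], [2, 0, 2], [4, 2, 0]], dtype=float)
        m = ContactMatrix(GenomeBinning("chrX", 300_000, 100_000), vals)
        out = ice_balance(m, tol=1e-9)
        np.testing.assert_allclose(out.values, naive_ice(vals), atol=1e-8)

    def test_masked_bin_left_na(self):
        m = random_contact_matrix(10, seed=8)
        m.mask[4] = True
        out = ice_balance(m)
        assert np.isnan(out.values[4]).all() and np.isnan(out.values[:, 4]).all()
        keep = ~out.mask
        marg = out.values[np.ix_(keep, keep)].sum(axis=1)
        assert marg.std() / marg.mean() < 1e-6

    def test_marginal_cv_and_mean_preservation_random(self):
        for seed in range(10):
            m = random_contact_matrix(50, seed=seed)
            out = ice_balance(m)
            marg = out.values.sum(axis=1)
            assert marg.std() / marg.mean() < 1e-6
            assert out.values.mean() == pytest.approx(m.values.mean(), rel=1e-9)

    def test_fully_masked_fatal(self):
        m = random_contact_matrix(5, seed=9)
        m.mask[:] = True
        with pytest.raises(ValueError):
            ice_balance(m)


class TestObservedOverExpected:
    def test_translation_invariant_gives_unity(self):
        n = 15
        idx = np.arange(n)
        vals = 1.0 / (np.abs(idx[:, None] - idx[None, :]) + 1)
        m = ContactMatrix(GenomeBinning("chrX", n * 100_000, 100_000), vals)
        oe = observed_over_expected(m)
        np.testing.assert_allclose(oe.values, 1.0, atol=1e-12)

    def test_per_diagonal_means_are_one(self):
        m = random_contact_matrix(20, seed=10)
        oe = observed_over_expected(m)
        n = 20
        for d in range(n):
            diag = np.diagonal(oe.values, offset=d)
            assert diag.mean() == pytest.approx(1.0, abs=1e-12)

    def test_matches_loop_oracle(self):
        m = random_contact_matrix(20, seed=11)
        m.mask[[2, 17]] = True
        oe = observed_over_expected(m)
        n = 20
        for d in range(n):
            vals = [m.values[i, i + d] for i in range(n - d)
                    if not (m.mask[i] or m.mask[i + d])]
            exp = np.mean(vals)
            for i in range(n - d):
                if m.mask[i] or m.mask[i + d]:
                    assert np.isnan(oe.values[i, i + d])
                else:
                    assert oe.values[i, i + d] == pytest.approx(
                        m.values[i, i + d] / exp, rel=1e-12)


class TestPearsonMap:
    def test_checkerboard_perfectly_anticorrelated(self):
        n = 16
        lab = np.resize([1, -1], n)
        oe_vals = 1.0 + 0.5 * np.outer(lab, lab)
        m = ContactMatrix(GenomeBinning("chrX", n * 100_000, 100_000), oe_vals)
        c = pearson_map(m)
        same = np.equal.outer(lab, lab)
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(c.values[same & off], 1.0)
        assert np.allclose(c.values[~same], -1.0)

    def test_constant_matrix_all_na(self):
        n = 10
        m = ContactMatrix(GenomeBinning("chrX", n * 100_000, 100_000), np.full((n, n), 2.0))
        c = pearson_map(m)
        assert np.isnan(c.values).all()

    def test_matches_pairwise_loop_oracle(self):
        m = random_contact_matrix(15, seed=12)
        c = pearson_map(m)
        n = 15
        for i in range(n):
            for j in range(i + 1, n):
                cols = np.ones(n, dtype=bool)
                cols[[i, j]] = False
                r = np.corrcoef(m.values[i, cols], m.values[j, cols])[0, 1]
                assert c.values[i, j] == pytest.approx(r, abs=1e-10)

    def test_banded_nan_matches_pairwise_complete_oracle(self):
        # distant diagonals with zero expected produce NaN bands in O/E;
        # the correlation must use pairwise-complete deletion
        rng = np.random.default_rng(14)
        n = 15
        vals = rng.uniform(1, 10, (n, n))
        vals = (vals + vals.T) / 2
        vals[np.abs(np.subtract.outer(np.arange(n), np.arange(n))) > 10] = np.nan
        m = ContactMatrix(GenomeBinning("chrX", n * 100_000, 100_000), vals)
        c = pearson_map(m)
        for i in range(n):
            for j in range(i + 1, n):
                cols = np.ones(n, dtype=bool)
                cols[[i, j]] = False
                x, y = vals[i, cols], vals[j, cols]
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 3:
                    assert np.isnan(c.values[i, j])
                else:
                    r = np.corrcoef(x[ok], y[ok])[0, 1]
                    assert c.values[i, j] == pytest.approx(r, abs=1e-10)

    def test_scale_invariance_and_symmetry(self):
        m = random_contact_matrix(15, seed=13)
        scaled = ContactMatrix(m.binning, m.values * 7.3)
        a, b = pearson_map(m), pearson_map(scaled)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)
        np.testing.assert_allclose(a.values, a.values.T, atol=1e-12)
        assert np.allclose(np.diag(a.values), 1.0)
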