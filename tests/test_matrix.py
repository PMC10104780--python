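import numpy as np
import pandas as pd
import pytest

from dsb3d.io import BinTable, ContactMatrix, ValidationError
from dsb3d.matrix import (
    contact_scaling,
    downsample,
    expected_cis,
    ice_balance,
    insulation_profile,
    observed_over_expected,
    pool,
)
from conftest import dense_to_matrix, random_matrix


def sinkhorn_oracle(dense, tol=1e-12, max_iter=100_000):
    """Independent dense Sinkhorn balancing, mean balanced marginal = 1."""
    n = dense.shape[0]
    bias = np.ones(n)
    for _ in range(max_iter):
        bal = dense * bias[:, None] * bias[None, :]
        m = bal.sum(axis=1)
        if np.abs(m / m.mean() - 1).max() < tol:
            break
        bias /= np.sqrt(m / m.mean())
    bias /= np.sqrt((dense * bias[:, None] * bias[None, :]).sum(axis=1).mean())
    return bias


class TestIceBalance:
    def test_doubly_stochastic_fixed_point(self):
        # equal marginals already: all weights equal
        dense = np.full((6, 6), 3)
        m = dense_to_matrix(dense)
        w = ice_balance(m, ignore_diags=0, mad_max=np.inf)
        np.testing.assert_allclose(w, w[0], rtol=1e-6)

    def test_recovers_outer_product_bias(self):
        """counts = r_i r_j: balancing must recover weights ∝ 1/r_i."""
        r = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        dense = np.rint(np.outer(r, r) * 16).astype(int)
        m = dense_to_matrix(dense)
        w = ice_balance(m, ignore_diags=0, mad_max=np.inf, tol=1e-10)
        ratio = w * r
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-4)

    def test_agrees_with_dense_sinkhorn(self):
        rng = np.random.default_rng(11)
        dense = rng.integers(1, 60, (40, 40))
        dense = dense + dense.T
        m = dense_to_matrix(dense)
        w = ice_balance(m, ignore_diags=0, mad_max=np.inf, tol=1e-10)
        oracle = sinkhorn_oracle(dense.astype(float))
        bal_ours = dense * w[:, None] * w[None, :]
        bal_oracle = dense * oracle[:, None] * oracle[None, :]
        assert np.abs(bal_ours - bal_oracle).max() < 1e-6

    def test_all_zero_bin_filtered(self):
        dense = np.full((6, 6), 5)
        dense[2, :] = 0
        dense[:, 2] = 0
        m = dense_to_matrix(dense)
        w = ice_balance(m, ignore_diags=0, mad_max=np.inf)
        assert np.isnan(w[2]) and np.isfinite(np.delete(w, 2)).all()

    def test_marginal_equality_with_ignored_diagonals(self):
        m = random_matrix(BinTable.from_chromsizes({"chr1": 300_000}, 10_000), seed=8)
        w = ice_balance(m, ignore_diags=2, mad_max=np.inf, tol=1e-8)
        dense = m.to_dense("chr1", balanced=True)
        n = dense.shape[0]
        mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
        marg = np.where(mask, dense, 0).sum(axis=1)
        assert np.abs(marg / marg.mean() - 1).max() < 1e-7


class TestExpectedAndOE:
    def test_constant_diagonals_returned_exactly(self):
        n = 6
        dense = np.zeros((n, n), dtype=int)
        for d in range(n):
            for i in range(n - d):
                dense[i, i + d] = dense[i + d, i] = 10 * (d + 1)
        m = dense_to_matrix(dense)
        m.weights = np.ones(n)
        prof = expected_cis(m, ignore_diags=0)
        np.testing.assert_allclose(prof.profile("chr1"), 10 * (np.arange(n) + 1))

    def test_matches_dense_averaging_oracle(self):
        m = random_matrix(BinTable.from_chromsizes({"chr1": 40_000}, 10_000), seed=4)
        ice_balance(m, ignore_diags=0, mad_max=np.inf, tol=1e-10)
        dense = m.to_dense("chr1", balanced=True)
        prof = expected_cis(m, ignore_diags=0).profile("chr1")
        for d in range(4):
            np.testing.assert_allclose(prof[d], np.diagonal(dense, d).mean(), rtol=1e-9)

    def test_fully_filtered_diagonal_is_nan_not_zero(self):
        dense = np.zeros((5, 5), dtype=int)
        dense[0, 1] = dense[1, 0] = 3  # only diagonal 1 has data
        m = dense_to_matrix(dense)
        m.weights = np.array([1.0, 1.0, np.nan, np.nan, np.nan])
        prof = expected_cis(m, ignore_diags=0).profile("chr1")
        assert np.isnan(prof[3])

    def test_oe_diagonal_means_are_one(self):
        m = random_matrix(BinTable.from_chromsizes({"chr1": 200_000}, 10_000), seed=9)
        ice_balance(m, ignore_diags=0, mad_max=np.inf, tol=1e-8)
        oe = observed_over_expected(m, ignore_diags=0)["chr1"]
        n = oe.shape[0]
        for d in range(n):
            diag = np.diagonal(oe, d)
            if np.isfinite(diag).any():
                assert abs(np.nanmean(diag) - 1.0) < 1e-9

    def test_oe_elementwise_against_dense_oracle(self):
        m = random_matrix(BinTable.from_chromsizes({"chr1": 40_000}, 10_000), seed=2)
        ice_balance(m, ignore_diags=0, mad_max=np.inf, tol=1e-10)
        dense = m.to_dense("chr1", balanced=True)
        n = dense.shape[0]
        exp = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                exp[i, j] = np.diagonal(dense, abs(i - j)).mean()
        oe = observed_over_expected(m, ignore_diags=0)["chr1"]
        np.testing.assert_allclose(oe, dense / exp, rtol=1e-9)


class TestContactScaling:
    @staticmethod
    def _power_law_matrix(alpha, n=1500, scale=20_000):
        idx = np.arange(n)
        s = np.abs(np.subtract.outer(idx, idx)).astype(float)
        dense = np.rint(scale * np.maximum(s, 1.0) ** (-alpha)).astype(int)
        return dense_to_matrix(dense, bin_size=10_000)

    def test_analytic_power_law_slope(self):
        m = self._power_law_matrix(1.0)
        m.weights = np.ones(len(m.bins))
        curve = contact_scaling(m, bins_per_decade=8)
        mid = (curve.s > 1e5) & (curve.s < 3e6)
        assert np.all(np.abs(curve.derivative[mid] + 1.0) < 0.05)

    def test_scale_invariance(self):
        m1 = self._power_law_matrix(1.2, n=600, scale=200)
        dense2 = m1.to_dense("chr1") * 5
        m2 = dense_to_matrix(dense2, bin_size=10_000)
        for m in (m1, m2):
            m.weights = np.ones(len(m.bins))
        c1 = contact_scaling(m1)
        c2 = contact_scaling(m2)
        np.testing.assert_allclose(c1.derivative, c2.derivative, rtol=1e-9)

    def test_too_few_bins_rejected(self):
        m = dense_to_matrix(np.full((4, 4), 9), bin_size=10_000)
        m.weights = np.ones(4)
        with pytest.raises(ValidationError):
            contact_scaling(m, bins_per_decade=1)


class TestInsulation:
    def test_uniform_matrix_scores_zero(self):
        m = dense_to_matrix(np.full((30, 30), 20), bin_size=10_000)
        m.weights = np.ones(30)
        track = insulation_profile(m, window=30_000)
        vals = track.values[np.isfinite(track.values)]
        np.testing.assert_allclose(vals, 0.0, atol=1e-9)

    def test_planted_boundary_is_local_minimum(self):
        n = 40
        dense = np.full((n, n), 2)
        dense[:20, :20] = 30
        dense[20:, 20:] = 30
        m = dense_to_matrix(dense, bin_size=10_000)
        m.weights = np.ones(n)
        track = insulation_profile(m, window=50_000)
        vals = track.values
        finite = np.flatnonzero(np.isfinite(vals))
        # dense diamond-mean oracle at the boundary bin
        w = 5
        b = 20
        oracle = np.log2(
            dense[b - w : b, b + 1 : b + w + 1].mean()
            / np.mean([dense[i - w : i, i + 1 : i + w + 1].mean() for i in finite])
        )
        assert np.nanargmin(vals) in (19, 20)
        np.testing.assert_allclose(vals[b], oracle, rtol=1e-9)

    def test_edges_missing(self):
        m = dense_to_matrix(np.full((20, 20), 8), bin_size=10_000)
        m.weights = np.ones(20)
        track = insulation_profile(m, window=40_000)
        assert np.isnan(track.values[:4]).all() and np.isnan(track.values[-4:]).all()

    def test_tiny_window_rejected(self):
        m = dense_to_matrix(np.full((20, 20), 8), bin_size=10_000)
        m.weights = np.ones(20)
        with pytest.raises(ValidationError):
            insulation_profile(m, window=10_000)


class TestDownsamplePool:
    def test_identity_and_empty_targets(self, random_small_matrix):
        total = random_small_matrix.total_valid_pairs
        same = downsample(random_small_matrix, total, seed=1)
        assert same.total_valid_pairs == total
        pd.testing.assert_frame_equal(
            same.pixels, random_small_matrix.pixels, check_dtype=False
        )
        assert downsample(random_small_matrix, 0, seed=1).total_valid_pairs == 0

    def test_exact_target_and_reproducibility(self, random_small_matrix):
        target = random_small_matrix.total_valid_pairs // 3
        d1 = downsample(random_small_matrix, target, seed=42)
        d2 = downsample(random_small_matrix, target, seed=42)
        assert d1.total_valid_pairs == target
        pd.testing.assert_frame_equal(d1.pixels, d2.pixels)

    def test_target_above_total_rejected(self, random_small_matrix):
        with pytest.raises(ValidationError):
            downsample(random_small_matrix, random_small_matrix.total_valid_pairs + 1, 0)

    def test_thinning_is_unbiased(self, random_small_matrix):
        """Empirical pixel means over 200 seeds within 3 SE of count*target/total."""
        total = random_small_matrix.total_valid_pairs
        target = total // 2
        counts = random_small_matrix.pixels["count"].to_numpy()
        acc = np.zeros_like(counts, dtype=float)
        n_rep = 200
        for s in range(n_rep):
            d = downsample(random_small_matrix, target, seed=s)
            merged = random_small_matrix.pixels.merge(
                d.pixels, on=["bin1_id", "bin2_id"], how="left", suffixes=("", "_d")
            )
            acc += merged["count_d"].fillna(0).to_numpy()
        mean = acc / n_rep
        expect = counts * target / total
        # hypergeometric variance per pixel
        var = counts * (target / total) * (1 - target / total) * (total - counts) / (total - 1)
        se = np.sqrt(var / n_rep)
        assert np.all(np.abs(mean - expect) <= 3 * np.maximum(se, 1e-9))

    def test_pool_doubles_and_identity(self, random_small_matrix):
        doubled = pool([random_small_matrix, random_small_matrix])
        np.testing.assert_array_equal(
            doubled.pixels["count"], 2 * random_small_matrix.pixels["count"]
        )
        single = pool([random_small_matrix])
        assert single.total_valid_pairs == random_small_matrix.total_valid_pairs

    def test_pooled_replicate_depth_bookkeeping(self, small_bins):
        """Two equal-depth downsampled replicates pool to twice the target."""
        px = pd.DataFrame({"bin1_id": [0, 1], "bin2_id": [1, 2], "count": [80_000_000, 40_000_000]})
        deep = ContactMatrix(small_bins, px)
        target = 56_446_063
        reps = [downsample(deep, target, seed=s) for s in (1, 2)]
        assert pool(reps).total_valid_pairs == 112_892_126

    def test_complementary_halves_restore_total(self, random_small_matrix):
        # downsample + its complement pool back to the original counts
        total = random_small_matrix.total_valid_pairs
        half = downsample(random_small_matrix, total // 2, seed=7)
        merged = random_small_matrix.pixels.merge(
            half.pixels, on=["bin1_id", "bin2_id"], how="left", suffixes=("", "_h")
        )
        comp = merged.assign(count=lambda d: d["count"] - d["count_h"].fillna(0).astype(int))
        comp = comp[comp["count"] > 0][["bin1_id", "bin2_id", "count"]]
        restored = pool([half, ContactMatrix(random_small_matrix.bins, comp)])
        assert restored.total_valid_pairs == total

    def test_pool_bin_mismatch_rejected(self, random_small_matrix):
        other = random_matrix(
            BinTable.from_chromsizes({"chr1": 60_000}, 10_000), seed=1
        )
        with pytest.raises(ValidationError):
            pool([random_small_matrix, other])
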