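"""FC construction, confound regression, thresholding, and affinity."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cingrad import (
    ConnectivityMatrix,
    TimeSeriesMatrix,
    VoxelSet,
    compute_fc,
    cosine_affinity,
    extract_compcor_components,
    regress_confounds,
    standardize_and_concatenate,
    threshold_rows,
)
from cingrad.exceptions import (
    AlignmentError,
    ConfigurationError,
    DegenerateVoxelWarning,
    RankDeficiencyWarning,
)


def _vs(n, offset=0, label="vs"):
    grid = np.column_stack([np.arange(n) + offset, np.zeros(n, int), np.zeros(n, int)])
    return VoxelSet(np.arange(n) + offset, grid, grid.astype(float), label)


def _ts(values, offset=0, sid="s"):
    values = np.asarray(values, dtype=float)
    return TimeSeriesMatrix(values, _vs(values.shape[1], offset), subject_id=sid)


class TestStandardizeConcatenate:
    def test_single_subject_zscore(self):
        rng = np.random.default_rng(0)
        out = standardize_and_concatenate([_ts(rng.normal(5, 3, (100, 4)))])
        assert out.standardized
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0), 1, atol=1e-6)

    def test_two_subjects_row_count_and_unit_sd(self):
        rng = np.random.default_rng(1)
        a, b = (_ts(rng.normal(size=(200, 3)), sid=f"s{i}") for i in range(2))
        out = standardize_and_concatenate([a, b])
        assert out.values.shape == (400, 3)
        np.testing.assert_allclose(out.values.std(axis=0), 1, atol=1e-6)

    def test_affine_rescaling_gives_identical_columns(self):
        """A subject whose voxel series is an affine rescaling of another's
        z-scores to the same column."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 1))
        a, b = _ts(x, sid="a"), _ts(3.5 * x - 7.0, sid="b")
        out = standardize_and_concatenate([a, b])
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(out.values[:80, 0], z.ravel(), atol=1e-10)
        np.testing.assert_allclose(out.values[80:, 0], z.ravel(), atol=1e-10)

    def test_zero_variance_column_zeroed_with_warning(self):
        vals = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.warns(DegenerateVoxelWarning):
            out = standardize_and_concatenate([_ts(vals)])
        assert np.all(out.values[:, 0] == 0)

    def test_mismatched_voxel_sets_rejected(self):
        a = _ts(np.random.default_rng(0).normal(size=(10, 3)))
        b = _ts(np.random.default_rng(0).normal(size=(10, 3)), offset=5)
        with pytest.raises(AlignmentError):
            standardize_and_concatenate([a, b])


class TestRegressConfounds:
    def test_residuals_orthogonal_to_global_mean(self):
        rng = np.random.default_rng(3)
        ts = _ts(rng.normal(size=(120, 6)))
        gm = ts.values.mean(axis=1, keepdims=True)
        out = regress_confounds(ts, gm)
        inner = np.abs(out.values.T @ gm).max()
        assert inner < 1e-8 * np.linalg.norm(gm) * np.linalg.norm(out.values)

    def test_self_regression_gives_zero_residual(self):
        rng = np.random.default_rng(4)
        ts = _ts(rng.normal(size=(60, 3)))
        out = regress_confounds(ts, ts.values[:, [1]])
        np.testing.assert_allclose(out.values[:, 1], 0, atol=1e-10)

    def test_expected_residual_variance_ratio(self):
        """Residualizing white noise on 5 random confounds + intercept keeps
        (n-1-5)/(n-1) of the centered variance in expectation (n=200)."""
        rng = np.random.default_rng(5)
        n, q = 200, 5
        ts = _ts(rng.normal(size=(n, 400)))
        out = regress_confounds(ts, rng.normal(size=(n, q)))
        orig_var = ts.values.var(axis=0)
        resid_var = out.values.var(axis=0)
        ratio = float(np.mean(resid_var / orig_var))
        assert ratio == pytest.approx((n - 1 - q) / (n - 1), abs=0.02)

    def test_rank_deficient_confounds_dropped(self):
        rng = np.random.default_rng(6)
        ts = _ts(rng.normal(size=(50, 2)))
        c = rng.normal(size=(50, 1))
        with pytest.warns(RankDeficiencyWarning):
            out = regress_confounds(ts, np.hstack([c, 2 * c]))
        assert out.values.shape == ts.values.shape


class TestCompCor:
    def test_recovers_dominant_shared_component(self):
        rng = np.random.default_rng(7)
        shared = rng.normal(size=(150, 1))
        noise = rng.normal(scale=0.3, size=(150, 30))
        ts = _ts(shared @ rng.normal(size=(1, 30)) + noise)
        comps = extract_compcor_components(ts, 3)
        r = np.corrcoef(comps[:, 0], shared.ravel())[0, 1]
        assert abs(r) > 0.99

    def test_orthonormality_and_variance_ordering(self):
        rng = np.random.default_rng(8)
        ts = _ts(rng.normal(size=(100, 20)))
        comps = extract_compcor_components(ts, 5)
        np.testing.assert_allclose(comps.T @ comps, np.eye(5), atol=1e-8)
        Z = (ts.values - ts.values.mean(0)) / ts.values.std(0)
        var = np.linalg.norm(Z.T @ comps, axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_rank_exceeded_is_error(self):
        ts = _ts(np.outer(np.arange(20.0), np.ones(4)) + 0.0)
        with pytest.raises(ConfigurationError):
            extract_compcor_components(ts, 3)


class TestComputeFC:
    def test_matches_naive_pearson_oracle(self):
        """Vectorized FC equals a per-pair two-loop Pearson computation."""
        rng = np.random.default_rng(9)
        seed = _ts(rng.normal(size=(40, 20)), offset=0)
        targ = _ts(rng.normal(size=(40, 30)), offset=100)
        conn = compute_fc(seed, targ, apply_fisher=False)
        expected = np.empty((20, 30))
        for i in range(20):
            for j in range(30):
                expected[i, j] = np.corrcoef(seed.values[:, i],
                                             targ.values[:, j])[0, 1]
        np.testing.assert_allclose(conn.values, expected, atol=1e-10)

    def test_fisher_values(self):
        """atanh checks: r=0 -> z=0; r=0.5 -> 0.5493; r=1 capped finite."""
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        u = (x - x.mean()) / np.linalg.norm(x - x.mean())
        w = rng.normal(size=50)
        w -= w.mean()
        w -= (w @ u) * u           # exactly orthogonal to u
        w /= np.linalg.norm(w)
        y05 = 0.5 * u + np.sqrt(0.75) * w   # Pearson r with x is exactly 0.5
        seed = _ts(x[:, None], offset=0)
        targ = _ts(np.column_stack([x, w, y05]), offset=10)
        conn = compute_fc(seed, targ, apply_fisher=True)
        assert np.isfinite(conn.values).all()
        assert conn.values[0, 0] == pytest.approx(np.arctanh(1 - 1e-7))
        assert conn.values[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert conn.values[0, 2] == pytest.approx(0.5493, abs=2e-4)

    def test_overlap_requires_flag(self):
        rng = np.random.default_rng(10)
        a = _ts(rng.normal(size=(30, 5)))
        b = _ts(rng.normal(size=(30, 5)))
        with pytest.raises(AlignmentError):
            compute_fc(a, b)
        conn = compute_fc(a, b, allow_overlap=True)
        assert conn.values.shape == (5, 5)

    def test_zero_variance_voxel_zero_row(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(30, 3))
        vals[:, 1] = 2.0
        seed = _ts(vals, offset=0)
        targ = _ts(rng.normal(size=(30, 4)), offset=50)
        with pytest.warns(DegenerateVoxelWarning):
            conn = compute_fc(seed, targ)
        assert np.all(conn.values[1] == 0)


class TestThresholdRows:
    def test_k_equals_one_keeps_maximum(self):
        row = np.array([[9.0, 1, 2, 3, 4, 5, 6, 7, 8, 0]])
        conn = ConnectivityMatrix(row, _vs(1), _vs(10, 100))
        out = threshold_rows(conn, 0.1)
        expected = np.zeros(10)
        expected[0] = 9.0
        np.testing.assert_array_equal(out.values[0], expected)

    def test_full_fraction_is_identity(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(5, 8))
        conn = ConnectivityMatrix(vals, _vs(5), _vs(8, 100))
        out = threshold_rows(conn, 1.0)
        np.testing.assert_array_equal(out.values, vals)

    def test_tie_break_matches_bruteforce_sort_oracle(self):
        """Ties at the cutoff retain lower column indices; count is exact."""
        row = np.array([[5.0, 3.0, 3.0, 3.0, 1.0, 3.0]])
        conn = ConnectivityMatrix(row, _vs(1), _vs(6, 100))
        out = threshold_rows(conn, 0.5)  # k = 3
        # brute-force: sort (value desc, col asc), keep first 3
        order = sorted(range(6), key=lambda j: (-row[0, j], j))[:3]
        expected = np.zeros(6)
        expected[order] = row[0, order]
        np.testing.assert_array_equal(out.values[0], expected)
        assert np.count_nonzero(out.values[0]) == 3

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 9999), st.floats(0.05, 1.0))
    def test_nonzero_count_always_ceil_fraction(self, rseed, frac):
        rng = np.random.default_rng(rseed)
        n_seed, n_targ = rng.integers(2, 8), rng.integers(3, 25)
        vals = rng.normal(size=(n_seed, n_targ))
        conn = ConnectivityMatrix(vals, _vs(int(n_seed)), _vs(int(n_targ), 100))
        out = threshold_rows(conn, frac)
        k = int(np.ceil(frac * n_targ))
        assert np.all(np.count_nonzero(out.values, axis=1) == k)
        assert out.sparsity == "row_thresholded"

    def test_invalid_fraction(self):
        conn = ConnectivityMatrix(np.ones((2, 4)), _vs(2), _vs(4, 100))
        with pytest.raises(ConfigurationError):
            threshold_rows(conn, 0.0)


class TestCosineAffinity:
    def test_hand_computed_cases(self):
        rows = np.array([
            [1.0, 1.0, 0.0],   # a
            [1.0, 0.0, 1.0],   # b: cos(a,b) = 0.5
            [1.0, 1.0, 0.0],   # c: identical to a -> 1
            [0.0, 0.0, 2.0],   # d: disjoint support with a -> 0
        ])
        conn = ConnectivityMatrix(rows, _vs(4), _vs(3, 100),
                                  sparsity="row_thresholded", top_fraction=0.5)
        aff = cosine_affinity(conn)
        assert aff.values[0, 1] == pytest.approx(0.5)
        assert aff.values[0, 2] == pytest.approx(1.0)
        assert aff.values[0, 3] == pytest.approx(0.0)
        np.testing.assert_array_equal(np.diag(aff.values), 1.0)

    def test_negative_cosines_clamped(self):
        rows = np.array([[1.0, 0.0], [-1.0, 0.0]])
        conn = ConnectivityMatrix(rows, _vs(2), _vs(2, 100))
        aff = cosine_affinity(conn)
        assert aff.values[0, 1] == 0.0

    def test_zero_row_warning_and_unit_diagonal(self):
        rows = np.array([[1.0, 2.0], [0.0, 0.0]])
        conn = ConnectivityMatrix(rows, _vs(2), _vs(2, 100))
        with pytest.warns(DegenerateVoxelWarning):
            aff = cosine_affinity(conn)
        assert aff.values[1, 0] == 0.0 and aff.values[1, 1] == 1.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(1, 10**6))
    def test_symmetric_unit_interval_properties(self, rseed):
        """Symmetry, unit diagonal, [0,1] entries over random sparse rows."""
        rng = np.random.default_rng(rseed)
        n_seed, n_targ = int(rng.integers(2, 12)), int(rng.integers(3, 20))
        vals = rng.normal(size=(n_seed, n_targ))
        vals[rng.random(vals.shape) < 0.6] = 0.0
        conn = ConnectivityMatrix(vals, _vs(n_seed), _vs(n_targ, 100))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateVoxelWarning)
            aff = cosine_affinity(conn)
        assert np.max(np.abs(aff.values - aff.values.T)) < 1e-10
        assert aff.values.min() >= 0.0 and aff.values.max() <= 1.0
        np.testing.assert_array_equal(np.diag(aff.values), 1.0)
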