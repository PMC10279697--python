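"""Diffusion embedding against independent spectral oracles."""

import numpy as np
import pytest

from cingrad import (
    AffinityMatrix,
    compare_gradient_maps,
    diffusion_embedding,
    explained_variance_pct,
)
from cingrad.exceptions import AlignmentError, DegenerateDataError, DisconnectedGraphWarning
from conftest import random_affinity


def brute_force_embedding(W, alpha):
    """Independent oracle: eigendecompose the explicitly built transition
    operator with the general (non-symmetric) solver."""
    d = W.sum(axis=1)
    W_a = W / np.outer(d ** alpha, d ** alpha)
    P = W_a / W_a.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


class TestEmbeddingOracle:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_matches_dense_bruteforce(self, alpha):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(10, 51))
            W = random_affinity(rng, n)
            res = diffusion_embedding(AffinityMatrix(W), n_components=5,
                                      alpha=alpha)
            evals, evecs = brute_force_embedding(W, alpha)
            assert evals[0] == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(res.eigenvalues, evals[1:6], atol=1e-10)
            for g in range(5):
                _, abs_r = compare_gradient_maps(res.gradient_maps[:, g],
                                                 evecs[:, g + 1])
                assert abs_r == pytest.approx(1.0, abs=1e-8)

    def test_two_block_affinity_separates_blocks(self):
        """Two disjoint all-ones blocks: gradient 1 is piecewise constant
        with opposite signs across the blocks."""
        W = np.zeros((10, 10))
        W[:5, :5] = 1.0
        W[5:, 5:] = 1.0
        with pytest.warns(DisconnectedGraphWarning):
            res = diffusion_embedding(AffinityMatrix(W), n_components=2)
        g1 = res.gradient_maps[:, 0]
        assert np.allclose(g1[:5], g1[0], atol=1e-8)
        assert np.allclose(g1[5:], g1[5], atol=1e-8)
        assert g1[0] * g1[5] < 0

    def test_eigenvalues_bounded_and_nonincreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            W = random_affinity(rng, int(rng.integers(8, 30)))
            res = diffusion_embedding(AffinityMatrix(W), n_components=5)
            assert np.all(res.spectrum <= 1.0 + 1e-12)
            assert np.all(np.diff(res.spectrum) <= 1e-12)

    def test_ring_graph_circulant_spectrum(self):
        """8-node ring with unit self-loops: the transition operator is
        circulant with eigenvalues (1 + 2 cos(2 pi m / 8)) / 3."""
        n = 8
        W = np.eye(n)
        for i in range(n):
            W[i, (i + 1) % n] = W[i, (i - 1) % n] = 1.0
        res = diffusion_embedding(AffinityMatrix(W), n_components=6, alpha=0.5)
        analytic = np.sort(
            [(1 + 2 * np.cos(2 * np.pi * m / n)) / 3 for m in range(1, n)]
        )[::-1]
        np.testing.assert_allclose(res.spectrum, analytic, atol=1e-10)

    def test_asymmetric_input_rejected(self):
        W = np.eye(5)
        W[0, 1] = 0.5
        with pytest.raises(AlignmentError):
            diffusion_embedding(AffinityMatrix(W), n_components=2)

    def test_diffusion_time_scales_by_eigenvalue_power(self):
        rng = np.random.default_rng(3)
        W = random_affinity(rng, 20)
        r0 = diffusion_embedding(AffinityMatrix(W), n_components=4)
        r2 = diffusion_embedding(AffinityMatrix(W), n_components=4,
                                 diffusion_time=2.0)
        scale = np.linalg.norm(r2.gradient_maps, axis=0)
        np.testing.assert_allclose(scale, np.clip(r0.eigenvalues, 0, None) ** 2,
                                   atol=1e-8)

    def test_sign_convention_deterministic(self, default_dataset):
        from cingrad.connectome import (
            compute_fc, cosine_affinity, standardize_and_concatenate,
            threshold_rows,
        )
        ds = default_dataset
        sc = standardize_and_concatenate([s for s, _ in ds.subject_series[:3]])
        tc = standardize_and_concatenate([t for _, t in ds.subject_series[:3]])
        aff = cosine_affinity(threshold_rows(compute_fc(sc, tc), 0.1))
        a = diffusion_embedding(aff, n_components=3, voxel_set=ds.seed_voxels)
        b = diffusion_embedding(aff, n_components=3, voxel_set=ds.seed_voxels)
        np.testing.assert_array_equal(a.gradient_maps, b.gradient_maps)


class TestExplainedVariance:
    def test_ratio_arithmetic(self):
        np.testing.assert_allclose(explained_variance_pct([4.0, 2.0, 2.0]),
                                   [50.0, 25.0, 25.0])
        np.testing.assert_allclose(explained_variance_pct([1.0]), [100.0])

    def test_full_spectrum_sums_to_100(self, default_dataset):
        from cingrad.connectome import (
            compute_fc, cosine_affinity, standardize_and_concatenate,
            threshold_rows,
        )
        ds = default_dataset
        sc = standardize_and_concatenate([s for s, _ in ds.subject_series])
        tc = standardize_and_concatenate([t for _, t in ds.subject_series])
        aff = cosine_affinity(threshold_rows(compute_fc(sc, tc), 0.1))
        res = diffusion_embedding(aff, n_components=10,
                                  voxel_set=ds.seed_voxels)
        pct = explained_variance_pct(np.clip(res.spectrum, 0, None))
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(res.explained_variance_pct, pct[:10])

    def test_all_zero_spectrum_is_error(self):
        with pytest.raises(DegenerateDataError):
            explained_variance_pct(np.zeros(4))


class TestCompareGradientMaps:
    def test_self_and_sign_flip(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        assert compare_gradient_maps(a, a) == (pytest.approx(1.0), pytest.approx(1.0))
        r, abs_r = compare_gradient_maps(a, -a)
        assert r == pytest.approx(-1.0)
        assert abs_r == pytest.approx(1.0)

    def test_permuted_map_decorrelates(self):
        """Independent permutations of a map give |r| concentrated near 0;
        tabulated null over 1000 shuffles of a 200-voxel map."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        abs_rs = np.array([
            compare_gradient_maps(a, rng.permutation(a))[1]
            for _ in range(1000)
        ])
        # |r| of independent permutations ~ |N(0, 1/sqrt(n-1))|
        assert np.median(abs_rs) < 3.0 / np.sqrt(199)
        assert abs_rs.max() < 0.35

    def test_constant_map_is_error(self):
        with pytest.raises(DegenerateDataError):
            compare_gradient_maps(np.ones(10), np.arange(10.0))
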