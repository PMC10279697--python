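"""Diffusion-map embedding of a connectivity affinity matrix.

Given a positive symmetric affinity matrix W, the embedding (a) removes the
influence of sampling density with the anisotropic normalization
W_a = W / (d^alpha d^alpha^T), where d is the degree vector and alpha in
[0, 1] (alpha = 0.5 balances manifold geometry against point density and is
the convention for brain connectivity data); (b) row-normalizes W_a to a
Markov transition operator P; (c) eigendecomposes P. The leading eigenvector
of P is constant (eigenvalue 1) and is discarded; the remaining eigenvectors,
ordered by eigenvalue, are the connectivity *gradients* — spatial axes along
which connectivity profiles change gradually. Optionally each gradient is
scaled by lambda^t (diffusion time t; t = 0 leaves eigenvectors unscaled).

The eigenproblem is solved through the symmetric conjugate
S = D^{-1/2} W_a D^{-1/2}, which shares eigenvalues with P; right
eigenvectors of P are recovered as v / sqrt(d). A dense solver is used up to
5000 voxels and a Lanczos solver above.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import scipy.linalg
import scipy.sparse.linalg
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr

from .containers import AffinityMatrix, GradientResult, VoxelSet
from .exceptions import AlignmentError, DegenerateDataError, DisconnectedGraphWarning

__all__ = ["diffusion_embedding", "explained_variance_pct", "compare_gradient_maps"]

_DENSE_LIMIT = 5000


def _orient_sign(gradients: np.ndarray, voxel_set: Optional[VoxelSet]) -> np.ndarray:
    """Deterministic sign convention for the (arbitrary-sign) eigenvectors.

    Each gradient is flipped, if needed, so that its correlation with the
    seed-voxel coordinate axis of largest absolute loading is positive.
    Without coordinates, the entry of largest magnitude is made positive.
    """
    out = gradients.copy()
    coords = None
    if voxel_set is not None:
        coords = voxel_set.world_coords_mm - voxel_set.world_coords_mm.mean(axis=0)
    for g in range(out.shape[1]):
        col = out[:, g]
        if np.allclose(col, col[0]):
            continue
        flipped = False
        if coords is not None:
            cc = col - col.mean()
            denom = np.linalg.norm(cc)
            rs = np.zeros(3)
            for ax in range(3):
                ax_c = coords[:, ax]
                n2 = np.linalg.norm(ax_c)
                if n2 > 0 and denom > 0:
                    rs[ax] = float(cc @ ax_c) / (denom * n2)
            if np.any(np.abs(rs) > 1e-12):
                best = int(np.argmax(np.abs(rs)))
                if rs[best] < 0:
                    out[:, g] = -col
                flipped = True
        if not flipped:
            peak = int(np.argmax(np.abs(col)))
            if col[peak] < 0:
                out[:, g] = -col
    return out


def diffusion_embedding(affinity: AffinityMatrix, n_components: int = 10,
                        alpha: float = 0.5, diffusion_time: float = 0.0,
                        seed: int = 0,
                        voxel_set: Optional[VoxelSet] = None) -> GradientResult:
    """Embed an affinity matrix into its leading connectivity gradients.

    Parameters
    ----------
    affinity
        Valid affinity matrix (symmetric, entries in [0, 1], unit diagonal).
    n_components
        Number of nontrivial gradients to return (< n_voxels - 1).
    alpha
        Anisotropic diffusion parameter in [0, 1].
    diffusion_time
        Eigenvector scaling exponent; 0 returns unscaled eigenvectors.
    seed
        Seeds the Lanczos starting vector on the iterative path; the dense
        path is deterministic regardless.
    voxel_set
        Optional voxel set used for the sign convention and carried into the
        result.

    A disconnected affinity graph triggers a warning but the embedding
    proceeds on the full matrix; an asymmetric input is an error.
    """
    W = affinity.values
    n = W.shape[0]
    if not 0 <= alpha <= 1:
        raise DegenerateDataError(f"alpha must be in [0, 1], got {alpha}")
    if diffusion_time < 0:
        raise DegenerateDataError("diffusion_time must be nonnegative")
    if not 1 <= n_components < n - 1:
        raise DegenerateDataError(
            f"n_components must be in [1, {n - 2}], got {n_components}"
        )
    if np.max(np.abs(W - W.T)) >= 1e-10:
        raise AlignmentError("affinity matrix must be symmetric")

    n_comp_graph, _ = connected_components(W > 0, directed=False)
    if n_comp_graph > 1:
        warnings.warn(
            f"affinity graph has {n_comp_graph} connected components; "
            "embedding the full matrix anyway",
            DisconnectedGraphWarning,
        )

    d = W.sum(axis=1)
    d_alpha = np.power(d, alpha)
    W_a = W / np.outer(d_alpha, d_alpha)
    d2 = W_a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d2)
    S = W_a * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0

    if n <= _DENSE_LIMIT:
        evals, evecs = scipy.linalg.eigh(S)
        evals = evals[::-1]
        evecs = evecs[:, ::-1]
    else:
        rng = np.random.default_rng(seed)
        k = min(n - 1, n_components + 1)
        evals, evecs = scipy.sparse.linalg.eigsh(
            S, k=k, which="LA", v0=rng.standard_normal(n))
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]

    # With a disconnected graph the top eigenvalue is degenerate and the
    # solver returns an arbitrary basis of that eigenspace; rotate it so the
    # trivial (constant) eigenvector is the one in slot 0 and gets dropped.
    top = np.flatnonzero(evals[0] - evals <= 1e-12)
    if top.size > 1:
        B = evecs[:, top]
        v0 = np.sqrt(d2)
        v0 /= np.linalg.norm(v0)
        c = B.T @ v0
        nc = np.linalg.norm(c)
        if nc > 1e-12:
            c /= nc
            Q, _ = np.linalg.qr(np.column_stack([c, np.eye(top.size)]))
            Q = Q[:, :top.size]
            Q[:, 0] *= np.sign(c @ Q[:, 0])
            evecs[:, top] = B @ Q

    # right eigenvectors of the transition operator; index 0 is the trivial
    # constant eigenvector (eigenvalue 1 for a connected graph)
    psi = evecs * inv_sqrt[:, None]
    spectrum = evals[1:]
    comps = psi[:, 1:1 + n_components]
    comps = comps / np.linalg.norm(comps, axis=0)
    lam = spectrum[:n_components]
    if diffusion_time > 0:
        comps = comps * np.power(np.clip(lam, 0.0, None), diffusion_time)

    comps = _orient_sign(comps, voxel_set)
    ev_pct_full = explained_variance_pct(np.clip(spectrum, 0.0, None))
    return GradientResult(
        gradient_maps=comps,
        eigenvalues=lam.copy(),
        explained_variance_pct=ev_pct_full[:n_components],
        spectrum=spectrum.copy(),
        alpha=alpha,
        diffusion_time=diffusion_time,
        kernel=affinity.kernel,
        voxel_set=voxel_set,
    )


def explained_variance_pct(eigenvalues: np.ndarray) -> np.ndarray:
    """Percent of the spectrum carried by each component.

    ``eigenvalues`` is the full nontrivial spectrum, nonnegative and sorted
    descending; component g maps to 100 * lambda_g / sum(lambda).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.all(lam == 0):
        raise DegenerateDataError("all-zero spectrum: explained variance undefined")
    if np.any(lam < 0):
        raise DegenerateDataError("eigenvalues must be nonnegative")
    if np.any(np.diff(lam) > 1e-12):
        raise DegenerateDataError("eigenvalues must be sorted descending")
    return 100.0 * lam / lam.sum()


def compare_gradient_maps(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Cross-voxel Pearson r between two gradient maps, and its magnitude.

    The magnitude |r| is the robustness metric: eigenvector signs are
    arbitrary, so two pipelines may legitimately return flipped maps.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise AlignmentError(f"map lengths differ: {a.size} vs {b.size}")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise DegenerateDataError("constant map: correlation undefined")
    r = float(pearsonr(a, b).statistic)
    return r, abs(r)
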