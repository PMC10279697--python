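"""Seed-to-target functional connectivity: construction, confound handling,
row sparsification, and the cosine affinity matrix.

The workflow mirrors the standard gradient-analysis recipe: per-subject
z-scored BOLD series are concatenated in time (or correlated per subject and
averaged), seed-to-target Pearson correlations are Fisher z-transformed, each
row is thresholded to its strongest connections, and pairwise cosine
similarity of the sparse rows yields a positive symmetric affinity matrix.
"""

from __future__ import annotations

import warnings
from typing import List, Optional

import numpy as np
import scipy.linalg

from .containers import AffinityMatrix, ConnectivityMatrix, TimeSeriesMatrix
from .exceptions import (
    AlignmentError,
    ConfigurationError,
    DegenerateVoxelWarning,
    RankDeficiencyWarning,
)

__all__ = [
    "standardize_and_concatenate",
    "regress_confounds",
    "extract_compcor_components",
    "compute_fc",
    "threshold_rows",
    "cosine_affinity",
]

_FISHER_CAP = 1.0 - 1e-7  # |r| clip before atanh, keeps self-connections finite


def _zscore_columns(values: np.ndarray, warn: bool = True) -> np.ndarray:
    """Population (ddof=0) z-score per column; zero-variance columns -> 0."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    flat = sd == 0
    if np.any(flat) and warn:
        warnings.warn(
            f"{int(flat.sum())} zero-variance voxel column(s) set to zero",
            DegenerateVoxelWarning,
        )
    sd = np.where(flat, 1.0, sd)
    out = (values - mean) / sd
    out[:, flat] = 0.0
    return out


def standardize_and_concatenate(series_list: List[TimeSeriesMatrix]) -> TimeSeriesMatrix:
    """Z-score each subject's series per voxel, then stack along time.

    All series must share one voxel set and have at least 3 timepoints.
    The result is marked ``standardized``; its row count is the sum of the
    subjects' timepoints. Zero-variance columns are zeroed with a warning.
    """
    if not series_list:
        raise AlignmentError("empty series list")
    ref = series_list[0].voxel_set
    for ts in series_list:
        if not ts.voxel_set.equals(ref):
            raise AlignmentError(
                f"series {ts.subject_id!r} is bound to a different voxel set"
            )
        if ts.n_timepoints < 3:
            raise AlignmentError(
                f"series {ts.subject_id!r} has fewer than 3 timepoints"
            )
    blocks = [_zscore_columns(ts.values) for ts in series_list]
    return TimeSeriesMatrix(
        np.vstack(blocks),
        ref,
        subject_id="+".join(ts.subject_id for ts in series_list),
        standardized=True,
    )


def regress_confounds(series: TimeSeriesMatrix,
                      confounds: np.ndarray) -> TimeSeriesMatrix:
    """Residualize every voxel column against [intercept, confounds].

    Linearly dependent confound columns are dropped with a warning. The
    residual columns are orthogonal to each retained confound.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != series.n_timepoints:
        if confounds.shape[1] == series.n_timepoints:
            confounds = confounds.T
        else:
            raise AlignmentError(
                f"confound rows {confounds.shape[0]} do not match series "
                f"timepoints {series.n_timepoints}"
            )
    if confounds.shape[1] < 1:
        raise ConfigurationError("need at least one confound column")

    X = np.column_stack([np.ones(series.n_timepoints), confounds])
    # rank-revealing QR to drop dependent columns (intercept always kept)
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = X.shape[1] - rank
        warnings.warn(
            f"dropped {dropped} linearly dependent confound column(s)",
            RankDeficiencyWarning,
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    resid = series.values - X @ beta
    return TimeSeriesMatrix(resid, series.voxel_set,
                            subject_id=series.subject_id, standardized=False)


def extract_compcor_components(series: TimeSeriesMatrix,
                               n_components: int) -> np.ndarray:
    """Top principal component time courses of a noise-region series.

    Columns are standardized first; the returned ``timepoints x k`` matrix
    holds the leading left singular vectors — orthonormal, ordered by
    explained variance, with a deterministic sign convention.
    """
    if n_components < 1:
        raise ConfigurationError("n_components must be >= 1")
    if series.n_timepoints < n_components + 1:
        raise ConfigurationError(
            f"need at least {n_components + 1} timepoints for "
            f"{n_components} components"
        )
    Z = _zscore_columns(series.values, warn=False)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    if n_components > np.sum(s > s[0] * max(Z.shape) * np.finfo(float).eps):
        raise ConfigurationError(
            f"n_components={n_components} exceeds matrix rank"
        )
    comps = U[:, :n_components]
    # orient each component so its largest-|u| element is positive
    idx = np.argmax(np.abs(comps), axis=0)
    comps = comps * np.sign(comps[idx, np.arange(n_components)])
    return comps


def compute_fc(seed_series: TimeSeriesMatrix, target_series: TimeSeriesMatrix,
               apply_fisher: bool = True,
               allow_overlap: bool = False) -> ConnectivityMatrix:
    """Pearson correlation of every seed voxel with every target voxel.

    With ``apply_fisher`` the correlations are passed through atanh after
    clipping to +/-(1 - 1e-7), so self-identical voxel pairs stay finite.
    Seed and target voxel sets must be disjoint unless ``allow_overlap``
    (the include-seed-in-target validation mode). Zero-variance voxels give
    zero rows/columns with a warning.
    """
    if seed_series.n_timepoints != target_series.n_timepoints:
        raise AlignmentError(
            f"timepoint mismatch: {seed_series.n_timepoints} vs "
            f"{target_series.n_timepoints}"
        )
    if not allow_overlap and seed_series.voxel_set.overlaps(target_series.voxel_set):
        raise AlignmentError(
            "seed and target voxel sets overlap; pass allow_overlap=True for "
            "the include-seed-in-target mode"
        )

    def _unit_columns(values):
        c = values - values.mean(axis=0)
        norm = np.linalg.norm(c, axis=0)
        flat = norm == 0
        if np.any(flat):
            warnings.warn(
                f"{int(flat.sum())} zero-variance voxel(s): connectivity set to 0",
                DegenerateVoxelWarning,
            )
        norm = np.where(flat, 1.0, norm)
        out = c / norm
        out[:, flat] = 0.0
        return out

    r = _unit_columns(seed_series.values).T @ _unit_columns(target_series.values)
    np.clip(r, -1.0, 1.0, out=r)
    if apply_fisher:
        r = np.arctanh(np.clip(r, -_FISHER_CAP, _FISHER_CAP))
        scale = "fisher_z"
    else:
        scale = "pearson_r"
    return ConnectivityMatrix(r, seed_series.voxel_set, target_series.voxel_set,
                              scale=scale, sparsity="dense")


def threshold_rows(conn: ConnectivityMatrix,
                   top_fraction: float) -> ConnectivityMatrix:
    """Keep the top fraction of connections per row (by signed value).

    Retains ``k = ceil(top_fraction * n_target)`` entries per row and zeroes
    the rest. Ties at the cutoff are resolved deterministically: larger
    value first, then lower column index.
    """
    if not 0 < top_fraction <= 1:
        raise ConfigurationError(
            f"top_fraction must be in (0, 1], got {top_fraction}"
        )
    if conn.sparsity != "dense":
        raise ConfigurationError("connectivity matrix is already thresholded")
    n = conn.n_target
    k = int(np.ceil(top_fraction * n))
    # stable argsort of -values: descending value, ties by ascending column
    order = np.argsort(-conn.values, axis=1, kind="stable")
    out = np.zeros_like(conn.values)
    rows = np.arange(conn.n_seed)[:, None]
    keep = order[:, :k]
    out[rows, keep] = conn.values[rows, keep]
    return ConnectivityMatrix(out, conn.seed_set, conn.target_set,
                              scale=conn.scale, sparsity="row_thresholded",
                              top_fraction=top_fraction)


def cosine_affinity(conn: ConnectivityMatrix,
                    kernel: str = "clamped_cosine") -> AffinityMatrix:
    """Pairwise cosine similarity of (sparsified) connectivity rows.

    ``clamped_cosine`` (default) maps negative cosines to 0 so the affinity
    is positive as the embedding requires; ``normalized_angle`` instead uses
    1 - arccos(cos)/pi. The diagonal is 1 and the output exactly symmetric.
    All-zero rows give zero affinity (unit diagonal) with a warning.
    """
    if kernel not in ("clamped_cosine", "normalized_angle"):
        raise ConfigurationError(f"unknown affinity kernel {kernel!r}")
    X = conn.values
    norms = np.linalg.norm(X, axis=1)
    flat = norms == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} all-zero connectivity row(s): affinity row "
            "zeroed except unit diagonal",
            DegenerateVoxelWarning,
        )
    norms = np.where(flat, 1.0, norms)
    Xn = X / norms[:, None]
    C = Xn @ Xn.T
    C = (C + C.T) / 2.0
    np.clip(C, -1.0, 1.0, out=C)
    if kernel == "clamped_cosine":
        np.clip(C, 0.0, None, out=C)
    else:
        C = 1.0 - np.arccos(C) / np.pi
    C[flat, :] = 0.0
    C[:, flat] = 0.0
    np.fill_diagonal(C, 1.0)
    return AffinityMatrix(C, kernel=kernel)
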