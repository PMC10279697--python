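"""Core data containers shared by every stage of the gradient pipeline.

The central contract is the *canonical voxel ordering*: a :class:`VoxelSet`
fixes the order of voxels once (ascending linear grid index, x fastest), and
every matrix, map, and table that refers to those voxels uses that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import AlignmentError

__all__ = [
    "VoxelSet",
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "AffinityMatrix",
    "GradientResult",
]


@dataclass(eq=False)
class VoxelSet:
    """An ordered collection of voxels with grid indices and mm coordinates.

    Parameters
    ----------
    ids
        Unique, strictly increasing integer identifiers. By convention the id
        of a voxel is its linear index into the enclosing volume with the
        first (x) axis varying fastest (Fortran ravel order).
    grid_indices
        ``(n, 3)`` integer array of (i, j, k) grid positions.
    world_coords_mm
        ``(n, 3)`` float array of world-space coordinates in millimeters
        (grid indices pushed through the volume affine).
    source_mask
        Provenance label, e.g. the mask filename or ``"synthetic-seed"``.
    volume_shape, affine
        Optional provenance of the enclosing volume, required when maps over
        this set are written back to NIfTI.
    """

    ids: np.ndarray
    grid_indices: np.ndarray
    world_coords_mm: np.ndarray
    source_mask: str = ""
    volume_shape: Optional[tuple] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.grid_indices = np.asarray(self.grid_indices, dtype=np.int64)
        self.world_coords_mm = np.asarray(self.world_coords_mm, dtype=float)
        if self.ids.ndim != 1:
            raise AlignmentError("voxel ids must be one-dimensional")
        n = self.ids.size
        if self.grid_indices.shape != (n, 3) or self.world_coords_mm.shape != (n, 3):
            raise AlignmentError(
                f"coordinate arrays must be (n, 3) with n={n}; got "
                f"{self.grid_indices.shape} and {self.world_coords_mm.shape}"
            )
        if n and (np.unique(self.ids).size != n or np.any(np.diff(self.ids) <= 0)):
            raise AlignmentError("voxel ids must be unique and strictly increasing")

    def __len__(self) -> int:
        return int(self.ids.size)

    def equals(self, other: "VoxelSet") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.ids, other.ids)
            and np.array_equal(self.grid_indices, other.grid_indices)
        )

    def overlaps(self, other: "VoxelSet") -> bool:
        """Whether any voxel (by grid index) appears in both sets."""
        a = {tuple(r) for r in self.grid_indices}
        b = {tuple(r) for r in other.grid_indices}
        return bool(a & b)


@dataclass(eq=False)
class TimeSeriesMatrix:
    """A timepoints x voxels signal matrix bound to a :class:`VoxelSet`."""

    values: np.ndarray
    voxel_set: VoxelSet
    subject_id: str = ""
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise AlignmentError("time series values must be 2-D (time x voxels)")
        if self.values.shape[1] != len(self.voxel_set):
            raise AlignmentError(
                f"column count {self.values.shape[1]} does not match voxel set "
                f"size {len(self.voxel_set)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise AlignmentError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass(eq=False)
class ConnectivityMatrix:
    """Seed-voxels x target-voxels functional connectivity matrix.

    ``scale`` records whether entries are raw Pearson r (``"pearson_r"``) or
    Fisher z (``"fisher_z"``); ``sparsity`` is ``"dense"`` or
    ``"row_thresholded"`` with the retained ``top_fraction``.
    """

    values: np.ndarray
    seed_set: VoxelSet
    target_set: VoxelSet
    scale: str = "pearson_r"
    sparsity: str = "dense"
    top_fraction: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.seed_set), len(self.target_set))
        if self.values.shape != expected:
            raise AlignmentError(
                f"connectivity shape {self.values.shape} does not match voxel "
                f"sets {expected}"
            )
        if np.any(np.isnan(self.values)):
            raise AlignmentError("connectivity matrix contains NaN")

    @property
    def n_seed(self) -> int:
        return self.values.shape[0]

    @property
    def n_target(self) -> int:
        return self.values.shape[1]


@dataclass(eq=False)
class AffinityMatrix:
    """Symmetric nonnegative seed x seed similarity of connectivity profiles."""

    values: np.ndarray
    kernel: str = "clamped_cosine"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise AlignmentError("affinity matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        v = self.values
        if np.max(np.abs(v - v.T)) >= atol:
            raise AlignmentError("affinity matrix is not symmetric")
        if v.min() < -atol or v.max() > 1 + 1e-9:
            raise AlignmentError("affinity entries must lie in [0, 1]")


@dataclass(eq=False)
class GradientResult:
    """Output of the diffusion-map embedding.

    Attributes
    ----------
    gradient_maps
        ``(n_seed, k)`` array; column g is the g-th connectivity gradient
        (the trivial constant eigenvector is excluded).
    eigenvalues
        Eigenvalues of the diffusion operator for the returned components,
        in non-increasing order.
    explained_variance_pct
        Percent of the positive nontrivial spectrum carried by each returned
        component (100 * lambda_g / sum of positive nontrivial lambdas).
    spectrum
        The full nontrivial eigenvalue spectrum (descending), kept so that
        explained-variance conventions can be recomputed.
    """

    gradient_maps: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_pct: np.ndarray
    spectrum: np.ndarray
    alpha: float
    diffusion_time: float
    kernel: str = ""
    voxel_set: Optional[VoxelSet] = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.gradient_maps.shape[1]
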