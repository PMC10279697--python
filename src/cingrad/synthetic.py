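"""Synthetic resting-state datasets with planted connectivity-gradient structure.

The generator emulates the statistical situation the gradient pipeline is
built for: a block of *seed* voxels whose connectivity profiles to a larger
*target* (cerebrum stand-in) region vary smoothly along known spatial axes.
Each of ``n_networks`` canonical networks is represented by one latent time
course per subject; target voxels carry their network's latent plus white
noise, and each seed voxel carries a convex mixture of the latents whose
weights change along the voxel's projection onto the planted axes via
logistic ramps. Because the mixture weights are stored, every downstream
stage (embedding, parcellation, decoding, geometry, morphometry) has exact
ground truth.

The latent time courses are drawn white (no autocorrelation) and are made
exactly orthonormal within each subject, so that in the zero-noise limit a
seed voxel's correlation with a network latent is proportional to its
mixture weight — this is what makes the winner-take-all exactness oracle
hold to machine precision.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .containers import TimeSeriesMatrix, VoxelSet
from .exceptions import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "make_synthetic_dataset",
    "write_synthetic_as_nifti",
    "DEFAULT_NETWORK_NAMES",
]

# Canonical seven-network naming, reused when n_networks == 7.
DEFAULT_NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

_RAMP_SLOPE = 4.0   # logistic ramp slope, per min-max-normalized axis unit
_AXIS2_MOD = 0.3    # secondary-axis weight modulation amplitude
_AXIS3_MOD = 0.15   # tertiary-axis weight modulation amplitude
_BOUND_OFFSET = 1e-3  # boundary nudge avoiding exact weight ties at voxels


@dataclass
class SyntheticConfig:
    """Parameters of the planted-gradient generator.

    ``noise_sd`` is the standard deviation of additive white noise relative
    to the unit-variance latent network signals. ``planted_axes`` is an
    ``(a, 3)`` array (a <= 3) of unit, mutually orthogonal direction vectors
    in seed-grid space; defaults to the grid axes x, y, z.
    """

    n_seed_voxels: int = 300
    n_target_voxels: int = 2000
    n_networks: int = 7
    n_timepoints: int = 200
    n_subjects: int = 10
    noise_sd: float = 0.5
    n_noise_voxels: int = 50
    planted_axes: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.planted_axes is None:
            self.planted_axes = np.eye(3)
        self.planted_axes = np.asarray(self.planted_axes, dtype=float)
        if self.planted_axes.ndim == 1:
            self.planted_axes = self.planted_axes[None, :]

    def validate(self) -> None:
        for name in ("n_seed_voxels", "n_target_voxels", "n_networks",
                     "n_timepoints", "n_subjects", "n_noise_voxels"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if self.n_seed_voxels < 10:
            raise ConfigurationError("n_seed_voxels must be >= 10")
        if self.n_target_voxels < self.n_networks:
            raise ConfigurationError("n_target_voxels must be >= n_networks")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.n_networks > self.n_timepoints:
            raise ConfigurationError("n_networks must not exceed n_timepoints")
        A = self.planted_axes
        if A.shape[0] > 3 or A.shape[1] != 3:
            raise ConfigurationError("planted_axes must be at most 3 vectors of length 3")
        gram = A @ A.T
        if not np.allclose(gram, np.eye(A.shape[0]), atol=1e-8):
            raise ConfigurationError("planted_axes must be unit-length and mutually orthogonal")


@dataclass(eq=False)
class SyntheticDataset:
    """A realized synthetic dataset with its generating ground truth."""

    seed_voxels: VoxelSet
    target_voxels: VoxelSet
    noise_voxels: VoxelSet
    subject_series: List[Tuple[TimeSeriesMatrix, TimeSeriesMatrix]]
    noise_series: List[TimeSeriesMatrix]
    true_gradient_maps: np.ndarray          # (n_seed, n_axes), zero mean per column
    mixture_weights: np.ndarray             # (n_seed, n_networks), rows sum to 1
    dominant_network: np.ndarray            # (n_seed,), 1-based argmax of weights
    network_labels: np.ndarray              # (n_target,), 1-based
    network_names: Dict[int, str]
    term_maps: Dict[str, np.ndarray]        # term -> (n_seed,) z-like map
    gmv_map: np.ndarray                     # (n_seed,), nonnegative
    generator_log: dict = field(default_factory=dict)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)


def _box_dims(n: int, aspect: float = 0.75) -> Tuple[int, int, int]:
    """Box dimensions elongated along x that hold at least n voxels."""
    side = max(2, int(round(n ** (1.0 / 3.0) * aspect)))
    nx = math.ceil(n / (side * side))
    return nx, side, side


def _grid_voxels(n: int, dims: Tuple[int, int, int],
                 offset: Tuple[int, int, int] = (0, 0, 0)) -> np.ndarray:
    """First n grid triples of a box in x-fastest linear order."""
    nx, ny, nz = dims
    lin = np.arange(n)
    i = lin % nx
    j = (lin // nx) % ny
    k = lin // (nx * ny)
    return np.stack([i, j, k], axis=1) + np.asarray(offset)


def _voxelset_from_grid(grid: np.ndarray, volume_shape: Tuple[int, int, int],
                        label: str) -> VoxelSet:
    ids = np.ravel_multi_index(grid.T, volume_shape, order="F")
    order = np.argsort(ids)
    grid = grid[order]
    return VoxelSet(
        ids=ids[order],
        grid_indices=grid,
        world_coords_mm=grid.astype(float),  # identity affine: 1 mm isotropic
        source_mask=label,
        volume_shape=tuple(volume_shape),
        affine=np.eye(4),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _mixture_weights(proj: np.ndarray, n_networks: int) -> np.ndarray:
    """Convex network weights varying along planted-axis projections.

    Each projection is min-max normalized to [0, 1] so the logistic ramp
    slope is expressed per axis length and the transition width scales with
    the seed region. Along the first axis the range is split into
    ``n_networks`` equal-count bands with soft (slope 4) edges — for two
    networks this is a single ramp with midpoint at the axis median;
    additional axes multiplicatively modulate alternating networks, giving
    secondary structure without displacing the first-axis organization.
    Band boundaries and modulation midpoints are nudged by 1e-3 so that no
    voxel sits exactly on a boundary, which would create machine-precision
    weight ties and make the dominant network ill-defined.
    """
    n_vox, n_axes = proj.shape
    span = proj.max(axis=0) - proj.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    P = (proj - proj.min(axis=0)) / span
    t1 = P[:, 0]
    bounds = np.quantile(t1, np.arange(1, n_networks) / n_networks) + _BOUND_OFFSET
    raw = np.ones((n_vox, n_networks))
    for m in range(n_networks):
        w = np.ones(n_vox)
        if m > 0:
            w = w * _sigmoid(_RAMP_SLOPE * (t1 - bounds[m - 1]))
        if m < n_networks - 1:
            w = w * _sigmoid(-_RAMP_SLOPE * (t1 - bounds[m]))
        raw[:, m] = w
    if n_axes >= 2 and n_networks >= 2:
        mid = np.median(P[:, 1]) + _BOUND_OFFSET
        g2 = _sigmoid(_RAMP_SLOPE * (P[:, 1] - mid)) - 0.5
        signs = np.where(np.arange(n_networks) % 2 == 0, 1.0, -1.0)
        raw *= 1.0 + 2.0 * _AXIS2_MOD * np.outer(g2, signs)
    if n_axes >= 3 and n_networks >= 3:
        mid = np.median(P[:, 2]) + _BOUND_OFFSET
        g3 = _sigmoid(_RAMP_SLOPE * (P[:, 2] - mid)) - 0.5
        signs = np.where((np.arange(n_networks) // 2) % 2 == 0, 1.0, -1.0)
        raw *= 1.0 + 2.0 * _AXIS3_MOD * np.outer(g3, signs)
    return raw / raw.sum(axis=1, keepdims=True)


def _orthonormal_latents(rng: np.random.Generator, n_timepoints: int,
                         n_networks: int) -> np.ndarray:
    """Zero-mean, exactly orthogonal, unit-variance latent time courses."""
    X = rng.standard_normal((n_timepoints, n_networks))
    X -= X.mean(axis=0)
    Q, R = np.linalg.qr(X)
    Q = Q * np.sign(np.diag(R))  # deterministic orientation
    # columns of Q are zero-mean (span of centered columns) and orthonormal;
    # rescale to unit population variance
    return Q * np.sqrt(n_timepoints)


def make_synthetic_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset with planted gradients; deterministic given seed.

    See the module docstring for the construction. Raises
    :class:`~cingrad.exceptions.ConfigurationError` naming the offending
    field for an invalid configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    seed_dims = _box_dims(config.n_seed_voxels)
    gap = 3
    targ_dims = _box_dims(config.n_target_voxels)
    noise_dims = _box_dims(config.n_noise_voxels)
    targ_off = (seed_dims[0] + gap, 0, 0)
    noise_off = (seed_dims[0] + gap + targ_dims[0] + gap, 0, 0)

    seed_grid = _grid_voxels(config.n_seed_voxels, seed_dims)
    targ_grid = _grid_voxels(config.n_target_voxels, targ_dims, targ_off)
    noise_grid = _grid_voxels(config.n_noise_voxels, noise_dims, noise_off)

    volume_shape = (
        noise_off[0] + noise_dims[0],
        max(seed_dims[1], targ_dims[1], noise_dims[1]),
        max(seed_dims[2], targ_dims[2], noise_dims[2]),
    )
    seed_vs = _voxelset_from_grid(seed_grid, volume_shape, "synthetic-seed")
    targ_vs = _voxelset_from_grid(targ_grid, volume_shape, "synthetic-target")
    noise_vs = _voxelset_from_grid(noise_grid, volume_shape, "synthetic-noise")

    axes = config.planted_axes
    proj = seed_vs.grid_indices.astype(float) @ axes.T
    weights = _mixture_weights(proj, config.n_networks)
    dominant = np.argmax(weights, axis=1) + 1

    labels = (np.arange(config.n_target_voxels) % config.n_networks) + 1
    if config.n_networks == len(DEFAULT_NETWORK_NAMES):
        names = {m + 1: DEFAULT_NETWORK_NAMES[m] for m in range(config.n_networks)}
    else:
        names = {m + 1: f"network_{m + 1}" for m in range(config.n_networks)}

    subject_series = []
    noise_series = []
    for s in range(config.n_subjects):
        latents = _orthonormal_latents(rng, config.n_timepoints, config.n_networks)
        targ = latents[:, labels - 1] + rng.normal(
            0.0, config.noise_sd, (config.n_timepoints, config.n_target_voxels))
        seed = latents @ weights.T + rng.normal(
            0.0, config.noise_sd, (config.n_timepoints, config.n_seed_voxels))
        pure = rng.standard_normal((config.n_timepoints, config.n_noise_voxels))
        sid = f"sub-{s + 1:02d}"
        subject_series.append((
            TimeSeriesMatrix(seed, seed_vs, subject_id=sid),
            TimeSeriesMatrix(targ, targ_vs, subject_id=sid),
        ))
        noise_series.append(TimeSeriesMatrix(pure, noise_vs, subject_id=sid))

    true_maps = proj - proj.mean(axis=0)
    term_maps = {names[m + 1]: 8.0 * weights[:, m] for m in range(config.n_networks)}
    t_last = proj[:, -1] - proj[:, -1].mean()
    gmv = np.clip(0.6 + 0.08 * t_last + rng.normal(0.0, 0.05, len(seed_vs)), 0.0, None)

    log = {
        "n_seed_voxels": config.n_seed_voxels,
        "n_target_voxels": config.n_target_voxels,
        "n_networks": config.n_networks,
        "n_timepoints": config.n_timepoints,
        "n_subjects": config.n_subjects,
        "noise_sd": config.noise_sd,
        "n_noise_voxels": config.n_noise_voxels,
        "seed": config.seed,
        "seed_box": seed_dims,
        "target_box": targ_dims,
        "volume_shape": volume_shape,
        "ramp_slope": _RAMP_SLOPE,
        "n_planted_axes": axes.shape[0],
    }
    return SyntheticDataset(
        seed_voxels=seed_vs,
        target_voxels=targ_vs,
        noise_voxels=noise_vs,
        subject_series=subject_series,
        noise_series=noise_series,
        true_gradient_maps=true_maps,
        mixture_weights=weights,
        dominant_network=dominant,
        network_labels=labels,
        network_names=names,
        term_maps=term_maps,
        gmv_map=gmv,
        generator_log=log,
    )


def _to_volume(values_per_voxel: np.ndarray, voxel_set: VoxelSet,
               shape: Tuple[int, int, int], dtype) -> np.ndarray:
    vol = np.zeros(shape, dtype=dtype)
    gi = voxel_set.grid_indices
    vol[gi[:, 0], gi[:, 1], gi[:, 2]] = values_per_voxel
    return vol


def write_synthetic_as_nifti(dataset: SyntheticDataset, directory) -> Dict[str, str]:
    """Write the dataset as NIfTI volumes plus a plain-text manifest.

    Emits one 4D BOLD file per subject (seed + target + noise voxels placed
    in a common volume, identity affine), 3D uint8 masks for seed / target /
    noise, an int16 atlas of network labels over the target voxels, one 3D
    float map per behavioral term, and the GMV map. Returns the manifest as
    a ``key -> path`` dict; the same mapping is written to ``manifest.txt``
    as ``key=path`` lines.
    """
    import nibabel as nib

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    shape = dataset.seed_voxels.volume_shape
    affine = np.eye(4)
    manifest: Dict[str, str] = {}

    def _save(key: str, img_data: np.ndarray) -> None:
        path = os.path.join(directory, f"{key}.nii")
        nib.save(nib.Nifti1Image(img_data, affine), path)
        manifest[key] = path

    for (seed_ts, targ_ts), noise_ts in zip(dataset.subject_series, dataset.noise_series):
        T = seed_ts.n_timepoints
        vol4 = np.zeros(shape + (T,), dtype=np.float32)
        for ts in (seed_ts, targ_ts, noise_ts):
            gi = ts.voxel_set.grid_indices
            vol4[gi[:, 0], gi[:, 1], gi[:, 2], :] = ts.values.T.astype(np.float32)
        _save(f"bold_{seed_ts.subject_id}", vol4)

    ones = lambda vs: _to_volume(np.ones(len(vs)), vs, shape, np.uint8)
    _save("seed_mask", ones(dataset.seed_voxels))
    _save("target_mask", ones(dataset.target_voxels))
    _save("noise_mask", ones(dataset.noise_voxels))
    _save("atlas", _to_volume(dataset.network_labels, dataset.target_voxels,
                              shape, np.int16))
    for term, zmap in dataset.term_maps.items():
        _save(f"term_{term}", _to_volume(zmap.astype(np.float32),
                                         dataset.seed_voxels, shape, np.float32))
    _save("gmv", _to_volume(dataset.gmv_map.astype(np.float32),
                            dataset.seed_voxels, shape, np.float32))

    with open(os.path.join(directory, "manifest.txt"), "w") as fh:
        for key, path in manifest.items():
            fh.write(f"{key}={path}\n")
    return manifest
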