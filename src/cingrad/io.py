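"""NIfTI and tabular I/O with the canonical voxel-ordering contract.

Every reader orders voxels by ascending linear index of the grid with the
first (x) axis varying fastest, and records that ordering in the returned
:class:`~cingrad.containers.VoxelSet`; writers invert it. All volume I/O
goes through nibabel.
"""

from __future__ import annotations

import os
from typing import Dict, Tuple

import nibabel as nib
import numpy as np

from .containers import ConnectivityMatrix, TimeSeriesMatrix, VoxelSet
from .exceptions import AlignmentError

__all__ = [
    "read_mask",
    "read_masked_series",
    "read_scalar_map",
    "read_atlas_labels",
    "read_term_maps",
    "write_seed_map",
    "save_connectivity",
    "load_connectivity",
]


def _load(path):
    img = nib.load(os.fspath(path))
    return img, np.asanyarray(img.dataobj)


def read_mask(mask_path) -> VoxelSet:
    """Read a 3D binary mask into a canonically ordered voxel set."""
    img, data = _load(mask_path)
    if data.ndim != 3:
        raise AlignmentError(f"mask {mask_path} is not 3-D (shape {data.shape})")
    grid = np.argwhere(data > 0)
    if grid.size == 0:
        raise AlignmentError(f"mask {mask_path} is empty")
    ids = np.ravel_multi_index(grid.T, data.shape, order="F")
    order = np.argsort(ids)
    grid = grid[order]
    world = nib.affines.apply_affine(img.affine, grid)
    return VoxelSet(
        ids=ids[order],
        grid_indices=grid,
        world_coords_mm=world,
        source_mask=os.fspath(mask_path),
        volume_shape=tuple(data.shape),
        affine=np.asarray(img.affine),
    )


def read_masked_series(bold_path, mask_path) -> Tuple[TimeSeriesMatrix, VoxelSet]:
    """Extract a timepoints x voxels matrix from a 4D volume under a mask."""
    vs = read_mask(mask_path)
    img, data = _load(bold_path)
    if data.ndim != 4:
        raise AlignmentError(f"BOLD {bold_path} is not 4-D (shape {data.shape})")
    if data.shape[:3] != vs.volume_shape:
        raise AlignmentError(
            f"grid mismatch: BOLD {data.shape[:3]} vs mask {vs.volume_shape}"
        )
    if not np.allclose(img.affine, vs.affine, atol=1e-4):
        raise AlignmentError("BOLD and mask affines differ")
    gi = vs.grid_indices
    series = data[gi[:, 0], gi[:, 1], gi[:, 2], :].T.astype(float)
    sid = os.path.basename(os.fspath(bold_path)).split(".")[0]
    return TimeSeriesMatrix(series, vs, subject_id=sid), vs


def read_scalar_map(map_path, voxel_set: VoxelSet) -> np.ndarray:
    """Sample a 3D scalar volume at the voxel set's grid positions."""
    img, data = _load(map_path)
    if data.ndim != 3:
        raise AlignmentError(f"map {map_path} is not 3-D")
    if data.shape != voxel_set.volume_shape:
        raise AlignmentError(
            f"grid mismatch: map {data.shape} vs voxel set {voxel_set.volume_shape}"
        )
    gi = voxel_set.grid_indices
    return data[gi[:, 0], gi[:, 1], gi[:, 2]].astype(float)


def read_atlas_labels(atlas_path, voxel_set: VoxelSet) -> np.ndarray:
    """Integer network labels of a labeled volume over the voxel set."""
    labels = read_scalar_map(atlas_path, voxel_set)
    out = labels.astype(np.int64)
    if not np.allclose(labels, out):
        raise AlignmentError(f"atlas {atlas_path} has non-integer labels")
    return out


def read_term_maps(directory, voxel_set: VoxelSet,
                   prefix: str = "term_") -> Dict[str, np.ndarray]:
    """Read every ``term_<name>.nii[.gz]`` map in a directory."""
    out: Dict[str, np.ndarray] = {}
    for fname in sorted(os.listdir(os.fspath(directory))):
        if not fname.startswith(prefix):
            continue
        if not (fname.endswith(".nii") or fname.endswith(".nii.gz")):
            continue
        term = fname[len(prefix):].split(".nii")[0]
        out[term] = read_scalar_map(os.path.join(os.fspath(directory), fname),
                                    voxel_set)
    if not out:
        raise AlignmentError(f"no {prefix}*.nii maps found in {directory}")
    return out


def write_seed_map(path, values: np.ndarray, voxel_set: VoxelSet) -> str:
    """Write per-voxel values back into the voxel set's volume as NIfTI."""
    if voxel_set.volume_shape is None or voxel_set.affine is None:
        raise AlignmentError("voxel set lacks volume shape/affine provenance")
    values = np.asarray(values, dtype=np.float32).ravel()
    if values.size != len(voxel_set):
        raise AlignmentError("value count does not match voxel set size")
    vol = np.zeros(voxel_set.volume_shape, dtype=np.float32)
    gi = voxel_set.grid_indices
    vol[gi[:, 0], gi[:, 1], gi[:, 2]] = values
    nib.save(nib.Nifti1Image(vol, voxel_set.affine), os.fspath(path))
    return os.fspath(path)


def save_connectivity(path, conn: ConnectivityMatrix) -> str:
    """Save an FC matrix as compressed npz plus a text sidecar of provenance."""
    path = os.fspath(path)
    np.savez_compressed(
        path,
        values=conn.values,
        seed_ids=conn.seed_set.ids,
        target_ids=conn.target_set.ids,
        seed_grid=conn.seed_set.grid_indices,
        target_grid=conn.target_set.grid_indices,
    )
    sidecar = path + (".txt" if path.endswith(".npz") else ".npz.txt")
    with open(sidecar, "w") as fh:
        fh.write(f"scale={conn.scale}\n")
        fh.write(f"sparsity={conn.sparsity}\n")
        fh.write(f"top_fraction={conn.top_fraction}\n")
        fh.write(f"n_seed={conn.n_seed}\nn_target={conn.n_target}\n")
        fh.write("voxel_order=ascending-linear-grid-index-x-fastest\n")
    return path if path.endswith(".npz") else path + ".npz"


def load_connectivity(path) -> dict:
    """Load the arrays written by :func:`save_connectivity`."""
    with np.load(os.fspath(path)) as npz:
        return {k: npz[k] for k in npz.files}
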