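"""Network and behavioral relevance of connectivity gradients.

Three analyses link a seed region's gradients to external references:

* winner-take-all parcellation — each seed voxel is assigned to the
  canonical network whose mean target-voxel time course it correlates with
  most strongly, yielding a functional atlas of the seed region;
* gradient-by-network summaries — median/quartile gradient value per
  functional subdivision, sorted by median;
* decile decoding — the gradient map is split into ten percentile bins,
  binarized into masks, and each behavioral term map is averaged within
  every mask, tracing how term loading changes along the gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .containers import TimeSeriesMatrix
from .exceptions import (
    AlignmentError,
    ConfigurationError,
    DegenerateDataError,
    DegenerateVoxelWarning,
    EmptyNetworkWarning,
    TieBreakWarning,
)

__all__ = [
    "NetworkAtlas",
    "SeedParcellation",
    "DecodingTable",
    "winner_take_all",
    "gradient_by_network",
    "decile_decode",
]

UNASSIGNED = 0  # parcellation label for zero-variance (unassignable) voxels


@dataclass(eq=False)
class NetworkAtlas:
    """Target-voxel network labels (1-based, contiguous ids) with names."""

    labels: np.ndarray
    network_names: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        ids = np.unique(self.labels)
        if ids.size == 0 or ids.min() < 1:
            raise ConfigurationError("atlas labels must be positive integers")
        if not self.network_names:
            self.network_names = {int(i): f"network_{int(i)}" for i in ids}

    @property
    def n_networks(self) -> int:
        return int(self.labels.max())


@dataclass(eq=False)
class SeedParcellation:
    """Per-seed-voxel winning network id (0 = unassignable) and winning r."""

    assignment: np.ndarray
    winning_r: np.ndarray
    network_names: Dict[int, str] = field(default_factory=dict)

    @property
    def assigned(self) -> np.ndarray:
        return self.assignment != UNASSIGNED


@dataclass(eq=False)
class DecodingTable:
    """Ten-percentile-bin decoding: bins x terms table plus the bin masks."""

    table: pd.DataFrame
    bin_masks: List[np.ndarray]


def winner_take_all(seed_series: TimeSeriesMatrix,
                    target_series: TimeSeriesMatrix,
                    atlas: NetworkAtlas) -> SeedParcellation:
    """Assign each seed voxel to its best-correlated functional network.

    The per-network reference is the unweighted mean time course of the
    target voxels carrying that label. Ties go to the lowest network id
    (with a warning); zero-variance seed voxels are flagged unassigned.
    Networks with no member voxels are skipped with a warning.
    """
    if seed_series.n_timepoints != target_series.n_timepoints:
        raise AlignmentError("seed and target series have different timepoints")
    if atlas.labels.size != target_series.n_voxels:
        raise AlignmentError(
            f"atlas covers {atlas.labels.size} voxels but target series has "
            f"{target_series.n_voxels}"
        )

    net_ids = []
    averages = []
    for net in range(1, atlas.n_networks + 1):
        members = atlas.labels == net
        if not members.any():
            warnings.warn(
                f"network {net} ({atlas.network_names.get(net, '?')}) has no "
                "target voxels; skipped",
                EmptyNetworkWarning,
            )
            continue
        net_ids.append(net)
        averages.append(target_series.values[:, members].mean(axis=1))
    if not net_ids:
        raise DegenerateDataError("no non-empty networks in atlas")
    A = np.column_stack(averages)

    def _unit(values):
        c = values - values.mean(axis=0)
        norm = np.linalg.norm(c, axis=0)
        flat = norm == 0
        norm = np.where(flat, 1.0, norm)
        u = c / norm
        u[:, flat] = 0.0
        return u, flat

    seed_u, seed_flat = _unit(seed_series.values)
    avg_u, avg_flat = _unit(A)
    R = seed_u.T @ avg_u  # n_seed x n_networks_present

    best = np.argmax(R, axis=1)
    winning = R[np.arange(R.shape[0]), best]
    n_tied = int(np.sum(np.sum(R == winning[:, None], axis=1) > 1))
    if n_tied:
        warnings.warn(
            f"{n_tied} voxel(s) had tied winning correlations; assigned to "
            "the lowest network id",
            TieBreakWarning,
        )
    assignment = np.asarray(net_ids, dtype=np.int64)[best]
    winning_r = winning.astype(float)
    if np.any(seed_flat):
        warnings.warn(
            f"{int(seed_flat.sum())} zero-variance seed voxel(s) left unassigned",
            DegenerateVoxelWarning,
        )
        assignment[seed_flat] = UNASSIGNED
        winning_r[seed_flat] = np.nan
    return SeedParcellation(assignment, winning_r, dict(atlas.network_names))


def gradient_by_network(gradient: np.ndarray,
                        parc: SeedParcellation) -> pd.DataFrame:
    """Per-network count/median/quartiles of gradient values, median-sorted.

    Unassigned voxels are excluded. Columns: network, name, n_voxels,
    median, q1, q3; rows ordered by ascending median.
    """
    gradient = np.asarray(gradient, dtype=float).ravel()
    if gradient.size != parc.assignment.size:
        raise AlignmentError("gradient map and parcellation sizes differ")
    rows = []
    for net in np.unique(parc.assignment):
        if net == UNASSIGNED:
            continue
        vals = gradient[parc.assignment == net]
        rows.append({
            "network": int(net),
            "name": parc.network_names.get(int(net), f"network_{int(net)}"),
            "n_voxels": int(vals.size),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        })
    table = pd.DataFrame(rows)
    return table.sort_values("median", kind="stable").reset_index(drop=True)


def _rank_bins(gradient: np.ndarray, n_bins: int) -> List[np.ndarray]:
    """Rank-based percentile bins, sizes as even as possible.

    Voxels are ordered by gradient value (ties by voxel index); the lowest
    bins absorb the remainder voxels so every bin is non-empty.
    """
    n = gradient.size
    order = np.argsort(gradient, kind="stable")
    base, rem = divmod(n, n_bins)
    masks, start = [], 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        masks.append(np.sort(order[start:start + size]))
        start += size
    return masks


def _value_bins(gradient: np.ndarray, n_bins: int) -> List[np.ndarray]:
    """Value-range percentile bins (can be emptied by heavy ties)."""
    edges = np.percentile(gradient, np.linspace(0, 100, n_bins + 1))
    masks = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if b < n_bins - 1:
            mask = (gradient >= lo) & (gradient < hi)
        else:
            mask = (gradient >= lo) & (gradient <= hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise DegenerateDataError(
                f"percentile bin {b * 100 // n_bins}-{(b + 1) * 100 // n_bins}% "
                "is empty (heavy ties); use rank binning"
            )
        masks.append(idx)
    return masks


def decile_decode(gradient: np.ndarray, term_maps: Dict[str, np.ndarray],
                  n_bins: int = 10, method: str = "rank") -> DecodingTable:
    """Bin a gradient map into percentile masks and average term maps in each.

    ``method="rank"`` (default) splits voxels by rank into equal-count bins;
    ``"value"`` uses value-range percentiles and errors on empty bins. Cell
    (bin, term) is the mean term z-statistic over the bin's voxels. Masks
    partition the seed voxels.
    """
    gradient = np.asarray(gradient, dtype=float).ravel()
    if n_bins < 2 or n_bins > gradient.size:
        raise ConfigurationError(
            f"n_bins must be in [2, {gradient.size}], got {n_bins}"
        )
    for term, zmap in term_maps.items():
        if np.asarray(zmap).size != gradient.size:
            raise AlignmentError(
                f"term map {term!r} length does not match the gradient map"
            )
    if method == "rank":
        masks = _rank_bins(gradient, n_bins)
    elif method == "value":
        masks = _value_bins(gradient, n_bins)
    else:
        raise ConfigurationError(f"unknown binning method {method!r}")

    labels = [f"{b * 100 // n_bins}-{(b + 1) * 100 // n_bins}%" for b in range(n_bins)]
    data = {
        term: [float(np.mean(np.asarray(zmap, dtype=float)[m])) for m in masks]
        for term, zmap in term_maps.items()
    }
    table = pd.DataFrame(data, index=pd.Index(labels, name="bin"))
    return DecodingTable(table=table, bin_masks=masks)
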