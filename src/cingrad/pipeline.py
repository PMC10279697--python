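"""End-to-end orchestration: configuration, staged execution, manifest.

``run_full_pipeline`` wires the stages together in a fixed order — read
masked series, confound handling, FC construction (concatenation or
per-subject averaging), row thresholding, cosine affinity, diffusion
embedding, then the relevance analyses (winner-take-all parcellation,
gradient-by-network table, decile decoding) and the spatial statistics
(gradient-distance and gradient-GMV correlations with permutation tests).
Every output file is listed in a JSON manifest with a SHA-256 checksum, so
a re-run with the same configuration and seed can be verified byte-for-byte
(NIfTI outputs are written uncompressed for this reason).

``analyze_dataset`` runs the same analysis stages on an in-memory
:class:`~cingrad.synthetic.SyntheticDataset`, which is how the examples and
most tests exercise the pipeline without touching disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__ as _version
from .connectome import (
    compute_fc,
    cosine_affinity,
    extract_compcor_components,
    regress_confounds,
    standardize_and_concatenate,
    threshold_rows,
)
from .containers import ConnectivityMatrix, GradientResult, TimeSeriesMatrix, VoxelSet
from .exceptions import ConfigurationError, PipelineStageError
from .gradients import diffusion_embedding
from .io import (
    read_atlas_labels,
    read_masked_series,
    read_scalar_map,
    read_term_maps,
    write_seed_map,
)
from .relevance import NetworkAtlas, decile_decode, gradient_by_network, winner_take_all
from .spatialstats import ScalarSeedMap, euclidean_distance_map, permutation_test

logger = logging.getLogger("cingrad")

__all__ = ["RunConfig", "RunManifest", "run_full_pipeline", "analyze_dataset",
           "load_config", "gradients_from_series"]

_CONFOUND_MODES = ("standard", "gsr", "compcor")
_AGGREGATIONS = ("concatenate", "average")


@dataclass
class RunConfig:
    """Paths and analysis parameters of one reproducible pipeline run."""

    bold_paths: List[str] = field(default_factory=list)
    seed_mask: str = ""
    target_mask: str = ""
    atlas: str = ""
    term_map_dir: str = ""
    gmv_map: str = ""
    noise_mask: str = ""              # CompCor noise-ROI mask
    output_dir: str = "cingrad_out"

    threshold_fraction: float = 0.1
    alpha: float = 0.5
    n_components: int = 10
    diffusion_time: float = 0.0
    n_perm: int = 5000
    decode_bins: int = 10
    include_seed_in_target: bool = False
    confound_mode: str = "standard"
    fc_aggregation: str = "concatenate"
    compcor_components: int = 5
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ConfigurationError(
                f"threshold_fraction must be in (0, 1], got {self.threshold_fraction}")
        if not 0 <= self.alpha <= 1:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if self.diffusion_time < 0:
            raise ConfigurationError("diffusion_time must be nonnegative")
        if self.n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")
        if self.decode_bins < 2:
            raise ConfigurationError("decode_bins must be >= 2")
        if self.confound_mode not in _CONFOUND_MODES:
            raise ConfigurationError(
                f"confound_mode must be one of {_CONFOUND_MODES}")
        if self.fc_aggregation not in _AGGREGATIONS:
            raise ConfigurationError(
                f"fc_aggregation must be one of {_AGGREGATIONS}")
        if self.confound_mode == "compcor" and check_paths and not self.noise_mask:
            raise ConfigurationError("compcor mode requires noise_mask")
        if check_paths:
            for p in [*self.bold_paths, self.seed_mask, self.target_mask]:
                if not os.path.exists(p):
                    raise ConfigurationError(f"path does not exist: {p}")
            for p in (self.atlas, self.term_map_dir, self.gmv_map, self.noise_mask):
                if p and not os.path.exists(p):
                    raise ConfigurationError(f"path does not exist: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a flat-YAML run configuration, rejecting unknown keys."""
    with open(os.fspath(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


@dataclass
class RunManifest:
    """Snapshot of a pipeline run: config, version, outputs, checksums."""

    config: dict
    version: str
    outputs: Dict[str, str] = field(default_factory=dict)
    checksums: Dict[str, str] = field(default_factory=dict)
    log_path: str = ""

    def save(self, path) -> str:
        with open(os.fspath(path), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return os.fspath(path)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _apply_confound_mode(seed_list, targ_list, noise_list, config: RunConfig):
    """Per-subject confound handling before FC construction."""
    if config.confound_mode == "standard":
        return seed_list, targ_list
    out_seed, out_targ = [], []
    for i, (s, t) in enumerate(zip(seed_list, targ_list)):
        if config.confound_mode == "gsr":
            both = np.hstack([s.values, t.values])
            conf = both.mean(axis=1, keepdims=True)
        else:  # compcor
            conf = extract_compcor_components(noise_list[i],
                                              config.compcor_components)
        out_seed.append(regress_confounds(s, conf))
        out_targ.append(regress_confounds(t, conf))
    return out_seed, out_targ


def _build_fc(seed_list, targ_list, config: RunConfig) -> ConnectivityMatrix:
    allow = config.include_seed_in_target
    if config.fc_aggregation == "concatenate":
        seed_cat = standardize_and_concatenate(seed_list)
        targ_cat = standardize_and_concatenate(targ_list)
        return compute_fc(seed_cat, targ_cat, apply_fisher=True, allow_overlap=allow)
    mats = []
    for s, t in zip(seed_list, targ_list):
        sz = standardize_and_concatenate([s])
        tz = standardize_and_concatenate([t])
        mats.append(compute_fc(sz, tz, apply_fisher=True, allow_overlap=allow).values)
    avg = np.mean(mats, axis=0)
    return ConnectivityMatrix(avg, seed_list[0].voxel_set,
                              targ_list[0].voxel_set, scale="fisher_z",
                              sparsity="dense")


def gradients_from_series(seed_list: List[TimeSeriesMatrix],
                          targ_list: List[TimeSeriesMatrix],
                          config: RunConfig,
                          noise_list: Optional[List[TimeSeriesMatrix]] = None,
                          ) -> Tuple[GradientResult, ConnectivityMatrix]:
    """Series -> confounds -> FC -> threshold -> affinity -> embedding."""
    if config.include_seed_in_target:
        merged = []
        for s, t in zip(seed_list, targ_list):
            both = np.hstack([s.values, t.values])
            ids = np.concatenate([s.voxel_set.ids, t.voxel_set.ids + 10**9])
            grid = np.vstack([s.voxel_set.grid_indices, t.voxel_set.grid_indices])
            world = np.vstack([s.voxel_set.world_coords_mm,
                               t.voxel_set.world_coords_mm])
            order = np.argsort(ids)
            vs = VoxelSet(ids[order], grid[order], world[order],
                          source_mask="seed+target")
            merged.append(TimeSeriesMatrix(both[:, order], vs,
                                           subject_id=s.subject_id))
        targ_list = merged
    seed_list, targ_list = _apply_confound_mode(seed_list, targ_list,
                                                noise_list or [], config)
    fc = _build_fc(seed_list, targ_list, config)
    sparse = threshold_rows(fc, config.threshold_fraction)
    affinity = cosine_affinity(sparse)
    grad = diffusion_embedding(
        affinity,
        n_components=min(config.n_components, len(fc.seed_set) - 2),
        alpha=config.alpha,
        diffusion_time=config.diffusion_time,
        seed=config.seed,
        voxel_set=fc.seed_set,
    )
    return grad, sparse


def analyze_dataset(dataset, config: Optional[RunConfig] = None) -> dict:
    """Run the full analysis on an in-memory synthetic dataset.

    Returns a dict with the gradient result, parcellation, network table,
    decoding table, and the distance / GMV permutation tests for the first
    three gradients.
    """
    config = config or RunConfig()
    config.validate(check_paths=False)
    seed_list = [s for s, _ in dataset.subject_series]
    targ_list = [t for _, t in dataset.subject_series]
    grad, _ = gradients_from_series(seed_list, targ_list, config,
                                    noise_list=dataset.noise_series)

    seed_cat = standardize_and_concatenate(seed_list)
    targ_cat = standardize_and_concatenate(targ_list)
    atlas = NetworkAtlas(dataset.network_labels, dict(dataset.network_names))
    parc = winner_take_all(seed_cat, targ_cat, atlas)
    net_table = gradient_by_network(grad.gradient_maps[:, 0], parc)
    decode = decile_decode(grad.gradient_maps[:, 0], dataset.term_maps,
                           n_bins=config.decode_bins)

    vs = dataset.seed_voxels
    distance_tests, gmv_tests = {}, {}
    gmv_map = ScalarSeedMap(dataset.gmv_map, vs, kind="gmv")
    for g in range(min(3, grad.n_components)):
        gmap = ScalarSeedMap(grad.gradient_maps[:, g], vs, kind="gradient")
        dmap = euclidean_distance_map(vs, gmap)
        distance_tests[f"gradient_{g + 1}"] = permutation_test(
            gmap, dmap, n_perm=config.n_perm, seed=config.seed + g)
        gmv_tests[f"gradient_{g + 1}"] = permutation_test(
            gmap, gmv_map, n_perm=config.n_perm, seed=config.seed + 100 + g)

    return {
        "gradients": grad,
        "parcellation": parc,
        "network_table": net_table,
        "decoding": decode,
        "distance_tests": distance_tests,
        "gmv_tests": gmv_tests,
    }


def run_full_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage from NIfTI inputs and write all outputs.

    Stage order is fixed; a failure aborts with the stage name. Returns the
    manifest (also written to ``<output_dir>/manifest.json``).
    """
    config.validate(check_paths=True)
    os.makedirs(config.output_dir, exist_ok=True)
    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run config: %s", config.to_dict())
    outputs: Dict[str, str] = {}

    try:
        @_stage("read")
        def _read():
            seed_list, targ_list, noise_list = [], [], []
            seed_vs = targ_vs = None
            for bp in config.bold_paths:
                s, seed_vs = read_masked_series(bp, config.seed_mask)
                t, targ_vs = read_masked_series(bp, config.target_mask)
                seed_list.append(s)
                targ_list.append(t)
                if config.noise_mask:
                    nser, _ = read_masked_series(bp, config.noise_mask)
                    noise_list.append(nser)
            return seed_list, targ_list, noise_list, seed_vs, targ_vs

        seed_list, targ_list, noise_list, seed_vs, targ_vs = _read()

        @_stage("gradients")
        def _grad():
            return gradients_from_series(seed_list, targ_list, config,
                                         noise_list=noise_list)

        grad, _sparse = _grad()

        @_stage("write-gradients")
        def _write_grad():
            for g in range(min(3, grad.n_components)):
                p = os.path.join(config.output_dir, f"gradient_{g + 1}.nii")
                outputs[f"gradient_{g + 1}"] = write_seed_map(
                    p, grad.gradient_maps[:, g], seed_vs)
            import pandas as pd
            tab = pd.DataFrame({
                "component": np.arange(1, grad.n_components + 1),
                "eigenvalue": grad.eigenvalues,
                "explained_variance_pct": grad.explained_variance_pct,
            })
            p = os.path.join(config.output_dir, "eigenvalues.tsv")
            tab.to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs["eigenvalues"] = p

        _write_grad()

        if config.atlas:
            @_stage("parcellation")
            def _parc():
                labels = read_atlas_labels(config.atlas, targ_vs)
                atlas = NetworkAtlas(labels)
                seed_cat = standardize_and_concatenate(seed_list)
                targ_cat = standardize_and_concatenate(targ_list)
                parc = winner_take_all(seed_cat, targ_cat, atlas)
                p = os.path.join(config.output_dir, "parcellation.nii")
                outputs["parcellation"] = write_seed_map(
                    p, parc.assignment.astype(float), seed_vs)
                table = gradient_by_network(grad.gradient_maps[:, 0], parc)
                p = os.path.join(config.output_dir, "network_table.tsv")
                table.to_csv(p, sep="\t", index=False, float_format="%.10g")
                outputs["network_table"] = p

            _parc()

        if config.term_map_dir:
            @_stage("decoding")
            def _decode():
                terms = read_term_maps(config.term_map_dir, seed_vs)
                decode = decile_decode(grad.gradient_maps[:, 0], terms,
                                       n_bins=config.decode_bins)
                p = os.path.join(config.output_dir, "decoding_table.tsv")
                decode.table.to_csv(p, sep="\t", float_format="%.10g")
                outputs["decoding_table"] = p

            _decode()

        @_stage("spatialstats")
        def _spatial():
            results = {}
            for g in range(min(3, grad.n_components)):
                gmap = ScalarSeedMap(grad.gradient_maps[:, g], seed_vs)
                dmap = euclidean_distance_map(seed_vs, gmap)
                results[f"gradient_{g + 1}"] = permutation_test(
                    gmap, dmap, n_perm=config.n_perm,
                    seed=config.seed + g).to_dict()
            p = os.path.join(config.output_dir, "distance_permutation.json")
            with open(p, "w") as fh:
                json.dump(results, fh, indent=2, sort_keys=True)
            outputs["distance_permutation"] = p

            if config.gmv_map:
                gmv = ScalarSeedMap(read_scalar_map(config.gmv_map, seed_vs),
                                    seed_vs, kind="gmv")
                results = {}
                for g in range(min(3, grad.n_components)):
                    gmap = ScalarSeedMap(grad.gradient_maps[:, g], seed_vs)
                    results[f"gradient_{g + 1}"] = permutation_test(
                        gmap, gmv, n_perm=config.n_perm,
                        seed=config.seed + 100 + g).to_dict()
                p = os.path.join(config.output_dir, "gmv_permutation.json")
                with open(p, "w") as fh:
                    json.dump(results, fh, indent=2, sort_keys=True)
                outputs["gmv_permutation"] = p

        _spatial()
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = RunManifest(
        config=config.to_dict(),
        version=_version,
        outputs=outputs,
        checksums={k: _sha256(p) for k, p in outputs.items()},
        log_path=log_path,
    )
    manifest.save(os.path.join(config.output_dir, "manifest.json"))
    return manifest
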