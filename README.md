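# cingrad

Functional connectivity **gradients** of a seed brain region — continuous
spatial axes along which a voxel's whole-brain connectivity profile changes
gradually — computed by diffusion-map embedding, together with the analyses
that give those gradients meaning: network parcellation, behavioral
decoding, intrinsic geometry, and gray matter volume, all with permutation
inference.

The package is written for connectomics researchers who want a tested,
reproducible implementation of the voxelwise gradient workflow (the kind
applied to regions such as the cingulate cortex) that runs end to end on
self-contained synthetic data with planted ground truth, and equally on
real preprocessed NIfTI inputs.

## Method

Let `X_s` (seed) and `X_t` (target, e.g. the cerebrum) be z-scored BOLD
time series concatenated across subjects. The pipeline computes:

1. **FC matrix** `Z = atanh(corr(X_s, X_t))` — voxelwise Pearson
   correlations, Fisher z-transformed (at full study scale this is the
   seed × cerebrum matrix, e.g. 1665 × 39780).
2. **Row sparsification** — per seed voxel, only the top 10% of
   connections are retained (20%/30% as validation variants).
3. **Affinity** `W_ij = max(cos(Z_i, Z_j), 0)` — clamped cosine similarity
   of the sparse connectivity profiles: positive, symmetric, unit diagonal.
4. **Diffusion embedding** — with degrees `d = W·1`, the α-normalized
   kernel `W_α = W / (d^α d^α^T)` (α = 0.5) is row-normalized to a Markov
   operator `P`; the nontrivial eigenvectors of `P`, ordered by eigenvalue,
   are the gradients, each explaining `100·λ_g / Σλ` percent of the
   connectivity variance.
5. **Relevance** — winner-take-all network parcellation of the seed and
   median gradient value per network; ten-percentile binning of each
   gradient with mean term z-statistics per bin; cross-voxel Pearson r
   against Euclidean distance from the gradient peak and against a GMV
   map, with p-values from 5000 voxel shuffles (reported as `< 1/n_perm`
   when never exceeded).

A synthetic generator plants known gradient structure (network mixture
weights varying smoothly along chosen spatial axes) so every stage can be
verified against ground truth.

## Worked example

```python
from cingrad import SyntheticConfig, compare_gradient_maps, make_synthetic_dataset
from cingrad.pipeline import RunConfig, gradients_from_series

ds = make_synthetic_dataset(SyntheticConfig(seed=7))
seeds = [s for s, _ in ds.subject_series]
targs = [t for _, t in ds.subject_series]
grad, _ = gradients_from_series(seeds, targs, RunConfig())
print(grad.explained_variance_pct[:3])
print(compare_gradient_maps(grad.gradient_maps[:, 0],
                            ds.true_gradient_maps[:, 0])[1])
```

prints

```
[12.51079512 12.03598372 11.59000363]
0.9560828936473037
```

— the principal gradient explains the largest share of connectivity
variance and recovers the planted spatial axis at |r| = 0.956 despite
noise at half the signal amplitude. The scripts in `examples/` walk
through each capability; e.g. `examples/05_validation_robustness.py`
re-runs the pipeline under different thresholds and confound modes:

```
top 20% threshold            |r| = 0.972
top 30% threshold            |r| = 0.949
global signal regression     |r| = 0.999
CompCor (5 components)       |r| = 1.000
averaged subject FC          |r| = 1.000
seed included in target      |r| = 0.956
```

A thin CLI mirrors the library (`cingrad simulate`, `cingrad run-all
--config run.yaml`, `cingrad spatialtest ...`); the full pipeline writes
gradient NIfTIs, eigenvalue and decoding tables, permutation JSONs, and a
checksummed manifest for byte-level reproducibility.

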