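# Methods

## The model

A connectivity gradient is an eigenvector of a diffusion operator built
from the similarity of voxelwise connectivity profiles. The pipeline
assumes its inputs are *preprocessed* BOLD series (nuisance-regressed,
filtered, normalized upstream); everything from standardization onward is
in scope.

Given per-subject seed and target series, the default ("concatenate")
route z-scores each voxel within subject using the population (ddof = 0)
standard deviation and stacks subjects along time. With per-subject
z-scoring, the concatenated columns have exactly zero mean and unit
population variance, which is the invariant the containers enforce; the
sample-variance convention would leave the pooled sd at ≈ 0.9978 for
10 × 200 timepoints. The alternative "average" route correlates within
subject, Fisher-transforms, and averages the z-matrices across subjects.

Fisher transformation clips |r| at 1 − 1e-7 before `atanh`: when the
target set includes the seed (a validation mode), the diagonal pairs are
self-correlations and would otherwise map to infinity and poison the
affinity.

Row thresholding keeps the `k = ceil(fraction × n_target)` largest
entries per row **by signed value** — "top" connections in the convention
of the gradient literature, not by magnitude (a config switch is not
needed; the signed rule is the one implemented, and ties at the cutoff
resolve deterministically by value descending, then column index
ascending). `ceil` guarantees at least one retained connection for any
positive fraction. Zero-variance voxels are kept as zero rows rather than
dropped, preserving the canonical voxel ordering that every matrix and
map shares (ascending linear grid index, x fastest).

The affinity is the cosine similarity of sparse rows with negatives
clamped to zero (`clamped_cosine`), honoring the requirement of a
positive symmetric kernel; after top-10% sparsification negative cosines
are rare. A `normalized_angle` kernel (1 − arccos(cos)/π) is available as
an option.

## Diffusion embedding

With degrees `d = W·1`, the anisotropic kernel is
`W_α = W / (d^α d^αᵀ)` with α = 0.5 (the convention for connectivity
data: balances manifold geometry against sampling density), row-normalized
to a transition operator `P`. Eigenpairs are computed through the
symmetric conjugate `S = D^{-1/2} W_α D^{-1/2}` (dense `eigh` up to 5000
voxels; Lanczos with a seeded start vector above). The trivial constant
eigenvector (eigenvalue 1) is dropped; when the graph is disconnected the
top eigenvalue is degenerate, so the returned eigenspace basis is rotated
so that the constant vector is exactly the one removed — without this the
two-cluster case returns an arbitrary mixture instead of the ± block
indicator.

Gradient g is eigenvector g scaled by `λ_g^t`; the diffusion time `t`
defaults to 0 (no scaling), the common choice, and is exposed in config.
Eigenvector sign is arbitrary, so a deterministic convention is applied:
each gradient is flipped so its correlation with the seed coordinate axis
of largest absolute loading is positive.

Explained variance of component g is `100 · λ_g / Σ λ` over the
*positive part* of the full nontrivial spectrum. Two notes: the
denominator convention (full spectrum vs computed components) is a
genuine choice and the full spectrum is used; and transition operators
can have negative eigenvalues (the 8-node ring used as a spectral oracle
has them), so the raw spectrum is stored on the result while negatives
are clipped to zero for the variance shares.

## Relevance analyses

*Winner-take-all*: each seed voxel is correlated with the unweighted mean
time course of every network's target voxels and assigned to the argmax;
ties go to the lowest network id, zero-variance voxels are flagged
unassigned (excluded from summaries, retained in maps), and empty
networks are skipped with a warning.

*Decile decoding*: bins are computed by rank (equal voxel counts, lower
bins absorbing remainders), which guarantees ten non-empty masks under
ties; value-range percentile binning is available and errors on an empty
bin. Cell (bin, term) is the mean term z-statistic over the bin's voxels.

*Geometry and morphometry*: Euclidean distance in mm from the gradient's
peak voxel (argmax; ties to the lowest voxel index), correlated across
voxels with the gradient; similarly for the GMV map, which is consumed as
a ready scalar map (VBM itself is upstream).

## Permutation inference

The null shuffles the first map's values across voxels with a seeded
generator; exceedances are counted as `|r_perm| ≥ |r_obs|` by default.
The one-sided signed rule ("greater than the observed r") is exposed as
`greater_signed`, but it cannot be the intended default: applied to a
strongly negative observed correlation it yields p ≈ 1, which is
inconsistent with reporting such correlations as significant, so the
magnitude reading is the self-consistent one. `p = n_exceeding / n_perm`;
zero exceedances are reported as below resolution, "< 1/n_perm"
(< 0.0002 at the 5000-permutation default). For n ≤ 9 voxels an
exhaustive mode enumerates all n! permutations. Naive shuffles are
deliberate — autocorrelation-preserving nulls (spin tests, variogram
surrogates) are out of scope.

## Synthetic data: what it emulates and what it does not

The generator emulates z-scored, nuisance-cleaned voxel series whose
seed-to-target connectivity varies smoothly along planted spatial axes.
Defaults: 300 seed voxels on a 12 × 5 × 5 box (elongated along x so
distance analyses have nontrivial structure), 2000 target voxels, 7
networks, 10 subjects × 200 timepoints, noise sd 0.5 relative to
unit-variance latents, axes = the grid axes, plus a 50-voxel pure-noise
block serving as the CompCor noise region.

Per subject, network latents are white-noise time courses made exactly
zero-mean and orthonormal (QR), so in the zero-noise limit a seed voxel's
correlation with a latent is proportional to its mixture weight — this is
what lets the winner-take-all parcellation equal the generator's
dominant-network map voxel for voxel. Target voxels carry their network's
latent plus noise; seed voxels carry a convex latent mixture whose
weights follow logistic band ramps (slope 4 per min-max-normalized axis
length; for two networks a single ramp with midpoint at the axis median)
along planted axis 1, multiplicatively modulated (±30%, ±15%) along axes
2 and 3 for alternating networks. The slope is expressed per normalized
axis so transition width scales with the region; band boundaries are
nudged by 1e-3 so no voxel sits exactly on one (an exact boundary would
tie two weights at machine epsilon and make the dominant network
ill-defined). Term maps are the mixture weights scaled to a z-like range
(× 8); GMV is an affine function of the last-axis projection
(0.6 + 0.08·proj + N(0, 0.05²), clipped at zero).

Not emulated: hemodynamic autocorrelation (irrelevant to
correlation-based downstream math and it would complicate the oracles),
head motion, scanner effects, surface geometry, or a global artifact —
so the confound-mode robustness results show that GSR/CompCor do no
*harm* on clean data, not that they remove real artifacts. Passing tests
demonstrate the pipeline's math and its robustness properties, not
empirical claims about real cohorts.

## Numerical choices and problem sizes

Dense eigendecomposition is exact to solver precision and checked against
an independent non-symmetric-solver oracle at 1e-10 (eigenvalues) and
1e-8 (maps). On the default synthetic conditions the nontrivial spectrum
is nearly flat beyond component 1 (variance shares 12.5/12.0/11.6% …), so
components 2+ span a near-degenerate eigenspace whose basis can rotate
between pipeline variants; robustness statements are therefore made about
the principal gradient (and, where order swaps on very small fixtures,
about the leading subspace). Real-data spectra decay much faster, which
is why per-component robustness is well-posed there.

Tests and the acceptance script run the full default conditions
(300 × 2000 voxels, 2000 concatenated timepoints, 5000 permutations,
200-replicate calibration at 1000 permutations); the whole suite
completes in seconds on one CPU, so no stage is approximated.

## Known limitations

- No Procrustes alignment of gradients across individuals; the pipeline
  is group-level by construction.
- The permutation null ignores spatial autocorrelation; with smooth real
  maps it is anticonservative.
- The explained-variance percentages of a flat synthetic spectrum are not
  comparable to real-data values, where the principal gradient dominates.
- BIDS ingestion, preprocessing, and VBM segmentation are out of scope;
  inputs must already be analysis-ready NIfTI volumes on a shared grid.
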