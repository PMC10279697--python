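"""Geometric-distance and gray-matter-volume relevance with permutation tests.

Correlates each gradient with (a) Euclidean distance from its own peak
voxel and (b) the gray-matter-volume map, assessing significance with
5000 voxel-shuffling permutations and the "< 1/n_perm" reporting floor.
"""

from cingrad import (
    ScalarSeedMap,
    SyntheticConfig,
    euclidean_distance_map,
    make_synthetic_dataset,
    permutation_test,
)
from cingrad.pipeline import RunConfig, gradients_from_series

ds = make_synthetic_dataset(SyntheticConfig(seed=7))
seeds = [s for s, _ in ds.subject_series]
targs = [t for _, t in ds.subject_series]
grad, _ = gradients_from_series(seeds, targs, RunConfig())

vs = ds.seed_voxels
gmv = ScalarSeedMap(ds.gmv_map, vs, kind="gmv")
for g in range(3):
    gmap = ScalarSeedMap(grad.gradient_maps[:, g], vs)
    dmap = euclidean_distance_map(vs, gmap)
    dist = permutation_test(gmap, dmap, n_perm=5000, seed=g)
    morpho = permutation_test(gmap, gmv, n_perm=5000, seed=100 + g)
    print(f"gradient {g + 1}: distance r = {dist.observed_r:+.3f} "
          f"(P_perm {dist.p_str}), GMV r = {morpho.observed_r:+.3f} "
          f"(P_perm {morpho.p_str})")
print("-> a strongly negative distance r means the gradient decays with"
      " spatial distance from its peak; the GMV r indexes whether the"
      " gradient follows regional morphometry (the generator ties GMV to"
      " the last planted axis, not to gradient 1).")
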