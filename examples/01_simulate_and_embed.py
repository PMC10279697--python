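"""Generate a synthetic dataset and compute its connectivity gradients.

Plants a smooth connectivity gradient along the x axis of a seed-voxel
block, builds the seed-to-target FC matrix, and checks that diffusion
embedding recovers the planted axis.
"""

import numpy as np

from cingrad import SyntheticConfig, compare_gradient_maps, make_synthetic_dataset
from cingrad.pipeline import RunConfig, gradients_from_series

ds = make_synthetic_dataset(SyntheticConfig(seed=7))
seeds = [s for s, _ in ds.subject_series]
targs = [t for _, t in ds.subject_series]

grad, sparse = gradients_from_series(seeds, targs, RunConfig())

print(f"seed voxels: {len(ds.seed_voxels)}, target voxels: {len(ds.target_voxels)}")
print(f"FC matrix thresholded to top {sparse.top_fraction:.0%} per row "
      f"({np.count_nonzero(sparse.values[0])} connections/voxel)")
print("explained variance (%) of gradients 1-5:",
      np.round(grad.explained_variance_pct[:5], 2))

_, abs_r = compare_gradient_maps(grad.gradient_maps[:, 0],
                                 ds.true_gradient_maps[:, 0])
print(f"|r| between gradient 1 and the planted axis: {abs_r:.3f}")
print("-> the principal gradient is the planted smooth axis of connectivity"
      " change, recovered from noisy multi-subject time series.")
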