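"""Winner-take-all network parcellation and its layout along gradient 1.

Each seed voxel is assigned to the canonical network whose mean time
course it correlates with best; the per-network medians show how the
networks are ordered along the principal gradient.
"""

from cingrad import (
    NetworkAtlas,
    SyntheticConfig,
    gradient_by_network,
    make_synthetic_dataset,
    standardize_and_concatenate,
    winner_take_all,
)
from cingrad.pipeline import RunConfig, gradients_from_series

ds = make_synthetic_dataset(SyntheticConfig(seed=7))
seeds = [s for s, _ in ds.subject_series]
targs = [t for _, t in ds.subject_series]

grad, _ = gradients_from_series(seeds, targs, RunConfig())
seed_cat = standardize_and_concatenate(seeds)
targ_cat = standardize_and_concatenate(targs)
atlas = NetworkAtlas(ds.network_labels, dict(ds.network_names))
parc = winner_take_all(seed_cat, targ_cat, atlas)

table = gradient_by_network(grad.gradient_maps[:, 0], parc)
print(table.to_string(index=False))
print("-> networks cluster at distinct positions along gradient 1 rather"
      " than being randomly interleaved; the median column orders them"
      " along the planted axis.")
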