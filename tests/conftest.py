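import numpy as np
import pytest

from cingrad import SyntheticConfig, make_synthetic_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard study-condition dataset: 300 seed / 2000 target voxels,
    7 networks, 10 subjects x 200 timepoints, noise_sd=0.5, seed=7."""
    return make_synthetic_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Zero-noise dataset used by the exactness oracles."""
    return make_synthetic_dataset(
        SyntheticConfig(seed=3, noise_sd=0.0, n_subjects=2))


@pytest.fixture(scope="session")
def series_lists(default_dataset):
    seeds = [s for s, _ in default_dataset.subject_series]
    targs = [t for _, t in default_dataset.subject_series]
    return seeds, targs


def random_affinity(rng, n):
    """A valid random affinity matrix: symmetric, [0, 1], unit diagonal."""
    X = rng.random((n, n))
    A = (X + X.T) / 2
    np.fill_diagonal(A, 1.0)
    return A
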