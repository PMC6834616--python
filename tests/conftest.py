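import numpy as np
import pytest

from wonparafac import SyntheticSpec, make_planted_cube
from wonparafac.cube import DataCube


@pytest.fixture(scope="session")
def small_planted():
    """Noiseless planted rank-3 cube (30 x 20 x 5) with its ground truth."""
    spec = SyntheticSpec(g=30, c=20, d=5, k_true=3, noise_sd=0.0, seed=0)
    return make_planted_cube(spec)


@pytest.fixture(scope="session")
def noisy_planted():
    """Planted rank-4 cube with mild additive noise."""
    spec = SyntheticSpec(g=40, c=30, d=5, k_true=4, noise_sd=0.05, seed=1)
    return make_planted_cube(spec)


@pytest.fixture
def random_cube():
    """Unstructured random non-negative cube."""
    rng = np.random.default_rng(7)
    vals = rng.uniform(0.0, 1.0, size=(8, 6, 3))
    return DataCube(values=vals,
                    gene_ids=[f"g{i}" for i in range(8)],
                    sample_ids=[f"s{i}" for i in range(6)],
                    layer_names=["A", "B", "C"])
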