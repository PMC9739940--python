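import numpy as np
import pytest

from mixseedling.cloud import LabeledCloud
from mixseedling.synth import SeedlingSpec, generate_seedling


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labeled_cloud(rng):
    """Small random cloud with semantic/instance labels and a noise mask."""
    n = 64
    return LabeledCloud(
        points=rng.standard_normal((n, 3)),
        semantic=rng.integers(0, 2, n),
        instance=rng.integers(0, 3, n),
        noise_mask=rng.random(n) < 0.2,
    )


@pytest.fixture(scope="session")
def two_leaf_seedling():
    return generate_seedling(SeedlingSpec(n_leaves=2, seed=7))


@pytest.fixture(scope="session")
def one_leaf_seedling():
    return generate_seedling(SeedlingSpec(n_leaves=1, seed=3))
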