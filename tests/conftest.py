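import numpy as np
import pytest

from cytohgnn import (
    ClusterSpec,
    CompoundScalingBackbone,
    ToyImageSpec,
    gen_feature_clusters,
    make_cell_image_arrays,
)


@pytest.fixture(scope="session")
def separable_table():
    """Well-separated 5-class Gaussian clusters (8 sigma, 100 per class)."""
    return gen_feature_clusters(ClusterSpec(seed=0))


@pytest.fixture(scope="session")
def overlapping_table():
    """Locally coherent but overlapping clusters (5 sigma in 32 dims)."""
    return gen_feature_clusters(
        ClusterSpec(dim=32, class_mean_separation=5.0, seed=0)
    )


@pytest.fixture(scope="session")
def toy_images():
    """100 toy cell images (5 classes x 20), with labels and class names."""
    return make_cell_image_arrays(ToyImageSpec())


@pytest.fixture(scope="session")
def backbone():
    """One seeded backbone shared across tests (construction is cheap,
    forward passes are not)."""
    return CompoundScalingBackbone(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
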