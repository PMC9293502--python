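import numpy as np
import pytest

from renalbold import ClusteringConfig, IntensityImage, PhantomSpec, make_phantom


@pytest.fixture
def two_group_image():
    """Six pixels in two well-separated intensity groups."""
    return IntensityImage(np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]]))


@pytest.fixture
def random_image():
    rng = np.random.default_rng(42)
    return IntensityImage(rng.normal(50.0, 20.0, (12, 12)))


@pytest.fixture
def noiseless_phantom():
    return make_phantom(PhantomSpec(shape=(64, 64)))


@pytest.fixture
def config3():
    return ClusteringConfig(n_clusters=3)
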