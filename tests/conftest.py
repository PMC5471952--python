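import numpy as np
import pytest
from hypothesis import settings

from sanjay import HDPointCloud

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_cloud():
    """Two well-separated 6-point 1D-ish blobs (12 points, 2 channels)."""
    rng = np.random.default_rng(0)
    a = rng.normal([10.0, 10.0], 1.0, size=(6, 2))
    b = rng.normal([100.0, 100.0], 1.0, size=(6, 2))
    return HDPointCloud(np.vstack([a, b]), ("c1", "c2"))


@pytest.fixture
def three_blob_cloud():
    """Three separated Gaussian blobs in 4 channels, 60 cells, with labels."""
    rng = np.random.default_rng(1)
    means = np.array(
        [[100.0, 100, 100, 100], [500.0, 500, 500, 500], [900.0, 100, 900, 100]]
    )
    labels = np.repeat([0, 1, 2], 20)
    values = means[labels] + rng.normal(0, 10.0, size=(60, 4))
    return HDPointCloud(np.clip(values, 0, None), tuple("abcd")), labels
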