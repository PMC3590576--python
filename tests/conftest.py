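import numpy as np
import pytest

from turnklr import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Fully annotated synthetic dataset, small enough for fast unit tests."""
    return generate_dataset(SimConfig(n_chains=14, length_range=(30, 60), seed=7))


@pytest.fixture(scope="session")
def blobs_50x5():
    """Two well-separated 5-D Gaussian blobs, 25 points each, labels ±1."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(50, 5))
    X[:25] += 2.0
    y = np.array([1] * 25 + [-1] * 25)
    return X, y
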