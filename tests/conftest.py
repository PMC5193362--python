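import numpy as np
import pytest

from hogmri import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_volume(rng):
    return Volume3D(rng.normal(size=(12, 12, 12)))


@pytest.fixture
def two_class_matrix(rng):
    """A small matrix dataset with two informative features among noise."""
    n = 120
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 8))
    X[:, 2] += 2.0 * y
    X[:, 5] -= 1.5 * y
    return X, y
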