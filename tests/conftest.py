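import numpy as np
import pytest

from rvassoc.data import GenotypeMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(20140513)


@pytest.fixture()
def small_dataset(rng):
    """A 60 x 4 dosage matrix with a real signal on the first column."""
    X = rng.integers(0, 3, size=(60, 4)).astype(float)
    y = 0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 2] + rng.normal(0, 1.0, 60)
    return GenotypeMatrix(X), y


@pytest.fixture()
def null_dataset(rng):
    """A 80 x 5 dosage matrix with a trait independent of the genotypes."""
    X = rng.integers(0, 3, size=(80, 5)).astype(float)
    y = rng.normal(0, 1.0, 80)
    return GenotypeMatrix(X), y
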