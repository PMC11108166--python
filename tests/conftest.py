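import numpy as np
import pytest

from rncv import Dataset, GeneratorSpec, generate_balanced_gaussian


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def small_ds():
    """A 30-point balanced Gaussian dataset (cheap for CV machinery tests)."""
    return generate_balanced_gaussian(GeneratorSpec(n_points=30, n_features=5, seed=7))


@pytest.fixture
def separable_ds():
    """Two well-separated Gaussian blobs: any sensible classifier is perfect."""
    return generate_balanced_gaussian(
        GeneratorSpec(n_points=40, n_features=4, class2_mean=8.0, seed=3)
    )


@pytest.fixture
def imbalanced_ds(rng):
    """A 20:30 noise dataset (the smallest imbalance the oversampler must fix)."""
    X = rng.normal(size=(50, 4))
    y = np.concatenate([np.full(20, "a"), np.full(30, "b")])
    return Dataset(X, y)
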