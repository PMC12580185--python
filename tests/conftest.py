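import numpy as np
import pytest

from swarmfs import LabeledDataset, SyntheticSpec, make_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny d >> n dataset with a planted signal, cheap enough for every test."""
    spec = SyntheticSpec(
        n_samples=40,
        n_features=30,
        n_informative=4,
        n_redundant=4,
        n_classes=2,
        class_sep=2.5,
        seed=11,
    )
    return make_synthetic_dataset(spec)


@pytest.fixture
def toy_xy():
    """4-sample, 2-class matrix whose Fisher score is hand-computable."""
    X = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    y = np.array([0, 0, 1, 1])
    return X, y
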