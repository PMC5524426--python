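import numpy as np
import pytest

from hybridcast.models import generate_training_data, lorenz63_model


@pytest.fixture(scope="session")
def lorenz():
    return lorenz63_model()


@pytest.fixture(scope="session")
def lorenz_realization(lorenz):
    """One noisy Lorenz-63 training realization at the printed settings."""
    clean, noisy = generate_training_data(lorenz, 500, 4.0, seed=1234)
    return clean, noisy


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
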