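import warnings

import numpy as np
import pytest
from hypothesis import settings

from pepsl import planted_design

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
warnings.filterwarnings("ignore", category=FutureWarning)

HR97 = "FSGKRRKRKPR"


@pytest.fixture(scope="session")
def hr97():
    return HR97


@pytest.fixture(scope="session")
def planted_regression():
    """The shared planted-signal regression design: n=500 samples, 5 driver
    variables + 50 standard-normal noise variables, oracle R^2 = 0.7."""
    X, y, info = planted_design(n=500, n_informative=5, n_noise=50, seed=11)
    return X, y, info


@pytest.fixture(scope="session")
def planted_classification():
    X, y, info = planted_design(n=400, n_informative=5, n_noise=20, seed=7,
                                task="classification")
    return X, y, info


@pytest.fixture
def rng():
    return np.random.default_rng(0)
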