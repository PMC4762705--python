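import numpy as np
import pytest

from orthognathics import generate_phantom
from orthognathics.synthetic import ErrorModel, generate_cohort


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(seed=0)


@pytest.fixture(scope="session")
def frame(phantom):
    return phantom.frame


@pytest.fixture(scope="session")
def clean_cohort():
    """Ten synthetic cases with known execution errors and no landmark noise."""
    return generate_cohort(n_cases=10, seed=2024,
                           error_model=ErrorModel(landmark_noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
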