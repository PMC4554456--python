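import numpy as np
import pytest

from colitype import (
    NoiseModel,
    default_templates,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseModel(log10_measurement_sd=0.0)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def small_cohort(default_noise):
    """Default five-template cohort, 10 samples per enterocolitype."""
    return simulate_cohort(default_templates(), 10, default_noise, seed=11)


@pytest.fixture(scope="session")
def zero_noise_cohort(zero_noise):
    return simulate_cohort(default_templates(), 10, zero_noise, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
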