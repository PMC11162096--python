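import numpy as np
import pytest
from hypothesis import settings

from bqdesign import DesignConfig, TrialData

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def config():
    """Default continuous-endpoint design configuration."""
    return DesignConfig()


@pytest.fixture
def small_config():
    """Light configuration for fast unit tests."""
    return DesignConfig(n_draws=500, stage_sizes=(20, 10, 10))


def make_data(dose, tox, eff, n_arms=5, endpoint_type="continuous", bounds=None):
    data = TrialData(n_arms, endpoint_type, bounds)
    data.add_arrays(np.asarray(dose), np.asarray(tox), np.asarray(eff, dtype=float))
    return data


@pytest.fixture
def balanced_data(rng):
    """100 patients spread over 5 arms with a rising efficacy trend."""
    J, n_per = 5, 20
    dose = np.repeat(np.arange(1, J + 1), n_per)
    tox = rng.binomial(1, 0.1, size=dose.size)
    eff = 0.2 + 0.1 * (dose - 1) + rng.normal(0, 1, size=dose.size)
    return make_data(dose, tox, eff)
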