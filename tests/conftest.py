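import numpy as np
import pytest

from warpkit.stimgen import ContinuumSpec, synthesize_continuum
from warpkit.experiment import DesignSpec
from warpkit.observer import PopulationParams, simulate_experiment


@pytest.fixture(scope="session")
def spec():
    return ContinuumSpec()


@pytest.fixture(scope="session")
def vowels(spec):
    return synthesize_continuum(spec)


@pytest.fixture(scope="session")
def small_design():
    return DesignSpec(trials_per_token=5)


@pytest.fixture(scope="session")
def small_log(small_design):
    """Four simulated subjects on a reduced (5 trials/token) design."""
    return simulate_experiment(small_design, PopulationParams(), 4, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
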