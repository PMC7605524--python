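import numpy as np
import pytest

from twitchlab.model import simulate_twitch
from twitchlab.params import SimulationConfig, default_rate_constants
from twitchlab.perturb import emulate_mutation

#: 43.5% reduction of the weak-attachment rate (the D230N emulation)
F_SCALE_D230N = 0.565


@pytest.fixture(scope="session")
def params():
    return default_rate_constants()


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def wt_trace(params, config):
    return simulate_twitch(params, config)


@pytest.fixture(scope="session")
def mutant_params(params):
    return emulate_mutation(params, F_SCALE_D230N)


@pytest.fixture(scope="session")
def mutant_trace(mutant_params, config):
    return simulate_twitch(mutant_params, config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
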