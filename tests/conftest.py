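import numpy as np
import pytest

from pulsestab import (
    GrowthParams,
    ObservationScheme,
    PulseTrainRegime,
    SinglePulse,
    simulate_single_pulse,
)

# reference scenario used throughout: fast/slow logistic growers at K = 50
# disturbed by a pulse of 40 at t = 4, observed every 0.1 time units
FAST = GrowthParams(r=0.5, K=50.0)
SLOW = GrowthParams(r=0.1, K=50.0)
PULSE = SinglePulse(t_dist=4.0, magnitude=40.0)
REGIME = PulseTrainRegime(mu=0.0, sigma=10.0, lam=0.03)


@pytest.fixture
def fast_params():
    return FAST


@pytest.fixture
def slow_params():
    return SLOW


@pytest.fixture
def pulse():
    return PULSE


@pytest.fixture
def regime():
    return REGIME


@pytest.fixture
def obs():
    return ObservationScheme(t_max=50.0, dt_obs=0.1)


@pytest.fixture
def fast_single(obs):
    return simulate_single_pulse(FAST, PULSE, obs)


@pytest.fixture
def slow_single(obs):
    return simulate_single_pulse(SLOW, PULSE, obs)
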