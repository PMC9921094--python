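import numpy as np
import pytest

from mothnav import GainTable, Turbulence, scenario_a
from mothnav.environment import PlumeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table():
    return GainTable()


@pytest.fixture
def calm_scenario():
    """Scenario A with turbulence and jitter switched off: fully deterministic."""
    return scenario_a(
        turbulence=Turbulence(direction_sd=0.0, speed_sd=0.0,
                              correlation_time=2.0),
        plume=PlumeConfig(jitter_sd=0.0),
    )


@pytest.fixture
def no_odor_scenario():
    """Scenario A with the odor release switched off."""
    return scenario_a(plume=PlumeConfig(release_rate=0.0))
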