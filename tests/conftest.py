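import numpy as np
import pytest

from teamstate import SimulationConfig, make_study
from teamstate.evaluation import split_sessions
from teamstate.simulate import bayes_accuracy


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study6(default_config):
    """The default synthetic study: six dyadic sessions, flicker off."""
    return make_study(default_config)


@pytest.fixture(scope="session")
def split42(study6):
    """Fixed 4/2 session-level split of the default study."""
    return split_sessions(study6, seed=1)


@pytest.fixture(scope="session")
def bayes_ceiling(default_config):
    """Closed-form Bayes accuracy of the default emission model."""
    return bayes_accuracy(default_config.emissions, default_config.target_stationary)


@pytest.fixture(scope="session")
def flicker_study():
    return make_study(SimulationConfig(seed=2, flicker_rate=0.25))


@pytest.fixture(scope="session")
def tiny_study():
    """Two short sessions for cheap structural tests."""
    return make_study(SimulationConfig(seed=3, n_sessions=2, steps_per_session=40))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
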