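import numpy as np
import pytest

from funpace import Condition, GatingModel, ModulationModel
from funpace.channel import make_protocol, simulate_recording


@pytest.fixture
def model():
    return GatingModel()


@pytest.fixture
def inside_out():
    return GatingModel(v_half0=-100.0, mode="inside_out")


@pytest.fixture
def modulation():
    return ModulationModel()


@pytest.fixture
def control():
    return Condition()


@pytest.fixture(scope="session")
def noiseless_two_pulse():
    """Noiseless control two-pulse recording, shared across tests."""
    return simulate_recording(make_protocol("two_pulse_train"), GatingModel(),
                              ModulationModel(), Condition(), 0.0, None)


@pytest.fixture(scope="session")
def noiseless_fullact():
    return simulate_recording(make_protocol("fullact_tails"), GatingModel(),
                              ModulationModel(), Condition(), 0.0, None)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
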