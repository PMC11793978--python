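import numpy as np
import pytest

from tailopt.collocation import TimeGrid
from tailopt.dynamics import ChainDynamics
from tailopt.fixtures import zero_target
from tailopt.model import build_uniform_model, build_variable_model


@pytest.fixture(scope="session")
def model_1v():
    return build_uniform_model(1)


@pytest.fixture(scope="session")
def model_2v():
    return build_uniform_model(2)


@pytest.fixture(scope="session")
def model_3v_variable():
    return build_variable_model([0.3, 0.7, 0.5])


@pytest.fixture(scope="session")
def dyn_2v(model_2v):
    return ChainDynamics(model_2v)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def zero_traj():
    return zero_target()


@pytest.fixture(scope="session")
def tiny_grid_2():
    return TimeGrid(t0=0.0, tf=0.5, dt=0.25)
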