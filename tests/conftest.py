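import numpy as np
import pytest

from vbcssp.geometry import build_sensor_array
from vbcssp.harmonics import regular_harmonic_basis
from vbcssp.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def array45():
    """The benchmark helmet: 15 tri-axial sensor sites, 45 channels."""
    return build_sensor_array(15, 3, 0.1, seed=0)


@pytest.fixture(scope="session")
def array_small():
    """A cheap 5-site tri-axial array (15 channels) for fast VB tests."""
    return build_sensor_array(5, 3, 0.1, seed=0)


@pytest.fixture(scope="session")
def static_sim():
    """One static benchmark dataset: order 3, 10% gain error."""
    return simulate(SimConfig(L_true=3, sigma_C=0.1, seed=11))


@pytest.fixture(scope="session")
def basis3(static_sim):
    return regular_harmonic_basis(static_sim.array, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
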