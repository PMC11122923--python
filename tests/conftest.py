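import numpy as np
import pytest

from plasmasep.core import DeviceGeometry, FiltrationModel
from plasmasep.simulate import SimulationConfig


@pytest.fixture
def model():
    """A representative fitted model: k = 0.1 uL^2 mm^-4 min^-1, Ve = 2 uL."""
    return FiltrationModel(k=0.1, Ve=2.0)


@pytest.fixture
def truth():
    """Ground-truth model used across simulation round trips."""
    return FiltrationModel(k=0.05, Ve=4.0)


@pytest.fixture
def geom():
    """Default device: 80 um channel, 7 mm^2 feasibility floor."""
    return DeviceGeometry(h=80.0)


@pytest.fixture
def noise_free_cfg():
    return SimulationConfig(seed=0, noise_cv=0.0)


def ode_volume(m: FiltrationModel, A: float, tau: float) -> float:
    """Independent oracle: integrate dV/dt = k A^2 / (2 (V + Ve)) with a
    high-order adaptive stepper, never touching the closed form."""
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, y: m.k * A**2 / (2.0 * (y[0] + m.Ve)),
        (0.0, tau),
        [0.0],
        rtol=1e-11,
        atol=1e-13,
        dense_output=False,
    )
    assert sol.success
    return float(sol.y[0, -1])
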