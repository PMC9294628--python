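import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pyramidal import NeuronParameters
from pyramidal.model_core import rate_constants


@pytest.fixture(scope="session")
def params():
    return NeuronParameters()


def rk4_gate_trajectory(gate, x0, v, dt_fine, t_end):
    """Independent oracle: integrate tau dx/dt = x_inf - x (i.e.
    dx/dt = alpha (1-x) - beta x) with classic RK4 at a fine step."""
    r = rate_constants(v)
    a = getattr(r, f"alpha_{gate}")
    b = getattr(r, f"beta_{gate}")

    def f(x):
        return a * (1.0 - x) - b * x

    n = int(round(t_end / dt_fine))
    xs = np.empty(n + 1)
    xs[0] = x = x0
    for i in range(n):
        k1 = f(x)
        k2 = f(x + 0.5 * dt_fine * k1)
        k3 = f(x + 0.5 * dt_fine * k2)
        k4 = f(x + dt_fine * k3)
        x = x + dt_fine * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        xs[i + 1] = x
    return xs
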