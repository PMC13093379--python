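import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glymphkin.kinetics import InputFunction, KineticParams
from glymphkin.synthetic import AcquisitionSpec, gamma_variate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ACQ_TIMES = np.array([0.0, 30, 60, 90, 120, 180, 240, 300])


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def input_function():
    """Smooth gamma-variate tracer input sampled every minute."""
    t = np.arange(0.0, 301.0, 1.0)
    return InputFunction(t, gamma_variate(t), source="csf_roi")


@pytest.fixture(scope="session")
def example_params():
    return KineticParams(0.08, 0.04, 0.02, 0.01)


def rk_oracle(params, input_function, t_eval):
    """High-order adaptive Runge-Kutta reference solution of the same ODEs.

    Independent of the forward-Euler implementation: integrates with
    scipy's DOP853 at tight tolerances.
    """
    from scipy.integrate import solve_ivp

    k1, k2, k3, k4 = params.as_array()

    def rhs(t, y):
        cin = input_function(t)
        return [k1 * cin - (k2 + k3) * y[0] + k4 * y[1], k3 * y[0] - k4 * y[1]]

    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), [0.0, 0.0], t_eval=t_eval,
        method="DOP853", rtol=1e-10, atol=1e-13, max_step=1.0,
    )
    return sol.y[0], sol.y[1]
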