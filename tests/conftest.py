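import numpy as np
import pytest

import photokin as pk


@pytest.fixture(scope="session")
def cfg():
    """Default study-condition scenario with the master seed fixed."""
    return pk.ScenarioConfig(seed=0)


@pytest.fixture(scope="session")
def default_surface(cfg):
    """The canonical noisy transient-absorption fixture."""
    return pk.synth.make_transient_dataset(cfg)


@pytest.fixture(scope="session")
def default_global_fit(default_surface):
    """Shared 4-exponential + offset global fit of the canonical fixture."""
    return pk.fit_global_multiexp(default_surface, 4, with_offset=True, n_restarts=8, seed=0)


def ode_propagate(matrix: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Independent dense stiff-ODE oracle for population propagation."""
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, p: matrix @ p,
        (0.0, float(times[-1])),
        p0,
        t_eval=times,
        method="Radau",
        rtol=1e-12,
        atol=1e-14,
        jac=lambda t, p: matrix,
    )
    return sol.y.T
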