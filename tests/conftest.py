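import numpy as np
import pytest

from csclineage import (
    PopulationState,
    REPORTED_PHI,
    phi_to_rates,
    reported_rates,
)


@pytest.fixture(scope="session")
def reported_k():
    """Published rate-constant set at k1 = 1/day."""
    return reported_rates(1.0)


@pytest.fixture(scope="session")
def phi():
    return REPORTED_PHI


@pytest.fixture(scope="session")
def colon_base():
    """Base parameters, initial state and control trajectory for the
    120-day colon-cancer course used by the scenario comparisons."""
    from csclineage import initial_state, simulate

    k = phi_to_rates(REPORTED_PHI, 0.07)
    init = initial_state(1e5, 0.0018, k, "asymptotic")
    control = simulate(k, init, t_end=420.0)
    return k, init, control


def random_rates(rng, k1_range=(0.02, 1.5)):
    """Random but biologically ordered rate constants for property tests."""
    from csclineage import RateConstants

    k1 = rng.uniform(*k1_range)
    return RateConstants(
        k1=k1,
        k2=k1 * rng.uniform(0.1, 2.0),
        k3=k1 * rng.uniform(0.0, 0.5),
        k4=k1 * rng.uniform(1.0, 8.0),
        k5=k1 * rng.uniform(0.5, 6.0),
        k6=k1 * rng.uniform(0.001, 0.2),
        k7=k1 * rng.uniform(0.01, 0.5),
        k8=k1 * rng.uniform(0.2, 2.0),
    )


def random_state(rng, t=0.0):
    return PopulationState(
        t=t,
        csc=rng.uniform(1.0, 1e4),
        p=rng.uniform(1.0, 1e5),
        d=rng.uniform(1.0, 1e6),
    )


def rk_oracle(k, init, t, rtol=1e-12, atol=1e-9):
    """High-accuracy Runge-Kutta reference solution, independent of the
    package's closed form and of its piecewise engine."""
    from scipy.integrate import solve_ivp

    a = k.k1 - k.k3 - k.k6
    b = k.k4 - k.k5 - k.k7
    alpha = k.k2 + 2.0 * k.k3

    def rhs(_, y):
        return [a * y[0], alpha * y[0] + b * y[1], 2.0 * k.k5 * y[1] - k.k8 * y[2]]

    sol = solve_ivp(rhs, (init.t, t), [init.csc, init.p, init.d],
                    method="DOP853", rtol=rtol, atol=atol)
    assert sol.success
    return sol.y[:, -1]
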