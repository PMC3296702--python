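import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import repkin as rk

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig2_scenario():
    return rk.two_zone_scenario()


@pytest.fixture(scope="session")
def fig2_grid_mc():
    return rk.two_zone_grid()


@pytest.fixture(scope="session")
def fig2_solution(fig2_scenario):
    """Courant-1 solution of the two-zone system (exact transport), rows every 250 s."""
    grid = rk.Grid(length=1000.0, dx=0.25, dt=6.25, t_max=20000.0)
    return rk.solve(fig2_scenario, grid, stop_when_complete=False, store_stride=40)


@pytest.fixture(scope="session")
def fig2_solution_dense(fig2_scenario):
    """Same solution with rows every 50 s, for timing/SMARD integrals."""
    grid = rk.Grid(length=1000.0, dx=0.25, dt=6.25, t_max=20000.0)
    return rk.solve(fig2_scenario, grid, stop_when_complete=False, store_stride=8)


@pytest.fixture(scope="session")
def fig2_ensemble(fig2_scenario, fig2_grid_mc):
    """1000 stochastic replication cycles of the two-zone system (seed 0)."""
    t_out = np.linspace(0.0, 20000.0, 81)
    return rk.run_ensemble(fig2_scenario, fig2_grid_mc, 1000, seed=0, t_out=t_out, x_bin=10.0)


def binomial_se_floor(n: int) -> float:
    """Smallest meaningful binomial standard error for an n-cycle mean."""
    p = 0.5 / (n + 1)
    return float(np.sqrt(p * (1 - p) / n))
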