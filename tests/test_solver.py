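import math

import numpy as np
import pytest

import repkin as rk
from repkin.solver import SolverError, boundary_fork_density


def homogeneous(I0=1e-5, v=0.04, L=500.0, dx=0.5, dt=10.0, t_max=8000.0):
    sc = rk.Scenario(initiation=rk.InitiationProfile(background=I0),
                     velocity=rk.VelocityProfile(v_plus=v))
    return sc, rk.Grid(length=L, dx=dx, dt=dt, t_max=t_max)


class TestSolveBasics:
    def test_no_sources_stays_zero(self):
        sc, g = homogeneous(I0=0.0, t_max=2000.0)
        sol = rk.solve(sc, g, stop_when_complete=False)
        assert np.all(sol.f == 0) and np.all(sol.rho_plus == 0) and np.all(sol.rho_minus == 0)

    def test_cfl_violation_raises(self):
        sc, _ = homogeneous()
        with pytest.raises(SolverError, match="CFL"):
            rk.solve(sc, rk.Grid(length=100.0, dx=0.1, dt=10.0, t_max=1000.0))

    def test_homogeneous_closed_form(self):
        """Nucleation-and-growth kinetics: f = 1-exp(-I v t^2), rho = I t exp(-I v t^2)."""
        I0, v = 1e-5, 0.04
        sc, g = homogeneous(I0=I0, v=v)
        sol = rk.solve(sc, g, stop_when_complete=False)
        t = sol.t
        f_err = np.abs(sol.f.mean(axis=1) - (1 - np.exp(-I0 * v * t * t))).max()
        r_err = np.abs(sol.rho_plus.mean(axis=1) - I0 * t * np.exp(-I0 * v * t * t)).max()
        assert f_err < 1e-2
        assert r_err < 1e-4  # rho is ~100x smaller in magnitude

    def test_f_monotone_and_directional_split(self, fig2_solution):
        sol = fig2_solution
        assert np.all(np.diff(sol.f, axis=0) >= -1e-12)
        # f+ + f- equals f (up to the clamp of f at 1)
        gap = np.abs(np.minimum(sol.f_plus + sol.f_minus, 1.0) - sol.f)
        assert gap.max() < 2e-3

    def test_fields_bounded(self, fig2_solution):
        sol = fig2_solution
        assert sol.f.min() >= 0 and sol.f.max() <= 1
        assert sol.rho_plus.min() >= 0 and sol.rho_minus.min() >= 0


class TestConservation:
    def test_pbc_initiations_equal_coalescences(self, fig2_scenario):
        """On a circle every pair of created forks must annihilate."""
        sol = rk.solve(fig2_scenario, rk.two_zone_grid(), stop_when_complete=False)
        ed = rk.event_densities(sol)
        assert abs(ed.N_init - ed.N_coal) / ed.N_init < 2e-3

    def test_event_densities_normalized(self, fig2_solution):
        ed = rk.event_densities(fig2_solution)
        from scipy.integrate import trapezoid

        for D in (ed.D_init, ed.D_coal):
            total = trapezoid(D.sum(axis=1) * fig2_solution.grid.dx, fig2_solution.t)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_isolated_molecule_has_extra_initiation(self):
        """A linear molecule dominated by one origin: N_init ~ N_coal + 1."""
        sc = rk.Scenario(
            initiation=rk.InitiationProfile(zones=(rk.Zone(center=100.0, width=10.0, amplitude=2e-4),)),
            velocity=rk.VelocityProfile(0.04),
            boundary=rk.BoundaryCondition(mode="isolated"),
        )
        g = rk.Grid(length=200.0, dx=0.25, dt=6.25, t_max=6000.0)
        sol = rk.solve(sc, g, stop_when_complete=False)
        assert sol.N_init > sol.N_coal
        assert sol.N_init - sol.N_coal == pytest.approx(1.0, abs=0.15)


class TestGridConvergence:
    def test_first_order_refinement(self):
        I0, v = 1e-5, 0.04
        errs = []
        for dx, dt in [(0.5, 10.0), (0.25, 5.0)]:
            sc, g = homogeneous(I0=I0, v=v, dx=dx, dt=dt)
            sol = rk.solve(sc, g, stop_when_complete=False)
            errs.append(np.abs(sol.f.mean(axis=1) - (1 - np.exp(-I0 * v * sol.t**2))).max())
        assert errs[1] < 0.6 * errs[0]

    def test_n_init_stable_under_refinement(self, fig2_scenario):
        n = []
        for dx, dt in [(0.5, 10.0), (0.25, 5.0)]:
            g = rk.Grid(length=1000.0, dx=dx, dt=dt, t_max=20000.0)
            sol = rk.solve(fig2_scenario, g, stop_when_complete=False, store_stride=200)
            n.append(sol.N_init)
        assert abs(n[1] - n[0]) / n[0] < 0.01


class TestBoundaryForkDensity:
    def test_zero_rate_and_zero_time(self):
        assert boundary_fork_density(0.0, 0.04, 500.0) == 0.0
        assert boundary_fork_density(1e-3, 0.04, 0.0) == 0.0

    def test_peak_location_and_value(self):
        """Flank density peaks at t* = 1/sqrt(2 I v) with value I t* e^{-1/2}."""
        I_out, v = 1e-3, 0.04
        t_star = 1.0 / math.sqrt(2 * I_out * v)
        assert t_star == pytest.approx(111.80, abs=0.01)
        t = np.linspace(0, 500, 50001)
        rho = boundary_fork_density(I_out, v, t)
        assert t[np.argmax(rho)] == pytest.approx(t_star, abs=0.05)
        assert rho.max() == pytest.approx(I_out * t_star * math.exp(-0.5), rel=1e-6)


class TestStalling:
    def scenario(self, d, tau):
        return rk.Scenario(
            initiation=rk.InitiationProfile(background=5e-5),
            velocity=rk.VelocityProfile(0.04),
            defects=rk.DefectModel(spacing=d, repair_time=tau),
        )

    def test_infinite_spacing_reduces_to_defect_free(self):
        g = rk.Grid(length=200.0, dx=0.5, dt=12.5, t_max=3000.0)
        base = rk.solve(self.scenario(1e12, 1000.0).without_defects(), g, stop_when_complete=False)
        stalled = rk.solve_with_stalls(self.scenario(1e12, 1000.0), g, stop_when_complete=False)
        assert np.abs(stalled.f - base.f).max() < 1e-6
        assert np.abs(stalled.rho_plus - base.rho_plus).max() < 1e-6
        assert stalled.rho_stall_plus.max() < 1e-12

    def test_instant_repair_limit(self):
        """As tau -> 0 the stalled population vanishes and fields converge."""
        g = rk.Grid(length=200.0, dx=0.5, dt=12.5, t_max=3000.0)
        base = rk.solve(self.scenario(50.0, 1.0).without_defects(), g, stop_when_complete=False)
        gaps = []
        for tau in (100.0, 10.0, 1.0):
            s = rk.solve_with_stalls(self.scenario(50.0, tau), g, stop_when_complete=False)
            gaps.append(np.abs(s.f - base.f).max())
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 5e-3

    def test_stalling_delays_completion(self):
        g = rk.Grid(length=200.0, dx=0.5, dt=12.5, t_max=8000.0)
        from scipy.integrate import trapezoid

        def mean_end(sol):
            pe = rk.end_probability(sol).P_end
            return trapezoid(1 - pe, sol.t)

        t_free = mean_end(rk.solve(self.scenario(50.0, 500.0).without_defects(), g, stop_when_complete=False))
        t_stall = mean_end(rk.solve_with_stalls(self.scenario(50.0, 500.0), g, stop_when_complete=False))
        assert t_stall > t_free

    def test_requires_defect_model(self, fig2_scenario):
        with pytest.raises(SolverError):
            rk.solve_with_stalls(fig2_scenario, rk.two_zone_grid())
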