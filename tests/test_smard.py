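import numpy as np
import pytest
from scipy.integrate import trapezoid

import repkin as rk
from repkin import smard
from repkin.scenario import ScenarioError


@pytest.fixture(scope="module")
def fig2_molecules(fig2_scenario, fig2_grid_mc, fig2_solution_dense):
    return smard.sample_smard(fig2_scenario, fig2_grid_mc, n_keep=600, seed=5,
                              sol=fig2_solution_dense)


class TestLabeling:
    def setup_log(self):
        sc = rk.Scenario(initiation=rk.InitiationProfile(), velocity=rk.VelocityProfile(0.04))
        g = rk.Grid(length=100.0, dx=0.5, dt=10.0, t_max=5000.0)
        return rk.simulate_cycle(sc, g, seed=2, forced_initiations=[(30.0, 100.0)])

    def test_switch_after_completion_fully_red(self):
        log = self.setup_log()
        m = smard.label_cycle(log, t_switch=4000.0)
        assert m.label.all() and m.fork_marks == []

    def test_switch_before_start_fully_green(self):
        log = self.setup_log()
        m = smard.label_cycle(log, t_switch=50.0)
        assert not m.label.any() and m.fork_marks == []

    def test_mid_replication_red_interval_with_outward_forks(self):
        """A single origin gives one red interval and two outward fork marks."""
        log = self.setup_log()
        m = smard.label_cycle(log, t_switch=600.0)  # forks at 30 +- 0.04*500 = 10, 50
        marks = m.fork_marks
        assert len(marks) == 2
        (x1, d1), (x2, d2) = sorted(marks)
        assert d1 == -1 and d2 == +1  # moving away from the origin
        assert x1 == pytest.approx(10.0, abs=0.3)
        assert x2 == pytest.approx(50.0, abs=0.3)
        assert m.is_two_color

    def test_marks_match_true_fork_positions(self, fig2_scenario, fig2_grid_mc):
        """Label transitions recover the simulator's fork positions at the switch."""
        log = rk.simulate_cycle(fig2_scenario, fig2_grid_mc, seed=17)
        t_switch = 0.5 * (log.t_first_init + log.t_last_coal)
        m = smard.label_cycle(log, t_switch)
        truth = []
        for p in log.fork_trajectories:
            verts = p.vertices
            if verts[0, 0] <= t_switch:
                alive = verts[-1, 0] > t_switch or p.fate == "alive"
                if alive:
                    x0, t0 = verts[0, 1], verts[0, 0]
                    truth.append((x0 + p.direction * 0.04 * (t_switch - t0)) % 1000.0)
        got = sorted(x for x, _ in m.fork_marks)
        assert len(got) == len(truth)
        for g_, t_ in zip(got, sorted(truth)):
            assert g_ == pytest.approx(t_, abs=0.2)

    def test_negative_switch_rejected(self):
        log = self.setup_log()
        with pytest.raises(ScenarioError):
            smard.label_cycle(log, -1.0)


class TestSampling:
    def test_two_color_filter(self, fig2_molecules):
        for m in fig2_molecules.molecules:
            assert m.is_two_color

    def test_acceptance_fraction_matches_prediction(self, fig2_molecules, fig2_solution_dense):
        curves = rk.start_probability(fig2_solution_dense, region="whole")
        pred = trapezoid(curves.P_start - curves.P_end, curves.t) / fig2_molecules.t_window
        emp = fig2_molecules.acceptance_fraction
        n = fig2_molecules.n_attempted
        se = np.sqrt(pred * (1 - pred) / n)
        assert abs(emp - pred) < 3 * se

    def test_keep_all_retains_one_color(self, fig2_scenario, fig2_grid_mc, fig2_solution_dense):
        ms = smard.sample_smard(fig2_scenario, fig2_grid_mc, n_keep=60, seed=8,
                                keep="all_fully_labeled", sol=fig2_solution_dense)
        assert any(not m.is_two_color for m in ms.molecules)


class TestProfiles:
    def test_all_red_set(self):
        mols = [smard.Molecule(id=f"m{i}", x0=0.0, dx=0.5, label=np.ones(200, dtype=np.uint8))
                for i in range(5)]
        ms = smard.MoleculeSet(molecules=mols, x0=0.0, dx=0.5, length=100.0)
        prof = smard.profiles(ms, bin_content=5.0, bin_fork=50.0)
        assert np.all(prof.r == 1.0)
        assert np.all(prof.rho_bar_plus == 0) and np.all(prof.rho_bar_minus == 0)

    def test_empty_set_rejected(self):
        ms = smard.MoleculeSet(molecules=[], x0=0.0, dx=0.5, length=100.0)
        with pytest.raises(ScenarioError):
            smard.profiles(ms)

    def test_zone_signature_in_fork_densities(self, fig2_molecules):
        """Across an initiation zone right-moving density rises and left-moving falls."""
        prof = smard.profiles(fig2_molecules)
        i = np.searchsorted(prof.x_fork, 200.0)  # early zone center
        assert prof.rho_bar_plus[i + 1] > prof.rho_bar_plus[i - 1]
        assert prof.rho_bar_minus[i + 1] < prof.rho_bar_minus[i - 1]

    def test_content_peaks_at_zone_centers(self, fig2_molecules):
        prof = smard.profiles(fig2_molecules)
        r = prof.r
        # global maximum at the early zone; a local maximum at the late zone
        assert abs(prof.x_content[np.argmax(r)] - 200.0) < 30.0
        late = slice(np.searchsorted(prof.x_content, 700.0), np.searchsorted(prof.x_content, 900.0))
        assert abs(prof.x_content[late][np.argmax(r[late])] - 800.0) < 30.0

    def test_autocorrelation_positive_at_short_lag(self, fig2_molecules):
        prof = smard.profiles(fig2_molecules)
        noise = prof.autocorr[np.abs(prof.lags - 350.0) < 100.0].std()
        assert prof.autocorr[1] > 3 * noise


class TestPredictions:
    def test_homogeneous_profiles_flat(self):
        sc = rk.Scenario(initiation=rk.InitiationProfile(background=1e-4),
                         velocity=rk.VelocityProfile(0.04))
        g = rk.Grid(length=100.0, dx=0.25, dt=6.25, t_max=4000.0)
        sol = rk.solve(sc, g, stop_when_complete=False)
        curves = rk.start_probability(sol, region="whole")
        _, r = smard.predict_red_green(sol, curves)
        _, rp, rm = smard.predict_fork_density(sol, curves)
        assert r.std() < 0.02
        np.testing.assert_allclose(rp, rm, rtol=1e-9)
        assert rp.std() / rp.mean() < 0.02

    def test_content_integrand_nonnegative(self, fig2_solution_dense):
        """P_e is a pointwise lower envelope of f (a finished molecule has f=1)."""
        curves = rk.start_probability(fig2_solution_dense, region="whole")
        gap = fig2_solution_dense.f - curves.P_end[:, None]
        assert gap.min() > -5e-3

    def test_estimates_converge_to_prediction(self, fig2_scenario, fig2_grid_mc, fig2_solution_dense):
        """Sampled profiles approach the mean-field prediction as n grows."""
        curves = rk.start_probability(fig2_solution_dense, region="whole")
        _, r_pred = smard.predict_red_green(fig2_solution_dense, curves)
        rb = r_pred.reshape(200, 20).mean(axis=1)
        errs = []
        for n in (50, 500):
            ms = smard.sample_smard(fig2_scenario, fig2_grid_mc, n_keep=n, seed=40 + n,
                                    sol=fig2_solution_dense)
            prof = smard.profiles(ms)
            errs.append(np.abs(prof.r - rb).mean())
        assert errs[1] < errs[0]

    def test_degenerate_scenario_rejected(self):
        t = np.linspace(0, 100, 11)
        curves = rk.timing.TimingCurves(t=t, P_start=np.zeros(11), P_end=np.zeros(11))
        sol_like = None
        with pytest.raises(ScenarioError):
            smard._s_phase_weight(curves)
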