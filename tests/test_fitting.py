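import numpy as np
import pytest
from scipy.linalg import solve_triangular

import repkin as rk
from repkin import fitting as ft
from repkin.scenario import ScenarioError


def make_blocks(x, kind="content", cond="single", frag=(0.0, 300.0)):
    return [ft.Block(kind=kind, condition=cond, fragment=frag, sl=slice(0, len(x)), x=x)]


class TestCovarianceEstimation:
    def test_identical_replicates_zero_matrix(self):
        reps = np.tile(np.arange(5.0), (4, 1))
        C = ft.estimate_covariance(reps)
        assert np.all(C == 0)

    def test_independent_unit_variance(self):
        rng = np.random.default_rng(0)
        reps = rng.standard_normal((1000, 8))
        C = ft.estimate_covariance(reps)
        assert np.abs(np.diag(C) - 1).max() < 0.2
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.15

    def test_rank_deficiency_flagged(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            ft.estimate_covariance(rng.standard_normal((5, 10)))

    def test_smard_replicates_positively_correlated_nearby(self, fig2_scenario, fig2_grid_mc,
                                                           fig2_solution_dense):
        from repkin import smard

        reps = []
        for s in range(24):
            ms = smard.sample_smard(fig2_scenario, fig2_grid_mc, n_keep=30, seed=600 + s,
                                    sol=fig2_solution_dense, mc_dx=0.5)
            reps.append(smard.profiles(ms).r)
        C = ft.estimate_covariance(np.stack(reps))
        sd = np.sqrt(np.diag(C))
        corr1 = np.diagonal(C, offset=1) / (sd[:-1] * sd[1:])
        assert np.nanmean(corr1) > 0.3


class TestCovarianceParametrization:
    def test_diagonal_input_gives_zero_decay(self):
        x = np.arange(10) * 5.0
        C = np.diag(np.linspace(1.0, 2.0, 10))
        cm = ft.parametrize_covariance(C, make_blocks(x), shrinkage=1.0)
        assert cm.lambdas[0] == 0.0
        expected = np.convolve(np.diag(C), np.ones(3), "same") / np.convolve(np.ones(10), np.ones(3), "same")
        np.testing.assert_allclose(np.diag(cm.C_par), expected, rtol=1e-9)
        assert np.abs(cm.C_par - np.diag(np.diag(cm.C_par))).max() == 0.0

    def test_known_decay_length_recovered(self):
        rng = np.random.default_rng(3)
        x = np.arange(40) * 5.0
        R = np.exp(-np.abs(np.subtract.outer(x, x)) / 30.0)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(40))
        reps = rng.standard_normal((1000, 40)) @ L.T
        cm = ft.parametrize_covariance(ft.estimate_covariance(reps), make_blocks(x))
        assert cm.lambdas[0] == pytest.approx(30.0, rel=0.2)

    def test_output_is_positive_definite(self):
        rng = np.random.default_rng(4)
        x = np.arange(12) * 5.0
        reps = rng.standard_normal((6, 12))  # fewer replicates than dimensions
        with pytest.warns(UserWarning):
            C = ft.estimate_covariance(reps)
        cm = ft.parametrize_covariance(C, make_blocks(x))
        # a successful Cholesky factorization is the certificate
        np.testing.assert_allclose(cm.L_chol @ cm.L_chol.T, cm.C_par, atol=1e-10)


class TestDecorrelation:
    def test_identity_covariance_is_noop(self):
        cm = ft.CovarianceModel(C_emp=np.eye(4), C_par=np.eye(4), L_chol=np.eye(4))
        v = np.array([1.0, -2.0, 3.0, 0.5])
        np.testing.assert_array_equal(ft.decorrelate(cm, v), v)

    def test_whitened_replicates_have_identity_covariance(self):
        rng = np.random.default_rng(5)
        x = np.arange(20) * 5.0
        R = np.exp(-np.abs(np.subtract.outer(x, x)) / 25.0)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(20))
        reps = rng.standard_normal((1000, 20)) @ L.T
        cm = ft.parametrize_covariance(ft.estimate_covariance(reps), make_blocks(x))
        white = ft.decorrelate(cm, reps)
        Cw = ft.estimate_covariance(white)
        assert np.abs(np.diag(Cw) - 1).max() < 0.3
        assert np.abs(Cw - np.diag(np.diag(Cw))).max() < 0.25

    def test_triangular_solve_roundtrip(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((6, 6))
        C = A @ A.T + np.eye(6)
        Lc = np.linalg.cholesky(C)
        cm = ft.CovarianceModel(C_emp=C, C_par=C, L_chol=Lc)
        v = rng.standard_normal(6)
        np.testing.assert_allclose(Lc @ ft.decorrelate(cm, v), v, atol=1e-12)

    def test_dimension_mismatch(self):
        cm = ft.CovarianceModel(C_emp=np.eye(3), C_par=np.eye(3), L_chol=np.eye(3))
        with pytest.raises(ScenarioError):
            ft.decorrelate(cm, np.arange(4.0))


class TestScenarioFamilies:
    def test_zero_amplitude_background_only(self):
        fam = ft.TwoZoneFamily(length=600.0, fragments=[(0.0, 300.0), (300.0, 600.0)])
        theta = np.array([150.0, 60.0, -7.5, 450.0, 60.0, -7.5, -7.0, -6.0, -6.0, np.log10(0.04)])
        cond = ft.scenario_from_params(theta, fam)[0]
        x = np.linspace(0, 600, 61)
        I = cond.scenario.initiation(x, 0.0)
        assert np.all(np.abs(I - (1e-7 + I.min() - I.min())) < 2e-7 + I.max() * 0)
        assert I.max() < 1e-7 + 2 * 10 ** -7.5

    def test_fig7_zone_positions(self):
        """Zones near 250 kb and 1150 kb over a ~1.4 Mb region."""
        fam = ft.Fig7Family(length=1400.0,
                            fragments_normal=[(0.0, 350.0), (350.0, 700.0), (700.0, 1050.0), (1050.0, 1400.0)],
                            fragments_rearranged=[(700.0, 1050.0), (1050.0, 1335.0)],
                            deletion_start=1120.0)
        theta = np.array([250.0, 60.0, -5.0, 1150.0, 60.0, -5.0, -7.0, -6.0, -6.0,
                          np.log10(0.04), np.log10(0.03)])
        conds = ft.scenario_from_params(theta, fam)
        assert [c.name for c in conds] == ["normal", "rearranged"]
        x = np.linspace(0, 1400, 2801)
        I = conds[0].scenario.initiation(x, 0.0)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(I, prominence=I.max() / 10)
        centers = sorted(x[peaks])
        assert abs(centers[0] - 250.0) < 5 and abs(centers[-1] - 1150.0) < 5

    def test_deletion_shortens_domain_and_drops_zone(self):
        fam = ft.Fig7Family(length=1400.0,
                            fragments_normal=[(0.0, 700.0)],
                            fragments_rearranged=[(0.0, 700.0)],
                            deletion_start=1120.0, deletion_length=65.0)
        theta = np.array([250.0, 60.0, -5.0, 1150.0, 60.0, -5.0, -7.0, -6.0, -6.0,
                          np.log10(0.04), np.log10(0.04)])
        normal, rearranged = ft.scenario_from_params(theta, fam)
        assert rearranged.grid.length == pytest.approx(normal.grid.length - 65.0)
        assert len(rearranged.scenario.initiation.zones) == 1
        # the surviving zone keeps its coordinate (it lies below the deletion)
        assert rearranged.scenario.initiation.zones[0].center == 250.0

    def test_out_of_bounds_rejected(self):
        fam = ft.TwoZoneFamily(length=600.0, fragments=[(0.0, 600.0)])
        theta = np.array([150.0, 60.0, -5.0, 450.0, 60.0, -5.0, -7.0, -6.0, -6.0, 0.5])
        with pytest.raises(ScenarioError):
            fam.build(theta)


@pytest.fixture(scope="module")
def small_problem():
    """A compact synthetic fit problem with known truth (150 kb fragments)."""
    fam = ft.TwoZoneFamily(length=300.0, fragments=[(0.0, 150.0), (150.0, 300.0)],
                           dx=1.0, t_max_hint=15000.0)
    theta_star = np.array([80.0, 40.0, np.log10(3e-5), 220.0, 40.0, np.log10(1.5e-5),
                           -7.0, -6.0, -6.0, np.log10(0.04)])
    from repkin import smard

    cond = fam.build(theta_star)[0]
    sol = rk.solve(cond.scenario, cond.grid, complete_threshold=0.9999)
    sets = []
    for j, frag in enumerate(cond.fragments):
        sets.append(smard.sample_smard(cond.scenario, cond.grid, n_keep=40, seed=300 + j,
                                       fragment=frag, mc_dx=0.2, sol=sol))
    model = ft.SmardReplicationModel({"single": sets}, fam)
    return fam, theta_star, model


class TestGlobalFit:
    def test_noise_free_fixed_point(self, small_problem):
        """Fitting the model's own prediction from the truth stays at the truth."""
        fam, theta_star, model = small_problem
        problem = model.problem
        m_star, _ = ft.predict_vector(fam, theta_star, t_windows=problem.t_windows)
        clean = ft.FitProblem(y=m_star, blocks=problem.blocks, family=fam,
                              n_molecules=problem.n_molecules, t_windows=problem.t_windows)
        cfg = ft.FitConfig(n_sim=12, max_outer=1, mc_dx=0.25)
        report = ft.global_fit(clean, cfg, seed=1, start_params=theta_star)
        assert report.chi2 < 1e-4
        np.testing.assert_allclose(report.theta, theta_star, atol=1e-3)

    def test_initialization_reads_peaks(self, small_problem):
        fam, theta_star, model = small_problem
        theta0 = ft.initial_params_from_profiles(model.problem)
        assert abs(theta0[0] - theta_star[0]) < 40.0
        assert abs(theta0[3] - theta_star[3]) < 40.0

    def test_light_recovery_and_summary(self, small_problem):
        """A short fit recovers the geometry and reports a sane summary table."""
        fam, theta_star, model = small_problem
        res = model.fit(seed=9, n_sim=16, max_outer=2, mc_dx=0.25)
        assert abs(res.params[0] - theta_star[0]) < 25.0
        assert abs(res.params[3] - theta_star[3]) < 25.0
        assert 0.3 < res.chi2_red < 3.0
        text = res.summary()
        assert "center1" in text and "reduced" in text
        phys = res.params_physical
        assert 0.01 <= phys["v"] <= 0.1

    def test_global_two_condition_fit_shares_zone(self):
        """Joint fit of a normal and a rearranged (zone-deleted) allele with
        shared initiation parameters recovers both zones and the
        per-condition velocities."""
        from repkin import smard

        fam = ft.Fig7Family(length=500.0, fragments_normal=[(0.0, 250.0), (250.0, 500.0)],
                            fragments_rearranged=[(0.0, 250.0), (250.0, 435.0)],
                            deletion_start=340.0, deletion_length=65.0,
                            dx=1.0, t_max_hint=22000.0)
        theta_star = np.array([120.0, 50.0, np.log10(2.5e-5), 370.0, 50.0, np.log10(2.5e-5),
                               -7.0, -6.0, -6.0, np.log10(0.04), np.log10(0.03)])
        sets = {}
        for ci, cond in enumerate(fam.build(theta_star)):
            sol = rk.solve(cond.scenario, cond.grid, complete_threshold=0.9999)
            sets[cond.name] = [
                smard.sample_smard(cond.scenario, cond.grid, n_keep=30,
                                   seed=7000 + 10 * ci + j, fragment=frag,
                                   mc_dx=0.2, sol=sol)
                for j, frag in enumerate(cond.fragments)
            ]
        model = ft.SmardReplicationModel(sets, fam)
        res = model.fit(seed=77, n_sim=24, max_outer=2, mc_dx=0.25)
        assert abs(res.params[0] - theta_star[0]) <= 25.0
        assert abs(res.params[3] - theta_star[3]) <= 25.0  # the zone inside the deletion
        assert 0.7 <= 10.0 ** res.params[-2] / 0.04 <= 1.4
        assert 0.7 <= 10.0 ** res.params[-1] / 0.03 <= 1.4
        assert 0.3 <= res.chi2_red <= 3.0

    def test_fit_reproducible(self, small_problem):
        fam, theta_star, model = small_problem
        r1 = model.fit(seed=4, n_sim=8, max_outer=1, mc_dx=0.25)
        r2 = model.fit(seed=4, n_sim=8, max_outer=1, mc_dx=0.25)
        np.testing.assert_array_equal(r1.params, r2.params)
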