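import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import repkin as rk
from repkin.scenario import SchemaError, ScenarioError, load_scenario, save_scenario


class TestInitiationProfile:
    def test_empty_profile_is_zero(self):
        prof = rk.InitiationProfile()
        assert rk.evaluate_initiation(prof, 123.4, 50.0) == 0.0

    def test_two_zone_peak_ratio_is_ten(self, fig2_scenario):
        """The late zone is ten times more efficient at its peak."""
        prof = fig2_scenario.initiation
        late = rk.evaluate_initiation(prof, 800.0, 6000.0)
        early = rk.evaluate_initiation(prof, 200.0, 6000.0)
        assert late / early == pytest.approx(10.0, rel=1e-9)

    def test_late_zone_silent_before_gate(self, fig2_scenario):
        """Before 5000 s the late zone contributes exactly zero."""
        prof = fig2_scenario.initiation
        assert rk.evaluate_initiation(prof, 800.0, 4000.0) < 1e-10  # Gaussian tail of the early zone only
        tail = prof.zones[0].spatial(np.array([800.0]))[0]
        assert rk.evaluate_initiation(prof, 800.0, 4000.0) == pytest.approx(tail)

    def test_gate_is_hard_step(self):
        z = rk.Zone(center=0.0, width=10.0, amplitude=1.0, t_on=100.0, t_off=200.0)
        prof = rk.InitiationProfile(zones=(z,))
        assert prof(np.array([0.0]), 99.999)[0] == 0.0
        assert prof(np.array([0.0]), 100.0)[0] == 1.0
        assert prof(np.array([0.0]), 200.0)[0] == 0.0

    def test_gaussian_integral(self):
        z = rk.Zone(center=0.0, width=20.0, amplitude=3.0)
        x = np.linspace(-400, 400, 16001)
        integral = np.trapezoid(z.spatial(x), x)
        assert integral == pytest.approx(3.0 * 20.0 * math.sqrt(2 * math.pi), rel=1e-6)

    def test_out_of_domain_errors(self):
        grid = rk.Grid(length=100.0)
        prof = rk.InitiationProfile(background=1e-5)
        with pytest.raises(ScenarioError):
            rk.evaluate_initiation(prof, 150.0, 0.0, grid=grid)

    def test_negative_rate_rejected(self):
        with pytest.raises(ScenarioError):
            rk.Zone(center=0.0, width=10.0, amplitude=-1.0)


class TestVelocityProfile:
    def test_constant(self):
        prof = rk.VelocityProfile(v_plus=0.04)
        for d in "+-":
            assert rk.evaluate_velocity(prof, 12.3, 99.0, d) == 0.04

    def test_piecewise_segment(self):
        prof = rk.VelocityProfile(v_plus=0.04, segments=((100.0, 200.0, 0.01),))
        assert rk.evaluate_velocity(prof, 150.0, 0.0, "+") == 0.01
        assert rk.evaluate_velocity(prof, 250.0, 0.0, "+") == 0.04

    def test_directional_asymmetry(self):
        prof = rk.VelocityProfile(v_plus=0.04, v_minus=0.02)
        assert rk.evaluate_velocity(prof, 0.0, 0.0, "+") != rk.evaluate_velocity(prof, 0.0, 0.0, "-")

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ScenarioError):
            rk.VelocityProfile(v_plus=0.0)


class TestBoundaryAndDefects:
    def test_periodic_forbids_injection(self):
        with pytest.raises(ScenarioError):
            rk.BoundaryCondition(mode="periodic", I_left=1e-4)

    def test_defect_validation(self):
        with pytest.raises(ScenarioError):
            rk.DefectModel(spacing=-1.0)
        assert math.isinf(rk.DefectModel(spacing=10.0).repair_time)


MINIMAL = """
initiation:
  background: 0.0
  zones:
    - {shape: gaussian, center: 50.0, width: 10.0, amplitude: 1.0e-5}
velocity: {v_plus: 0.04}
boundary: {mode: periodic}
"""


class TestSerialization:
    def test_minimal_config_evaluates(self):
        sc = load_scenario(MINIMAL)
        assert sc.initiation(np.array([50.0]), 0.0)[0] == pytest.approx(1e-5)
        assert sc.initiation(np.array([60.0]), 0.0)[0] == pytest.approx(1e-5 * math.exp(-0.5))
        assert sc.velocity.evaluate(np.array([0.0]), 0.0, "+")[0] == 0.04

    def test_negative_amplitude_is_schema_error(self):
        bad = MINIMAL.replace("1.0e-5", "-1.0")
        with pytest.raises(SchemaError):
            load_scenario(bad)

    def test_unknown_key_names_path(self):
        bad = MINIMAL + "wibble: 3\n"
        with pytest.raises(SchemaError, match="wibble"):
            load_scenario(bad)

    def test_missing_required_field(self):
        with pytest.raises(SchemaError, match="amplitude"):
            load_scenario("initiation:\n  zones:\n    - {center: 1.0, width: 2.0}\n")

    def test_canonical_roundtrip_fixed_point(self, fig2_scenario):
        text1 = save_scenario(fig2_scenario)
        text2 = save_scenario(load_scenario(text1))
        assert text1 == text2

    def test_packaged_fixture_loads(self):
        from repkin.scenario import two_zone_config_path

        sc = load_scenario(open(two_zone_config_path()).read())
        ref = rk.two_zone_scenario()
        x = np.linspace(0, 1000, 101)
        for t in (0.0, 4000.0, 6000.0):
            np.testing.assert_allclose(sc.initiation(x, t), ref.initiation(x, t))


zone_strategy = st.builds(
    rk.Zone,
    center=st.floats(0, 1000),
    width=st.floats(1, 100),
    amplitude=st.floats(0, 1e-3),
    shape=st.sampled_from(["gaussian", "rounded_box"]),
    edge_scale=st.floats(0.5, 10),
    t_on=st.floats(0, 5000),
)


class TestProperties:
    @given(zones=st.lists(zone_strategy, max_size=4), background=st.floats(0, 1e-4))
    def test_initiation_nonnegative_everywhere(self, zones, background):
        prof = rk.InitiationProfile(zones=tuple(zones), background=background)
        x = np.linspace(0, 1000, 97)
        for t in (0.0, 1000.0, 7000.0):
            assert np.all(prof(x, t) >= 0)

    @given(zones=st.lists(zone_strategy, min_size=1, max_size=3))
    def test_gated_zone_contributes_zero_outside_window(self, zones):
        gated = tuple(
            rk.Zone(center=z.center, width=z.width, amplitude=z.amplitude,
                    shape=z.shape, edge_scale=z.edge_scale, t_on=1000.0, t_off=2000.0)
            for z in zones
        )
        prof = rk.InitiationProfile(zones=gated)
        x = np.linspace(0, 1000, 51)
        assert np.all(prof(x, 999.9) == 0)
        assert np.all(prof(x, 2000.0) == 0)

    @given(zones=st.lists(zone_strategy, max_size=3), background=st.floats(0, 1e-4))
    def test_roundtrip_preserves_evaluation(self, zones, background):
        sc = rk.Scenario(initiation=rk.InitiationProfile(zones=tuple(zones), background=background))
        sc2 = load_scenario(save_scenario(sc))
        x = np.linspace(0, 1000, 41)
        for t in (0.0, 1500.0, 6000.0):
            np.testing.assert_allclose(sc2.initiation(x, t), sc.initiation(x, t), rtol=0, atol=1e-18)
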