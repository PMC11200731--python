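"""Heat-generation model: friction, cutting surrogate, partition, geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bonedrill as bd
from bonedrill.heat import (contact_annulus_mm, mean_contact_radius_mm,
                            removal_area_mm2, removed_volume_mm3,
                            tip_depth_schedule)
from bonedrill.materials import DrillSpec

D35 = DrillSpec(diameter_mm=3.5)

finite = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


class TestFrictionalHeat:
    def test_direct_arithmetic_example(self):
        # 2*pi * 1.75e-3 m * 13.333 rev/s * 0.3 * 20 N
        q = bd.frictional_heat_rate(1.75e-3, 800.0 / 60.0, 0.3, 20.0)
        assert q == pytest.approx(0.87965, rel=1e-4)

    @pytest.mark.parametrize("zeroed", range(4))
    def test_any_zero_factor_gives_zero(self, zeroed):
        args = [1.75e-3, 13.3, 0.3, 20.0]
        args[zeroed] = 0.0
        assert bd.frictional_heat_rate(*args) == 0.0

    @given(r=finite, n=finite, mu=st.floats(0, 1), f=finite)
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_force(self, r, n, mu, f):
        base = bd.frictional_heat_rate(r, n, mu, f)
        assert bd.frictional_heat_rate(r, n, mu, 2 * f) == pytest.approx(
            2 * base, abs=1e-12)

    def test_negative_input_names_argument(self):
        with pytest.raises(ValueError, match="normal_force_n"):
            bd.frictional_heat_rate(1e-3, 10.0, 0.3, -1.0)


class TestCuttingHeat:
    def test_unit_case(self):
        assert bd.cutting_heat_rate(2.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_zero_removal_gives_zero(self):
        assert bd.cutting_heat_rate(0.0, 5.0, 0.9) == 0.0

    def test_halving_eta_halves_output(self):
        assert bd.cutting_heat_rate(3.0, 2.0, 0.4) == pytest.approx(
            0.5 * bd.cutting_heat_rate(3.0, 2.0, 0.8))

    @pytest.mark.parametrize("eta", [-0.1, 1.1])
    def test_eta_out_of_range_rejected(self, eta):
        with pytest.raises(ValueError, match="eta"):
            bd.cutting_heat_rate(1.0, 1.0, eta)


class TestPartition:
    def test_even_split_default(self):
        assert bd.partition_heat(1.0, 0.5) == (0.5, 0.5)

    @pytest.mark.parametrize("eta1,expected", [(0.0, (0.0, 2.0)),
                                               (1.0, (2.0, 0.0))])
    def test_boundaries(self, eta1, expected):
        assert bd.partition_heat(2.0, eta1) == expected

    @given(total=st.floats(0, 1e6, allow_nan=False),
           eta1=st.floats(0, 1, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_split_conserves_exactly(self, total, eta1):
        drill, bone = bd.partition_heat(total, eta1)
        # bone is computed as total - drill, so the sum returns total to
        # within one ulp of floating-point re-association
        assert drill + bone == pytest.approx(total, rel=1e-15)
        assert drill >= 0.0 and bone >= 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="eta1"):
            bd.partition_heat(1.0, 1.2)


class TestRemovalGeometry:
    def test_annulus_area_with_pilot(self):
        sc = bd.preset_scenario("predrill-fig6-pilot",
                                bd.FeedCalibration(0.004, 1.0))
        # pi/4 (3.5^2 - 2.5^2) at full engagement
        area = removal_area_mm2(sc.drill, 4.0, 2.5, 3.0)
        assert area == pytest.approx(math.pi / 4 * 6.0, rel=1e-9)
        assert bd.removal_rate(sc, 1.0, 3.0) == pytest.approx(4.7124, rel=1e-4)

    def test_disc_area_without_pilot(self):
        sc = bd.preset_scenario("predrill-fig6-direct",
                                bd.FeedCalibration(0.004, 1.0))
        assert bd.removal_rate(sc, 1.0, 3.0) == pytest.approx(9.6211, rel=1e-4)

    def test_pilot_equal_to_drill_removes_nothing(self):
        assert removal_area_mm2(D35, 4.0, 3.5, 3.0) == 0.0

    def test_entry_area_grows_from_zero(self):
        areas = [removal_area_mm2(D35, 4.0, None, d) for d in (0.0, 0.3, 0.8, 1.5)]
        assert areas[0] == 0.0
        assert all(a1 > a0 for a0, a1 in zip(areas, areas[1:]))

    def test_breakthrough_area_shrinks_to_zero(self):
        full = removal_area_mm2(D35, 4.0, None, 3.0)
        late = removal_area_mm2(D35, 4.0, None, 4.8)
        done = removal_area_mm2(D35, 4.0, None, 4.0 + D35.cone_height_mm + 0.01)
        assert 0.0 < late < full
        assert done == 0.0

    def test_negative_tip_depth_rejected(self):
        sc = bd.preset_scenario("predrill-fig6-direct",
                                bd.FeedCalibration(0.004, 1.0))
        with pytest.raises(ValueError, match="tip_depth_mm"):
            bd.removal_rate(sc, 1.0, -0.1)

    def test_removed_volume_matches_quadrature(self):
        """Closed-form removed volume vs direct numeric z-integration."""
        tan_phi = math.tan(D35.tip_half_angle_rad)
        for tip, rp in ((0.8, None), (2.5, None), (4.6, None),
                        (2.5, 2.5), (5.0, 2.5)):
            z = np.linspace(0.0, min(tip, 4.0), 200001)
            rho = np.minimum(D35.radius_mm, (tip - z) * tan_phi)
            rpv = 0.0 if rp is None else 0.5 * rp
            area = math.pi * np.maximum(rho ** 2 - rpv ** 2, 0.0)
            expected = float(np.trapezoid(area, z))
            got = removed_volume_mm3(D35, 4.0, rp, tip)
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-6)


class TestPenetration:
    def test_linear_in_force_at_fixed_speed(self):
        calib = bd.FeedCalibration(0.004, 1.0)
        s10 = bd.preset_scenario("feedforce-fig5-10", calib)
        s20 = bd.preset_scenario("feedforce-fig5-20", calib)
        assert bd.penetration_rate(s20) == pytest.approx(
            2.0 * bd.penetration_rate(s10))

    def test_missing_calibration_directs_user(self):
        s = bd.preset_scenario("feedforce-fig5-10")
        with pytest.raises(bd.CalibrationMissingError, match="calibrate_feed"):
            bd.penetration_rate(s)

    def test_through_hole_time_equals_linear_law(self):
        """Engagement-scaled schedule completes 4 mm of cortex in d/(cFn)."""
        calib = bd.FeedCalibration(0.004, 1.0)
        sc = bd.preset_scenario("feedforce-fig5-20", calib)
        _, _, t_drill = tip_depth_schedule(sc, sc.effective_target_depth_mm)
        v_nom = bd.penetration_rate(sc)
        assert t_drill == pytest.approx(4.0 / v_nom, rel=1e-5)

    def test_pilot_pass_time_scales_with_annulus(self):
        calib = bd.FeedCalibration(0.004, 1.0)
        direct = bd.preset_scenario("predrill-fig6-direct", calib)
        pilot = bd.preset_scenario("predrill-fig6-pilot", calib)
        _, _, t_direct = tip_depth_schedule(direct, direct.effective_target_depth_mm)
        _, _, t_pilot = tip_depth_schedule(pilot, pilot.effective_target_depth_mm)
        assert t_pilot / t_direct == pytest.approx(
            (3.5 ** 2 - 2.5 ** 2) / 3.5 ** 2, rel=1e-4)


class TestHeatSourceState:
    def test_power_bookkeeping_is_consistent(self):
        calib = bd.FeedCalibration(0.004, 0.8)
        sc = bd.preset_scenario("feedforce-fig5-20", calib)
        src = bd.heat_source_state(sc, 1.0, 2.0)
        assert src.total_power_w == pytest.approx(
            src.friction_power_w + src.cutting_power_w)
        assert src.flux_to_bone_w + src.flux_to_drill_w == pytest.approx(
            src.total_power_w)
        assert src.friction_power_w > 0 and src.cutting_power_w > 0

    def test_friction_uses_area_weighted_mean_radius(self):
        ann = contact_annulus_mm(D35, 4.0, None, 3.0)
        assert ann == (0.0, 1.75)
        assert mean_contact_radius_mm(ann) == pytest.approx(2.0 / 3.0 * 1.75)

    def test_monotone_total_power_in_force_and_speed(self):
        calib = bd.FeedCalibration(0.004, 0.8)
        base = bd.preset_scenario("feedforce-fig5-10", calib)
        forces = [bd.heat_source_state(
            bd.preset_scenario(f"feedforce-fig5-{f}", calib),
            bd.penetration_rate(bd.preset_scenario(f"feedforce-fig5-{f}", calib)),
            2.0).total_power_w for f in (10, 20, 40, 60)]
        assert all(b > a for a, b in zip(forces, forces[1:]))
        import dataclasses
        fast = dataclasses.replace(base, rotational_speed_rpm=2000.0)
        assert bd.heat_source_state(fast, bd.penetration_rate(fast), 2.0
                                    ).total_power_w > forces[0]
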