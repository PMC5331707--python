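import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvtorsion.phantom import (AcquisitionPlan, BreathHoldRecord,
                               PhantomConfig, RespiratoryConfig,
                               calibrated_truncation_halfwidth, cycle_shape,
                               encode_phase, end_systole_frame,
                               generate_displacement_field, myocardial_mask,
                               plan_slices, sample_breathhold_positions,
                               select_min_mid_max, simulate_experiment1,
                               simulate_experiment2, twist_angle_at,
                               wrap_phase)


class TestConfigs:
    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            PhantomConfig(endo_radius_ed=30.0, epi_radius_ed=20.0)

    def test_invalid_contraction(self):
        with pytest.raises(ValueError):
            PhantomConfig(peak_contraction_fraction=1.0)

    def test_invalid_frames(self):
        with pytest.raises(ValueError):
            PhantomConfig(n_frames=1)

    def test_invalid_coupling(self):
        with pytest.raises(ValueError):
            RespiratoryConfig(diaphragm_to_heart_coupling=1.5)

    def test_negative_window(self):
        with pytest.raises(ValueError):
            RespiratoryConfig(navigator_window_halfwidth=-1.0)


class TestBreathholdSampling:
    def test_zero_variance_all_zero(self):
        resp = RespiratoryConfig(end_exp_sd=0.0)
        recs = sample_breathhold_positions(resp, 10, seed=3)
        assert all(r.mode_position == 0.0 for r in recs)

    def test_determinism(self, resp_default):
        a = sample_breathhold_positions(resp_default, 10, seed=7)
        b = sample_breathhold_positions(resp_default, 10, seed=7)
        assert [r.mode_position for r in a] == [r.mode_position for r in b]

    def test_nonpositive_n(self, resp_default):
        with pytest.raises(ValueError):
            sample_breathhold_positions(resp_default, 0, seed=1)

    def test_calibrated_range_monte_carlo(self, resp_default):
        # mean of per-draw sample ranges of 10 draws ~= configured 10.2 mm
        ranges = []
        for seed in range(1000):
            pos = [r.mode_position
                   for r in sample_breathhold_positions(resp_default, 10, seed)]
            ranges.append(max(pos) - min(pos))
        mean_range = np.mean(ranges)
        assert abs(mean_range - resp_default.end_exp_range) \
            <= 0.2 * resp_default.end_exp_range

    def test_positions_within_truncation(self, resp_default):
        bound = calibrated_truncation_halfwidth(resp_default)
        pos = [r.mode_position
               for r in sample_breathhold_positions(resp_default, 500, seed=0)]
        assert np.max(np.abs(pos)) <= bound

    def test_calibration_solves_small_range(self):
        # a reachable target range is matched by the order-statistics solve
        resp = RespiratoryConfig(end_exp_sd=3.3, end_exp_range=7.0)
        bound = calibrated_truncation_halfwidth(resp)
        assert bound < 8.0 * resp.end_exp_sd
        ranges = []
        for seed in range(800):
            pos = [r.mode_position
                   for r in sample_breathhold_positions(resp, 10, seed)]
            ranges.append(max(pos) - min(pos))
        assert abs(np.mean(ranges) - 7.0) <= 0.2 * 7.0

    def test_record_acceptance_rule(self):
        rec = BreathHoldRecord(mode_position=2.0, window_center=0.0,
                               window_halfwidth=3.0)
        assert rec.accepted
        rec = BreathHoldRecord(mode_position=4.0, window_center=0.0,
                               window_halfwidth=3.0)
        assert not rec.accepted


class TestSelectMinMidMax:
    def test_simple(self):
        recs = [BreathHoldRecord(p, 0.0, 50.0) for p in (-5.0, 0.0, 5.0)]
        assert select_min_mid_max(recs) == (-5.0, 0.0, 5.0)

    def test_degenerate(self):
        recs = [BreathHoldRecord(1.0, 0.0, 50.0)] * 4
        assert select_min_mid_max(recs) == (1.0, 1.0, 1.0)

    def test_tie_toward_smaller(self):
        # median of {-6,-2,0,1,3,8} is 0.5; 0 and 1 tie, smaller wins
        recs = [BreathHoldRecord(p, 0.0, 50.0)
                for p in (-6.0, -2.0, 0.0, 1.0, 3.0, 8.0)]
        assert select_min_mid_max(recs) == (-6.0, 0.0, 8.0)

    def test_too_few(self):
        recs = [BreathHoldRecord(0.0, 0.0, 50.0)] * 2
        with pytest.raises(ValueError):
            select_min_mid_max(recs)


class TestPlanSlices:
    def test_88mm_example(self):
        cfg = PhantomConfig(long_axis_length=88.0)
        plan = plan_slices(cfg)
        assert np.allclose(plan.slice_positions, [0, 22, 44, 66, 88])
        assert plan.d_nominal == pytest.approx(44.0)

    def test_basal_apical_are_second_and_fourth(self, default_cfg):
        plan = plan_slices(default_cfg)
        assert plan.basal_index == 2 and plan.apical_index == 4
        assert plan.basal_position == plan.slice_positions[1]
        assert plan.apical_position == plan.slice_positions[3]

    @given(st.floats(min_value=50.0, max_value=150.0))
    @settings(max_examples=25, deadline=None)
    def test_d_nominal_half_span(self, length):
        plan = plan_slices(PhantomConfig(long_axis_length=length))
        span = plan.slice_positions[4] - plan.slice_positions[0]
        assert plan.d_nominal == pytest.approx(span / 2)

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionPlan(slice_positions=(0.0, 10.0, 30.0, 60.0, 100.0))


class TestDisplacementField:
    def test_frame0_zero(self, default_cfg):
        ux, uy, mask = generate_displacement_field(default_cfg, 22.0, 0)
        assert np.allclose(ux[mask], 0.0) and np.allclose(uy[mask], 0.0)

    def test_linear_profile_gradient_exact(self, default_cfg):
        plan = plan_slices(default_cfg)
        es = end_systole_frame(default_cfg)
        theta_a = twist_angle_at(default_cfg, plan.apical_position)
        theta_b = twist_angle_at(default_cfg, plan.basal_position)
        expected = default_cfg.twist_gradient * plan.d_nominal / 10.0
        assert theta_a - theta_b == pytest.approx(expected)
        assert expected == pytest.approx(14.96)  # 3.4 deg/cm * 4.4 cm
        assert cycle_shape(default_cfg)[es] == pytest.approx(1.0)

    def test_pure_rotation_preserves_radius(self):
        cfg = PhantomConfig(peak_contraction_fraction=0.0)
        es = end_systole_frame(cfg)
        ux, uy, mask = generate_displacement_field(cfg, 66.0, es)
        half = (cfg.grid_size - 1) / 2 * cfg.pixel_spacing
        ax = np.linspace(-half, half, cfg.grid_size)
        x, y = np.meshgrid(ax, ax)
        r0 = np.hypot(x, y)[mask]
        rt = np.hypot(x[mask] + ux[mask], y[mask] + uy[mask])
        assert np.allclose(rt, r0)

    def test_outside_ventricle_raises(self, default_cfg):
        with pytest.raises(ValueError):
            generate_displacement_field(default_cfg, -1.0, 0)
        with pytest.raises(ValueError):
            generate_displacement_field(
                default_cfg, default_cfg.long_axis_length + 1.0, 0)

    def test_sign_convention_base_negative_apex_positive(self, default_cfg):
        plan = plan_slices(default_cfg)
        assert twist_angle_at(default_cfg, plan.basal_position) < 0
        assert twist_angle_at(default_cfg, plan.apical_position) > 0

    def test_sigmoid_profile_same_endpoints(self):
        lin = PhantomConfig(twist_profile="linear")
        sig = PhantomConfig(twist_profile="sigmoid")
        for z in (0.0, lin.long_axis_length):
            assert twist_angle_at(sig, z) == pytest.approx(
                twist_angle_at(lin, z), rel=1e-9)


class TestEncodePhase:
    def test_zero_displacement_zero_phase(self, default_cfg):
        mask = myocardial_mask(default_cfg)
        zeros = np.zeros_like(mask, dtype=float)
        px, py = encode_phase(zeros, zeros, mask, k=0.06)
        assert np.all(px == 0.0) and np.all(py == 0.0)

    def test_10mm_wraps(self, default_cfg):
        mask = myocardial_mask(default_cfg)
        u = np.full(mask.shape, 10.0)
        px, _ = encode_phase(u, np.zeros_like(u), mask, k=0.06)
        # 2*pi*0.6 wraps to 2*pi*(-0.4)
        assert np.allclose(px[mask], 2 * np.pi * -0.4)

    def test_half_period_maps_to_minus_pi(self, default_cfg):
        mask = myocardial_mask(default_cfg)
        k = 0.06
        u = np.full(mask.shape, 1.0 / (2 * k))
        px, _ = encode_phase(u, np.zeros_like(u), mask, k=k)
        assert np.allclose(px[mask], -np.pi)

    @given(st.floats(min_value=-100, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_wrap_range_half_open(self, value):
        w = wrap_phase(np.array([value]))
        assert -np.pi <= w[0] < np.pi


def _acq_digest(acq):
    h = hashlib.sha256()
    for arr in (acq.magnitude, acq.phase_x, acq.phase_y, acq.myocardial_mask):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(str((acq.plane_position, acq.true_diaphragm_offset,
                  acq.slice_label, acq.acquisition_index)).encode())
    return h.hexdigest()


class TestExperiment1:
    def test_eight_acquisitions(self, tiny_cfg, resp_default):
        plan = plan_slices(tiny_cfg)
        acqs, truth = simulate_experiment1(tiny_cfg, resp_default, plan, seed=1)
        assert len(acqs) == 8
        labels = [(a.slice_label, a.window_label) for a in acqs]
        for w in ("min", "mid", "max", "mid_repeat"):
            assert ("basal", w) in labels and ("apical", w) in labels

    def test_metadata_never_reflects_offset(self, tiny_cfg, resp_default):
        plan = plan_slices(tiny_cfg)
        acqs, _ = simulate_experiment1(tiny_cfg, resp_default, plan, seed=2)
        for a in acqs:
            expected = (plan.basal_position if a.slice_label == "basal"
                        else plan.apical_position)
            assert a.plane_position == expected

    def test_zero_window_mid_repeats_identical(self, tiny_cfg):
        resp = RespiratoryConfig(navigator_window_halfwidth=0.0)
        plan = plan_slices(tiny_cfg)
        acqs, truth = simulate_experiment1(tiny_cfg, resp, plan, seed=3)
        by_window = {(a["slice_label"], a["window_label"]): a["true_offset_mm"]
                     for a in truth["acquisitions"]}
        assert by_window[("basal", "mid")] == by_window[("basal", "mid_repeat")]
        assert by_window[("apical", "mid")] == by_window[("apical", "mid_repeat")]

    def test_offsets_within_windows(self, tiny_cfg, resp_default):
        plan = plan_slices(tiny_cfg)
        _, truth = simulate_experiment1(tiny_cfg, resp_default, plan, seed=4)
        for a in truth["acquisitions"]:
            assert abs(a["true_offset_mm"] - a["window_center_mm"]) \
                <= a["window_halfwidth_mm"] + 1e-12

    def test_bit_identical_under_fixed_seed(self, tiny_cfg, resp_default):
        plan = plan_slices(tiny_cfg)
        a1, _ = simulate_experiment1(tiny_cfg, resp_default, plan, seed=5)
        a2, _ = simulate_experiment1(tiny_cfg, resp_default, plan, seed=5)
        assert [_acq_digest(a) for a in a1] == [_acq_digest(a) for a in a2]

    def test_phases_wrapped_and_masks_shared(self, tiny_cfg, resp_default):
        plan = plan_slices(tiny_cfg)
        acqs, _ = simulate_experiment1(tiny_cfg, resp_default, plan, seed=6)
        for a in acqs:
            assert np.all(a.phase_x >= -np.pi) and np.all(a.phase_x < np.pi)
            assert np.all(a.phase_y >= -np.pi) and np.all(a.phase_y < np.pi)


class TestExperiment2:
    def test_counts(self, tiny_cfg, resp_default):
        plan = plan_slices(tiny_cfg)
        sessions, _ = simulate_experiment2(tiny_cfg, resp_default, plan,
                                           n_pairs=10, seed=1)
        assert len(sessions["breathhold"]) == 20
        assert len(sessions["navigator"]) == 20

    def test_alternating_order(self, tiny_cfg, resp_default):
        plan = plan_slices(tiny_cfg)
        sessions, _ = simulate_experiment2(tiny_cfg, resp_default, plan,
                                           n_pairs=3, seed=2)
        for acqs in sessions.values():
            labels = [a.slice_label for a in sorted(
                acqs, key=lambda a: a.acquisition_index)]
            assert labels == ["basal", "apical"] * 3

    def test_zero_window_all_offsets_equal(self, tiny_cfg):
        resp = RespiratoryConfig(navigator_window_halfwidth=0.0)
        plan = plan_slices(tiny_cfg)
        _, truth = simulate_experiment2(tiny_cfg, resp, plan, n_pairs=3, seed=3)
        nav = [a["true_offset_mm"] for a in truth["acquisitions"]
               if a["protocol"] == "navigator"]
        assert len(set(nav)) == 1

    def test_n_pairs_validation(self, tiny_cfg, resp_default):
        plan = plan_slices(tiny_cfg)
        with pytest.raises(ValueError):
            simulate_experiment2(tiny_cfg, resp_default, plan, n_pairs=1, seed=1)

    def test_breathhold_offset_sd_matches_config(self, resp_default):
        # Monte-Carlo oracle: free-protocol offsets have SD ~ end_exp_sd
        from lvtorsion.phantom import _draw_offsets
        rng = np.random.default_rng(0)
        draws = _draw_offsets(resp_default, 0.0,
                              resp_default.wide_window_halfwidth, 20000, rng)
        assert np.std(draws) == pytest.approx(resp_default.end_exp_sd, rel=0.05)
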