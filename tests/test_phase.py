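import numpy as np
import pytest

from condenstat import (
    CalibrationFactors,
    SimParams,
    classify_cellwide,
    classify_condensation,
    compare_boundaries,
    cytoplasm_intensity,
    fit_phase_boundary,
    intensity_to_concentration,
    phase_point,
    render_activation_response,
    simulate_cell,
    simulate_titration,
)
from condenstat.datamodel import ConfigurationError
from condenstat.phase import concentration_to_intensity

calib = CalibrationFactors(slope={"g": 1000.0, "r": 400.0}, offset={"r": 50.0})


class TestCalibration:
    def test_linear_conversion(self):
        assert intensity_to_concentration(2500.0, "g", calib) == pytest.approx(2.5)
        assert intensity_to_concentration(50.0, "r", calib) == 0.0

    def test_round_trip_identity(self):
        c = 3.7
        i = concentration_to_intensity(c, "r", calib)
        assert intensity_to_concentration(i, "r", calib) == pytest.approx(c)

    def test_unknown_channel_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            intensity_to_concentration(1.0, "missing", calib)


class TestPhasePoint:
    def test_core_is_monomer_over_24_and_valence_is_client_per_core(self):
        c_core, valence = phase_point(24.0, 10.0)
        assert c_core == 1.0 and valence == 10.0

    def test_unit_valence(self):
        _, valence = phase_point(12.0, 0.5)
        assert valence == 1.0

    def test_joint_rescaling_preserves_valence(self):
        c1, v1 = phase_point(6.0, 2.0)
        c2, v2 = phase_point(12.0, 4.0)
        assert v2 == pytest.approx(v1)
        assert c2 == pytest.approx(2 * c1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            phase_point(0.0, 1.0)


class TestCytoplasmIntensity:
    def test_uniform_pre_activation_frame(self):
        p = SimParams(seed=1, n_aggregates=0, n_condensates=0, bg_mean=480.0,
                      bg_sd=0.0, light_schedule=[(2, 4)], n_frames=5)
        stack, roi, _ = simulate_cell(p)
        vals = cytoplasm_intensity(stack, roi)
        assert vals["p62"] == pytest.approx(480.0)

    def test_patch_area_close_to_ten_square_microns(self):
        p = SimParams(seed=1, n_aggregates=0, n_condensates=0,
                      light_schedule=[(2, 4)], n_frames=5)
        stack, roi, _ = simulate_cell(p)
        from condenstat.segment import auto_background_region
        patch = auto_background_region(stack.frame(1, 0), roi,
                                       stack.pixel_size_um, tile_um=np.sqrt(10.0))
        area = patch.n_px * stack.pixel_size_um**2
        assert area == pytest.approx(10.0, rel=0.20)

    def test_concentration_recovered_through_calibration(self):
        cal = CalibrationFactors(slope={"p62": 100.0, "polyQ": 250.0})
        p = SimParams(seed=4, n_condensates=0, n_aggregates=0, bg_mean=500.0,
                      bg_sd=10.0, light_schedule=[(2, 4)], n_frames=5)
        stack, roi, _ = simulate_cell(p)
        vals = cytoplasm_intensity(stack, roi)
        assert intensity_to_concentration(vals["p62"], "p62", cal) == pytest.approx(5.0, rel=0.05)
        assert intensity_to_concentration(vals["polyQ"], "polyQ", cal) == pytest.approx(2.0, rel=0.05)

    def test_no_preactivation_frame_is_an_error(self):
        p = SimParams(seed=1, n_aggregates=0, n_condensates=0,
                      light_schedule=[(0, 2)], n_frames=3)
        stack, roi, _ = simulate_cell(p)
        with pytest.raises(ValueError):
            cytoplasm_intensity(stack, roi)


class TestCondensationClassifier:
    @pytest.mark.parametrize("seed", range(8))
    def test_droplet_and_uniform_responses_separated(self, seed):
        st, roi = render_activation_response(True, seed=seed)
        condensed, ev = classify_condensation(st, roi)
        assert condensed and ev["cv_ratio"] > 1.5 and ev["n_circular_objects"] >= 1
        st0, roi0 = render_activation_response(False, seed=seed)
        assert not classify_condensation(st0, roi0)[0]

    def test_gain_invariance(self):
        st, roi = render_activation_response(False, seed=1)
        st.data *= 2.0  # uniform brightening must not look like condensation
        condensed, ev = classify_condensation(st, roi)
        assert not condensed
        assert ev["cv_ratio"] == pytest.approx(1.0, abs=0.05)

    def test_cellwide_labels(self):
        st, roi = render_activation_response(True, seed=2)
        assert classify_cellwide(st, roi)[0] == "droplet_condensation"
        st0, roi0 = render_activation_response(False, seed=2)
        assert classify_cellwide(st0, roi0)[0] == "no_droplet_condensation"

    def test_irregular_recruitment_is_not_droplet_condensation(self):
        st, roi = render_activation_response(True, irregular=True, seed=2)
        label, ev = classify_cellwide(st, roi)
        assert label == "no_droplet_condensation"
        assert ev["n_circular_objects"] < 2


class TestPhaseBoundary:
    def test_separable_titration_recovers_threshold(self):
        pts = simulate_titration(400, K=1.0, seed=7)
        fit = fit_phase_boundary(pts)
        assert fit.accuracy == 1.0
        assert fit.K_hat == pytest.approx(1.0, rel=0.25)

    def test_shuffled_labels_drop_to_chance_accuracy(self, rng):
        pts = simulate_titration(400, K=1.0, seed=7)
        pts = pts.assign(condensed=rng.permutation(pts.condensed.to_numpy()))
        fit = fit_phase_boundary(pts)
        assert abs(fit.accuracy - 0.5) < 2 * 0.5 / np.sqrt(400) * 1.96 + 0.02

    def test_single_class_rejected(self):
        pts = simulate_titration(50, K=1e-9, seed=1)  # everything condenses
        with pytest.raises(ValueError):
            fit_phase_boundary(pts)

    def test_identical_conditions_show_no_shift(self):
        pts = simulate_titration(200, K=1.0, seed=5)
        shift = compare_boundaries(pts, pts.copy(), n_boot=200, seed=1)
        assert shift.log_ratio == 0.0
        assert shift.ci_low <= 0.0 <= shift.ci_high
        assert not shift.shifted

    def test_fourfold_threshold_shift_detected(self):
        a = simulate_titration(400, K=1.0, seed=8)
        b = simulate_titration(400, K=4.0, seed=9)
        shift = compare_boundaries(a, b, n_boot=300, seed=2)
        assert shift.shifted
        assert shift.log_ratio == pytest.approx(np.log(4.0), rel=0.30)
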