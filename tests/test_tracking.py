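"""Profile extraction, step detection, tracking and velocity statistics."""
import numpy as np
import pytest

from stepkin.errors import ConfigError, DomainError, InsufficientDataError, TrackingError
from stepkin.synth import StepLayoutItem, gen_height_series
from stepkin.tracking import (
    HeightProfile,
    StepTrace,
    detect_steps,
    extract_profile,
    fit_velocity,
    track_step,
    velocity_independence_test,
)

LINE = ((16.0, 0.0), (16.0, 255.0))
A_NM = 2.413


class TestExtractProfile:
    def test_constant_frame_gives_constant_profile(self):
        frame = np.full((32, 64), 5.0)
        prof = extract_profile(frame, (10, 0), (10, 63), pixel_size=4.0)
        assert np.allclose(prof.heights, 5.0)

    def test_diagonal_length_is_euclidean(self):
        frame = np.zeros((64, 64))
        prof = extract_profile(frame, (0, 0), (30, 40), pixel_size=2.0)
        assert prof.positions[-1] == pytest.approx(50.0 * 2.0)

    def test_two_terrace_map_has_single_riser(self):
        series, _ = gen_height_series([StepLayoutItem(300.0, "full", 0.0)], noise_sd=0.0,
                                      frame_times=(0.0, 1.0))
        prof = extract_profile(series.frames[0], *LINE, pixel_size=series.pixel_size)
        jumps = np.abs(np.diff(prof.heights))
        assert np.sum(jumps > 1.0) == 1

    def test_out_of_bounds_endpoint(self):
        with pytest.raises(DomainError, match="outside"):
            extract_profile(np.zeros((8, 8)), (0, 0), (10, 3), pixel_size=1.0)


class TestDetectSteps:
    def test_full_and_half_risers_classified(self):
        series, _ = gen_height_series(
            [StepLayoutItem(200.0, "full", 0.0), StepLayoutItem(600.0, "half", 0.0)],
            noise_sd=0.05, seed=1, frame_times=(0.0, 1.0),
        )
        prof = extract_profile(series.frames[0], *LINE, pixel_size=series.pixel_size)
        found = detect_steps(prof, A_NM, tol=0.3)
        assert [d.height_class for d in found] == ["full", "half"]
        assert found[0].position == pytest.approx(200.0, abs=8.0)

    def test_flat_profile_no_detections(self):
        prof = HeightProfile(np.arange(50.0), np.zeros(50))
        assert detect_steps(prof, A_NM, tol=0.3) == []

    def test_intermediate_riser_unclassified(self):
        heights = np.where(np.arange(60.0) < 30, 0.0, -0.6)
        prof = HeightProfile(np.arange(60.0) * 4.0, heights)
        found = detect_steps(prof, A_NM, tol=0.3)
        assert len(found) == 1 and found[0].height_class == "unclassified"

    def test_tolerance_bounded_by_quarter_unit(self):
        prof = HeightProfile(np.arange(10.0), np.zeros(10))
        with pytest.raises(ConfigError):
            detect_steps(prof, A_NM, tol=0.7)

    def test_recovery_rate_at_high_snr(self):
        # >= 95% riser recovery at SNR >= 5 (sigma = height/5 per class)
        found_total = expected_total = 0
        for seed in range(20):
            series, _ = gen_height_series(
                [StepLayoutItem(250.0, "full", 0.0), StepLayoutItem(650.0, "half", 0.0)],
                noise_sd=1.2065 / 5.0, seed=seed, frame_times=(0.0, 1.0),
            )
            prof = extract_profile(series.frames[0], *LINE, pixel_size=series.pixel_size)
            found = detect_steps(prof, A_NM, tol=0.45)
            expected_total += 2
            found_total += min(len(found), 2)
        assert found_total / expected_total >= 0.95

    def test_zero_false_positives_on_flat_noise(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            prof = HeightProfile(np.arange(200.0) * 4.0, rng.normal(0, 0.3 / 3.5, 200))
            assert detect_steps(prof, A_NM, tol=0.3) == []


class TestTrackStep:
    def test_constant_velocity_displacements(self):
        series, _ = gen_height_series(
            [StepLayoutItem(200.0, "full", 0.5)], noise_sd=0.05, seed=3,
            frame_times=tuple(float(t) for t in range(0, 100, 10)),
        )
        trace = track_step(series, LINE, A_NM, 0.3, reference_point_nm=1000.0)
        expected = 0.5 * np.arange(0, 100, 10)
        assert np.allclose(trace.displacements, expected, atol=4.0)

    def test_static_lattice_zero_displacements(self):
        series, _ = gen_height_series(
            [StepLayoutItem(400.0, "full", 0.0)], noise_sd=0.0, frame_times=(0.0, 10.0, 20.0)
        )
        trace = track_step(series, LINE, A_NM, 0.3, reference_point_nm=1000.0)
        assert np.allclose(trace.displacements, 0.0)

    def test_two_steps_inside_gate_is_tracking_error(self):
        series, _ = gen_height_series(
            [StepLayoutItem(400.0, "full", 0.0), StepLayoutItem(430.0, "half", 0.0)],
            noise_sd=0.0, frame_times=(0.0, 10.0),
        )
        with pytest.raises(TrackingError):
            track_step(series, LINE, A_NM, 0.3, reference_point_nm=1000.0,
                       initial_position_nm=400.0, gate_nm=50.0)

    def test_step_lost_reports_frame(self):
        series, _ = gen_height_series(
            [StepLayoutItem(400.0, "full", 0.0)], noise_sd=0.0, frame_times=(0.0, 10.0)
        )
        with pytest.raises(TrackingError, match="frame"):
            track_step(series, LINE, A_NM, 0.3, reference_point_nm=1000.0,
                       initial_position_nm=800.0, gate_nm=20.0)

    def test_dissolution_gives_negative_velocity(self):
        series, _ = gen_height_series(
            [StepLayoutItem(600.0, "full", -0.4)], noise_sd=0.0,
            frame_times=tuple(float(t) for t in range(0, 60, 10)),
        )
        trace = track_step(series, LINE, A_NM, 0.3, reference_point_nm=1000.0)
        assert fit_velocity(trace).velocity < 0


class TestFitVelocity:
    def test_exact_line(self):
        t = np.arange(10.0)
        est = fit_velocity(StepTrace(t, 0.8 * t))
        assert est.velocity == pytest.approx(0.8, rel=1e-12)
        assert est.sd == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_pipeline_recovery(self):
        series, _ = gen_height_series(
            [StepLayoutItem(200.0, "full", 0.25)], noise_sd=0.0,
            frame_times=tuple(float(t) for t in range(0, 200, 10)),
        )
        trace = track_step(series, LINE, A_NM, 0.3, reference_point_nm=1000.0)
        est = fit_velocity(trace)
        # pixel quantization (4 nm pixels) limits accuracy, not noise
        assert est.velocity == pytest.approx(0.25, abs=0.02)

    def test_noisy_recovery_within_3_sd(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 190, 20)
        est = fit_velocity(StepTrace(t, 0.5 * t + rng.normal(0, 2.0, t.size)))
        assert abs(est.velocity - 0.5) < 3 * est.sd

    def test_estimator_unbiased_over_replicates(self):
        vels = []
        t = np.linspace(0, 190, 20)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            vels.append(fit_velocity(StepTrace(t, 0.5 * t + rng.normal(0, 2.0, t.size))).velocity)
        sem = np.std(vels, ddof=1) / np.sqrt(len(vels))
        assert abs(np.mean(vels) - 0.5) < 2 * sem

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_velocity(StepTrace(np.array([0.0, 1.0]), np.array([0.0, 1.0])))

    def test_zero_time_span(self):
        with pytest.raises(DomainError):
            fit_velocity(StepTrace(np.array([1.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0])))


class TestVelocityIndependence:
    def test_null_groups_usually_not_rejected(self):
        rng = np.random.default_rng(1)
        accepted = 0
        for _ in range(20):
            groups = {
                "full": rng.normal(0.5, 0.05, 5),
                "half": rng.normal(0.5, 0.05, 5),
            }
            rep = velocity_independence_test(groups, n_permutations=2000, seed=0)
            accepted += rep["p_value"] > 0.05
        assert accepted >= 16  # the direct-incorporation signature

    def test_distinct_velocities_rejected(self):
        rng = np.random.default_rng(2)
        groups = {
            "short_l": rng.normal(0.5, 0.01, 6),
            "long_l": rng.normal(1.0, 0.01, 6),
        }
        rep = velocity_independence_test(groups, n_permutations=5000, seed=0)
        assert rep["p_value"] < 0.01
        assert rep["verdict"] != "consistent with direct incorporation"

    def test_identical_estimates_p_one(self):
        groups = {"a": [0.5, 0.5, 0.5], "b": [0.5, 0.5, 0.5]}
        rep = velocity_independence_test(groups, seed=0)
        assert rep["p_value"] == 1.0

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(InsufficientDataError):
            velocity_independence_test({"only": [0.5, 0.6, 0.7]})
        with pytest.raises(InsufficientDataError):
            velocity_independence_test({"a": [0.5, 0.6], "b": [0.5, 0.6, 0.7]})
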