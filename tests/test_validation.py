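import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from incuscan.errors import LowConfidenceError
from incuscan.motion import StageConfig, VirtualStage
from incuscan.validation import (
    MotionTrial,
    apply_steps_correction,
    build_motion_protocol,
    estimate_translation,
    measure_motion,
    measure_saved_protocol,
    rest_time_analysis,
    run_motion_protocol,
    stationary_stability_analysis,
    summarize_motion_fidelity,
)


class TestProtocol:
    def test_default_protocol_size(self):
        trials = build_motion_protocol()
        assert len(trials) == 400  # -> 800 images

    def test_custom_protocol_counting(self):
        trials = build_motion_protocol(
            distances=[0.5], axes=["x"], directions=[1], repeats=3
        )
        assert len(trials) == 3

    def test_empty_distances_rejected(self):
        with pytest.raises(ValueError):
            build_motion_protocol(distances=[])

    def test_trial_filenames(self):
        trial = MotionTrial(axis="x", direction=1, distance=0.3, repeat=2)
        assert trial.filename("start") == "X_pos_0.300_r02_start.bmp"
        assert trial.filename("end") == "X_pos_0.300_r02_end.bmp"


class TestEstimateTranslation:
    def test_identity(self):
        img = ndimage.gaussian_filter(
            np.random.default_rng(0).normal(100, 20, (128, 128)), 2
        )
        est = estimate_translation(img, img)
        assert (est.dx, est.dy) == (0.0, 0.0)
        assert est.confidence == pytest.approx(1.0, abs=0.01)

    def test_constructed_integer_shift(self):
        img = ndimage.gaussian_filter(
            np.random.default_rng(1).normal(100, 20, (200, 200)), 2
        )
        shifted = np.roll(img, (-3, 5), axis=(0, 1))
        est = estimate_translation(img, shifted)
        assert est.dx == pytest.approx(5, abs=0.5)
        assert est.dy == pytest.approx(-3, abs=0.5)

    def test_antisymmetry(self):
        img = ndimage.gaussian_filter(
            np.random.default_rng(2).normal(100, 20, (200, 200)), 2
        )
        shifted = np.real(
            np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img), (2.3, -7.6)))
        )
        ab = estimate_translation(img, shifted)
        ba = estimate_translation(shifted, img)
        assert ab.dx == pytest.approx(-ba.dx, abs=0.1)
        assert ab.dy == pytest.approx(-ba.dy, abs=0.1)

    def test_unrelated_noise_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(LowConfidenceError):
            estimate_translation(
                rng.normal(size=(200, 200)), rng.normal(size=(200, 200))
            )


def _synthetic_measurements(factor: float, distances=None) -> pd.DataFrame:
    """Trial table where observed motion = factor x commanded, on both axes."""
    distances = distances or [round(0.1 * k, 1) for k in range(1, 11)]
    ppum = 0.3
    rows = []
    for axis in ("x", "y"):
        for d in distances:
            for rep in (1, 2, 3):
                shift = d * factor * 1000 * ppum
                rows.append(
                    {
                        "axis": axis,
                        "direction": 1,
                        "distance_mm": d,
                        "repeat": rep,
                        "dx_px": shift if axis == "x" else 0.0,
                        "dy_px": shift if axis == "y" else 0.0,
                    }
                )
    return pd.DataFrame(rows)


class TestFidelitySummary:
    CURRENT = {"x": 80.0, "y": 80.0}

    def test_exact_motion_passes_unchanged(self):
        s = summarize_motion_fidelity(_synthetic_measurements(1.0), 0.3, self.CURRENT)
        assert s.all_pass
        assert s.recommended_steps_per_mm == self.CURRENT

    def test_four_percent_over_movement_passes(self):
        s = summarize_motion_fidelity(_synthetic_measurements(1.04), 0.3, self.CURRENT)
        assert s.all_pass
        assert s.recommended_steps_per_mm == self.CURRENT

    def test_eight_percent_fails_with_ratio_correction(self):
        s = summarize_motion_fidelity(_synthetic_measurements(1.08), 0.3, self.CURRENT)
        assert not s.all_pass
        assert s.recommended_steps_per_mm["x"] == pytest.approx(80.0 / 1.08)

    def test_under_movement_correction(self):
        s = summarize_motion_fidelity(_synthetic_measurements(0.8), 0.3, self.CURRENT)
        assert s.recommended_steps_per_mm["x"] == pytest.approx(100.0)

    def test_median_robust_to_single_outlier(self):
        df = _synthetic_measurements(1.0)
        df.loc[0, "dx_px"] *= 10  # one wild repeat
        s = summarize_motion_fidelity(df, 0.3, self.CURRENT)
        assert s.all_pass

    def test_long_distance_uses_absolute_bound(self):
        # 0.8% deviation at 1.5 mm is 12 µm: inside ±13 µm, outside nothing
        df = _synthetic_measurements(1.008, distances=[1.5])
        s = summarize_motion_fidelity(df, 0.3, self.CURRENT)
        assert s.all_pass
        df = _synthetic_measurements(1.01, distances=[1.5])  # 15 µm
        s = summarize_motion_fidelity(df, 0.3, self.CURRENT)
        assert not s.all_pass

    def test_missing_scale_rejected(self):
        with pytest.raises(ValueError):
            summarize_motion_fidelity(_synthetic_measurements(1.0), 0.0, self.CURRENT)


class TestClosedLoop:
    def test_protocol_saves_named_pairs(self, survey_camera, cells_specimen, tmp_path):
        stage = VirtualStage(StageConfig(position_noise_sd=0.0))
        trials = build_motion_protocol(distances=[0.3], axes=["x"],
                                       directions=[1], repeats=2)
        manifest = run_motion_protocol(
            stage, survey_camera, cells_specimen, trials, tmp_path
        )
        assert len(manifest) == 2 * len(trials)
        assert (tmp_path / "X_pos_0.300_r02_start.bmp").exists()
        assert (tmp_path / "X_pos_0.300_r02_end.bmp").exists()
        measured = measure_saved_protocol(tmp_path)
        observed = abs(measured["dx_px"].iloc[0]) / 0.3 / 1000.0
        assert observed == pytest.approx(0.3, rel=0.01)

    def test_calibration_recovery_single_cycle(self, survey_camera, cells_specimen):
        cfg = StageConfig(
            firmware_steps_per_mm=(80, 80, 400),
            true_steps_per_mm=(100, 100, 400),  # stage under-moves by 20%
            seed=2,
        )
        stage = VirtualStage(cfg)
        trials = build_motion_protocol(repeats=3)
        m = measure_motion(stage, survey_camera, cells_specimen, trials)
        summary = summarize_motion_fidelity(
            m, survey_camera.pixels_per_um, {"x": 80.0, "y": 80.0}
        )
        assert not summary.all_pass
        corrected = apply_steps_correction(cfg, summary)
        post_ratio = np.array(corrected.firmware_steps_per_mm[:2]) / np.array(
            corrected.true_steps_per_mm[:2]
        )
        assert np.all(np.abs(post_ratio - 1.0) < 0.01)


class TestStability:
    def test_constant_positions(self):
        r = stationary_stability_analysis(np.zeros((10, 2)), 60.0)
        assert r.max_deviation_um == (0.0, 0.0)
        assert r.slope_um_per_min == (0.0, 0.0)

    def test_null_noise_rarely_flags_drift(self):
        # per-axis false-positive rate of the 5% trend test stays near 5%
        flags = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pos = rng.normal(0.0, 2.0, size=(60, 2))
            r = stationary_stability_analysis(pos, 60.0)
            flags += sum(r.drift_detected())
        assert flags <= 20  # 200 axis-tests at alpha = 0.05

    def test_injected_drift_detected(self):
        rng = np.random.default_rng(0)
        t = np.arange(60.0)  # minutes
        pos = np.column_stack([t * 1.0, np.zeros(60)]) + rng.normal(0, 0.5, (60, 2))
        r = stationary_stability_analysis(pos, 60.0)
        assert r.slope_um_per_min[0] == pytest.approx(1.0, abs=0.05)
        assert r.drift_detected()[0]
        assert r.verdict == "persistent drift detected"

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            stationary_stability_analysis(np.zeros((2, 2)), 60.0)


class TestRestTime:
    def test_settle_times_recovered(self, survey_camera, cells_specimen):
        for axis, expected in (("x", 0.6), ("y", 1.0)):
            stage = VirtualStage(StageConfig(position_noise_sd=0.0))
            r = rest_time_analysis(stage, survey_camera, cells_specimen, axis=axis)
            assert r.stabilized
            assert r.min_delay_s == pytest.approx(expected, abs=0.1)

    def test_no_vibration_means_no_delay(self, survey_camera, cells_specimen):
        stage = VirtualStage(
            StageConfig(position_noise_sd=0.0, vibration_amplitude_um=0.0)
        )
        r = rest_time_analysis(stage, survey_camera, cells_specimen, axis="x")
        assert r.min_delay_s == 0.0
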