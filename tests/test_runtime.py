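from pathlib import Path

import numpy as np
import pytest

from incuscan.camera import CameraConfig, build_specimen
from incuscan.motion import StageConfig, VirtualStage
from incuscan.plate import Anchor, PlateSpec, WellAddress
from incuscan.runtime import (
    estimate_scan_duration_min,
    plan_plate_scan,
    plan_well_scan,
    run_timelapse,
    save_image,
    schedule_timelapse,
)


class TestWellScanPlanning:
    def test_single_position_is_anchor(self, plate6, profile_10x):
        pos = plan_well_scan(plate6, WellAddress(1, 1), profile_10x, 1, 1,
                             Anchor.CENTER)
        assert len(pos) == 1
        assert (pos[0].x_mm, pos[0].y_mm) == pytest.approx((30.0, 28.0))

    def test_grid_spacing_and_order(self, plate6):
        from incuscan.optics import derive_profile

        profile = derive_profile(1.0, (1300, 925), 0.8)  # increments 1040/740 µm
        plate = PlateSpec(format=6, well_diameter=36, pitch_x=39, pitch_y=39,
                          a1_center=(18, 18))
        pos = plan_well_scan(plate, WellAddress(1, 1), profile, 2, 2, Anchor.CENTER)
        xy = np.array([(p.x_mm - 18, p.y_mm - 18) for p in pos])
        assert np.allclose(
            xy, [(0, 0), (1.040, 0), (0, 0.740), (1.040, 0.740)], atol=1e-9
        )

    def test_consecutive_positions_differ_by_one_increment(self, plate6, profile_10x):
        pos = plan_well_scan(plate6, WellAddress(1, 1), profile_10x, 3, 3)
        diffs = np.array(
            [(b.x_mm - a.x_mm, b.y_mm - a.y_mm) for a, b in zip(pos, pos[1:])]
        )
        sx = profile_10x.step_increment_um[0] / 1000
        sy = profile_10x.step_increment_um[1] / 1000
        within_row = np.isclose(diffs[:, 0], sx) & np.isclose(diffs[:, 1], 0.0)
        row_wrap = np.isclose(diffs[:, 0], -2 * sx) & np.isclose(diffs[:, 1], sy)
        assert np.all(within_row | row_wrap)
        assert row_wrap.sum() == 2

    def test_bad_grid_rejected(self, plate6, profile_10x):
        with pytest.raises(ValueError):
            plan_well_scan(plate6, WellAddress(1, 1), profile_10x, 0, 2)


class TestPlateScanPlanning:
    def test_24_well_4x4_position_count(self, profile_10x):
        plate = PlateSpec(format=24, well_diameter=15.6, pitch_x=19.3,
                          pitch_y=19.3, a1_center=(20, 20))
        plan = plan_plate_scan(plate, profile_10x, 4, 4)
        assert len(plan) == 384

    def test_exclusion_skips_to_next_well(self, plate6, profile_10x):
        plan = plan_plate_scan(plate6, profile_10x, 2, 2, excluded=["A1"])
        assert plan.positions[0].well == "A2"
        assert "A1" not in plan.wells()

    def test_all_excluded_warns_empty(self, plate6, profile_10x):
        wells = [w.label for w in plate6.wells()]
        with pytest.warns(UserWarning, match="empty"):
            plan = plan_plate_scan(plate6, profile_10x, 2, 2, excluded=wells)
        assert len(plan) == 0

    def test_well_order_is_row_major(self, plate6, profile_10x):
        plan = plan_plate_scan(plate6, profile_10x, 1, 1)
        assert plan.wells() == ["A1", "A2", "A3", "B1", "B2", "B3"]

    def test_default_led_channel(self, plate6, profile_10x):
        assert plan_plate_scan(plate6, profile_10x, 1, 1).led_channel == "White 02"


class TestScheduler:
    def test_interval_longer_than_sweep(self):
        s = schedule_timelapse(3, 60.0, 32.8)
        assert s.start_times_min == (0.0, 60.0, 120.0)
        assert not s.back_to_back

    def test_back_to_back_when_interval_too_short(self):
        s = schedule_timelapse(3, 5.0, 7.2)
        assert s.start_times_min == pytest.approx((0.0, 7.2, 14.4))
        assert s.back_to_back

    def test_single_scan(self):
        assert schedule_timelapse(1, 60.0, 30.0).start_times_min == (0.0,)

    def test_duration_estimate_reproduces_published_sweep_times(self):
        # 24-well plate at 4x4 per well = 384 images
        assert estimate_scan_duration_min(384, "bmp") == pytest.approx(32.8)
        assert estimate_scan_duration_min(384, "jpeg") == pytest.approx(7.2)


class TestSaveImage:
    def test_bmp_default_resolution_byte_count(self, tmp_path):
        raster = np.zeros((1200, 1680, 3), dtype=np.uint8)
        n = save_image(raster, tmp_path / "frame.bmp", "bmp")
        assert n == 54 + 1680 * 3 * 1200  # header + unpadded rows (already x4)
        assert int(n / 1024 / 1024 * 100) / 100 == 5.76

    def test_jpeg_smaller_than_bmp(self, tmp_path):
        rng = np.random.default_rng(0)
        raster = rng.integers(0, 255, size=(300, 400), dtype=np.uint8)
        n_bmp = save_image(raster, tmp_path / "f.bmp", "bmp")
        n_jpg = save_image(raster, tmp_path / "f.jpg", "jpeg")
        assert n_jpg < n_bmp

    def test_row_padding_to_four_bytes(self, tmp_path):
        raster = np.zeros((10, 3, 3), dtype=np.uint8)  # 9-byte rows pad to 12
        n = save_image(raster, tmp_path / "f.bmp", "bmp")
        assert n == 54 + 12 * 10

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            save_image(np.zeros((4, 4), dtype=np.uint8), tmp_path / "f.tif", "TIFF")


class TestRunTimelapse:
    @pytest.fixture
    def tiny_rig(self, plate6, profile_10x):
        camera = CameraConfig(resolution=(120, 90), pixels_per_um=1.3, seed=0)
        specimen = build_specimen(
            "cells", n=150, window_mm=(120, 90), center_mm=(69, 47.5), seed=0
        )
        plan = plan_plate_scan(plate6, profile_10x, 2, 2)
        return camera, specimen, plan

    def test_file_and_manifest_counts(self, tiny_rig, tmp_path):
        camera, specimen, plan = tiny_rig
        schedule = schedule_timelapse(2, 1.0, 0.5)
        stage = VirtualStage(StageConfig(position_noise_sd=0.0))
        manifest = run_timelapse(stage, camera, specimen, plan, schedule, tmp_path)
        assert len(manifest) == 2 * len(plan) == 48
        assert len(list(Path(tmp_path).rglob("*.bmp"))) == 48
        assert set(manifest["well"]) == {"A1", "A2", "A3", "B1", "B2", "B3"}
        assert (tmp_path / "scan1" / "scan1_wellB3_x1_y1.bmp").exists()

    def test_excluded_wells_absent_from_manifest(self, plate6, profile_10x, tmp_path):
        camera = CameraConfig(resolution=(80, 60), pixels_per_um=1.3, seed=0)
        specimen = build_specimen("uniform")
        plan = plan_plate_scan(plate6, profile_10x, 1, 1, excluded=["B2"])
        schedule = schedule_timelapse(1, 60.0, 1.0)
        stage = VirtualStage(StageConfig(position_noise_sd=0.0))
        manifest = run_timelapse(stage, camera, specimen, plan, schedule, tmp_path)
        assert "B2" not in set(manifest["well"])

    def test_reruns_are_byte_identical(self, tiny_rig, tmp_path):
        camera, specimen, plan = tiny_rig
        schedule = schedule_timelapse(1, 60.0, 0.5)
        outputs = []
        for run in ("a", "b"):
            stage = VirtualStage(StageConfig(seed=4))
            run_timelapse(stage, camera, specimen, plan, schedule, tmp_path / run)
            outputs.append(
                sorted(p.read_bytes() for p in (tmp_path / run).rglob("*.bmp"))
            )
        assert outputs[0] == outputs[1]

    def test_autofocus_tracks_per_well_focal_planes(self, plate6, profile_10x,
                                                    tmp_path):
        camera = CameraConfig(resolution=(160, 120), pixels_per_um=1.3,
                              noise_sd=0.0, seed=0)
        # graticule texture exists everywhere, so every well has focusable
        # content regardless of its stage position
        specimens = {
            "*": build_specimen("graticule", spacing_um=20.0, focal_plane_z=0.2),
            "A2": build_specimen("graticule", spacing_um=20.0, focal_plane_z=0.6),
        }
        plan = plan_plate_scan(plate6, profile_10x, 1, 1)
        schedule = schedule_timelapse(1, 60.0, 1.0)
        stage = VirtualStage(StageConfig(position_noise_sd=0.0))
        manifest = run_timelapse(
            stage, camera, specimens, plan, schedule, tmp_path,
            autofocus_per_well=True, autofocus_range_mm=(-1.0, 1.0),
        )
        z = manifest.set_index("well")["z_mm"]
        assert z["A2"] - z["A1"] == pytest.approx(0.4, abs=0.2)

    def test_upload_hook_sees_every_file(self, tiny_rig, tmp_path):
        camera, specimen, plan = tiny_rig
        schedule = schedule_timelapse(1, 60.0, 0.5)
        stage = VirtualStage(StageConfig(position_noise_sd=0.0))
        seen = []
        run_timelapse(stage, camera, specimen, plan, schedule, tmp_path,
                      upload_hook=seen.append)
        assert len(seen) == len(plan)
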