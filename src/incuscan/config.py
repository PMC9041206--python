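"""YAML run configuration.

A run config collects everything a scan needs: the calibrated plate
geometry, the objective profile, the stage settings (firmware and, for the
virtual rig, true steps/mm), the camera model and the scan parameters.
Unknown keys are rejected with the offending dotted key named; omitted
optional fields take the documented defaults.  A minimal config needs only
``plate.format`` and ``objective.pixels_per_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .camera import CameraConfig
from .errors import ConfigError
from .motion import StageConfig
from .optics import ObjectiveProfile
from .plate import Anchor, PlateSpec

__all__ = ["ScanSettings", "RunConfig", "load_config", "save_config"]

#: nominal geometry (well diameter mm, pitch mm) used when a plate has not
#: been landmark-calibrated yet
NOMINAL_PLATE_GEOMETRY = {6: (34.8, 39.12), 24: (15.6, 19.3), 96: (6.4, 9.0)}

DEFAULT_A1_CENTER = (30.0, 30.0)


@dataclass(frozen=True)
class ScanSettings:
    """Per-run acquisition parameters."""

    nx: int = 4
    ny: int = 4
    excluded: tuple[str, ...] = ()
    start_anchor: str = Anchor.MIN_CORNER.value
    image_format: str = "bmp"
    n_scans: int = 1
    interval_min: float = 60.0
    led_channel: str = "White 02"

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be at least 1")
        Anchor(self.start_anchor)
        if self.image_format.lower() not in ("bmp", "jpeg", "jpg"):
            raise ValueError("image_format must be bmp or jpeg")
        if self.n_scans < 1 or self.interval_min < 0:
            raise ValueError("n_scans must be >= 1 and interval_min >= 0")


@dataclass(frozen=True)
class RunConfig:
    plate: PlateSpec
    objective: ObjectiveProfile
    stage: StageConfig = field(default_factory=StageConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    scan: ScanSettings = field(default_factory=ScanSettings)
    folder: str = "incuscan_run"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "plate": self.plate.to_dict(),
            "objective": self.objective.to_dict(),
            "stage": {
                "firmware_steps_per_mm": list(self.stage.firmware_steps_per_mm),
                "true_steps_per_mm": list(self.stage.true_steps_per_mm),
                "max_speed": self.stage.max_speed,
                "settle_time": list(self.stage.settle_time),
                "position_noise_sd": self.stage.position_noise_sd,
                "vibration_amplitude_um": self.stage.vibration_amplitude_um,
                "travel_limits": list(self.stage.travel_limits),
                "seed": self.stage.seed,
            },
            "camera": {
                "resolution": list(self.camera.resolution),
                "pixels_per_um": self.camera.pixels_per_um,
                "defocus_blur_per_mm": self.camera.defocus_blur_per_mm,
                "vibration_blur_gain": self.camera.vibration_blur_gain,
                "illumination": self.camera.illumination,
                "noise_sd": self.camera.noise_sd,
                "seed": self.camera.seed,
            },
            "scan": {
                "nx": self.scan.nx,
                "ny": self.scan.ny,
                "excluded": list(self.scan.excluded),
                "start_anchor": self.scan.start_anchor,
                "image_format": self.scan.image_format,
                "n_scans": self.scan.n_scans,
                "interval_min": self.scan.interval_min,
                "led_channel": self.scan.led_channel,
            },
            "folder": self.folder,
            "seed": self.seed,
        }


_SECTION_KEYS = {
    "plate": {"format", "well_diameter", "pitch_x", "pitch_y", "a1_center"},
    "objective": {"label", "pixels_per_um", "sensor_px", "overlap_factor"},
    "stage": {
        "firmware_steps_per_mm", "true_steps_per_mm", "max_speed", "settle_time",
        "position_noise_sd", "vibration_amplitude_um", "travel_limits", "seed",
    },
    "camera": {
        "resolution", "pixels_per_um", "defocus_blur_per_mm",
        "vibration_blur_gain", "illumination", "noise_sd", "seed",
    },
    "scan": {
        "nx", "ny", "excluded", "start_anchor", "image_format", "n_scans",
        "interval_min", "led_channel",
    },
}
_TOP_KEYS = set(_SECTION_KEYS) | {"folder", "seed"}


def _check_keys(section: str, data: dict) -> None:
    unknown = set(data) - _SECTION_KEYS[section]
    if unknown:
        raise ConfigError(
            f"unknown config key: {section}.{sorted(unknown)[0]}"
        )


def _build(section: str, builder, **kwargs):
    try:
        return builder(**kwargs)
    except (ValueError, TypeError, KeyError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key: {sorted(unknown)[0]}")

    plate_raw = dict(raw.get("plate") or {})
    _check_keys("plate", plate_raw)
    if "format" not in plate_raw:
        raise ConfigError("plate.format is required")
    fmt = int(plate_raw["format"])
    if fmt not in NOMINAL_PLATE_GEOMETRY:
        raise ConfigError(f"plate.format: unsupported plate format {fmt}")
    nominal_d, nominal_pitch = NOMINAL_PLATE_GEOMETRY[fmt]
    plate = _build(
        "plate",
        PlateSpec,
        format=fmt,
        well_diameter=float(plate_raw.get("well_diameter", nominal_d)),
        pitch_x=float(plate_raw.get("pitch_x", nominal_pitch)),
        pitch_y=float(plate_raw.get("pitch_y", nominal_pitch)),
        a1_center=tuple(plate_raw.get("a1_center", DEFAULT_A1_CENTER)),
    )

    obj_raw = dict(raw.get("objective") or {})
    _check_keys("objective", obj_raw)
    if "pixels_per_um" not in obj_raw:
        raise ConfigError("objective.pixels_per_um is required")
    objective = _build(
        "objective",
        ObjectiveProfile,
        label=str(obj_raw.get("label", "10X")),
        pixels_per_um=float(obj_raw["pixels_per_um"]),
        sensor_px=tuple(obj_raw.get("sensor_px", (1680, 1200))),
        overlap_factor=float(obj_raw.get("overlap_factor", 0.8)),
    )

    stage_raw = dict(raw.get("stage") or {})
    _check_keys("stage", stage_raw)
    if "travel_limits" in stage_raw:
        stage_raw["travel_limits"] = tuple(stage_raw["travel_limits"])
    stage = _build("stage", StageConfig, **stage_raw)

    cam_raw = dict(raw.get("camera") or {})
    _check_keys("camera", cam_raw)
    if "resolution" in cam_raw:
        cam_raw["resolution"] = tuple(cam_raw["resolution"])
    camera = _build("camera", CameraConfig, **cam_raw)

    scan_raw = dict(raw.get("scan") or {})
    _check_keys("scan", scan_raw)
    if "excluded" in scan_raw:
        scan_raw["excluded"] = tuple(scan_raw["excluded"])
    scan = _build("scan", ScanSettings, **scan_raw)

    return RunConfig(
        plate=plate,
        objective=objective,
        stage=stage,
        camera=camera,
        scan=scan,
        folder=str(raw.get("folder", "incuscan_run")),
        seed=int(raw.get("seed", 0)),
    )


def save_config(config: RunConfig, path) -> None:
    """Serialize a config back to YAML (inverse of :func:`load_config`)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
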