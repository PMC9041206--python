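"""Scan planning, time-lapse scheduling and acquisition runs.

A scan visits every non-excluded well in row-major order (A1, A2, ... B1,
B2, ...) and images an nx x ny grid inside each well, stepping by the
objective's overlap-adjusted increments (FOV x 0.8 by default, leaving 20%
overlap between neighbouring tiles for stitching).  Time-lapse runs repeat
the sweep at a fixed start-to-start interval; if the interval is shorter
than one sweep, scans run back to back and the schedule flags it.

Images are written as uncompressed 24-bit BMP (54-byte header, bottom-up
rows, 4-byte row padding — a default-resolution 1680x1200 frame is
6,048,054 bytes) or JPEG at quality 95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .autofocus import autofocus_sweep
from .camera import CameraConfig, SpecimenModel, render_frame
from .motion import VirtualStage
from .optics import ObjectiveProfile
from .plate import Anchor, PlateSpec, WellAddress, well_position

__all__ = [
    "GridPosition",
    "ScanPlan",
    "Schedule",
    "plan_well_scan",
    "plan_plate_scan",
    "schedule_timelapse",
    "estimate_scan_duration_min",
    "save_image",
    "run_timelapse",
]

#: per-image acquisition cost (seconds) by format; set so a 24-well plate at
#: 4x4 images per well (384 images) takes 32.8 min in BMP and 7.2 in JPEG
PER_IMAGE_COST_S = {"bmp": 5.125, "jpeg": 1.125}

DEFAULT_LED_CHANNEL = "White 02"


@dataclass(frozen=True)
class GridPosition:
    """One acquisition position: well, grid indices and stage XY (mm)."""

    well: str
    i: int  # grid column (X)
    j: int  # grid row (Y)
    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class ScanPlan:
    """Ordered acquisition positions for one sweep of the plate."""

    positions: tuple[GridPosition, ...]
    nx: int
    ny: int
    excluded_wells: frozenset[str] = frozenset()
    start_anchor: Anchor = Anchor.MIN_CORNER
    led_channel: str = DEFAULT_LED_CHANNEL

    def __len__(self) -> int:
        return len(self.positions)

    def wells(self) -> list[str]:
        seen: list[str] = []
        for p in self.positions:
            if p.well not in seen:
                seen.append(p.well)
        return seen


@dataclass(frozen=True)
class Schedule:
    """Time-lapse start times (minutes) for ``n_scans`` sweeps."""

    n_scans: int
    interval_min: float
    estimated_scan_duration_min: float
    start_times_min: tuple[float, ...] = field(init=False)
    back_to_back: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be at least 1")
        if self.interval_min < 0:
            raise ValueError("interval must be non-negative")
        back_to_back = self.interval_min < self.estimated_scan_duration_min
        step = (
            self.estimated_scan_duration_min if back_to_back else self.interval_min
        )
        object.__setattr__(
            self,
            "start_times_min",
            tuple(round(k * step, 9) for k in range(self.n_scans)),
        )
        object.__setattr__(self, "back_to_back", back_to_back)


def plan_well_scan(
    plate: PlateSpec,
    well: WellAddress,
    profile: ObjectiveProfile,
    nx: int,
    ny: int,
    start_anchor: Anchor = Anchor.MIN_CORNER,
) -> list[GridPosition]:
    """nx x ny grid of stage positions covering one well.

    The grid starts at the anchor (by default the minimum-X/Y corner of the
    well's bounding square, i.e. just outside the well) and steps by the
    objective's overlap-adjusted increments, row-major with X varying
    fastest.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be at least 1")
    ax, ay = well_position(plate, well, start_anchor)
    step_x = profile.step_increment_um[0] / 1000.0
    step_y = profile.step_increment_um[1] / 1000.0
    return [
        GridPosition(
            well=well.label, i=i, j=j, x_mm=ax + i * step_x, y_mm=ay + j * step_y
        )
        for j in range(ny)
        for i in range(nx)
    ]


def plan_plate_scan(
    plate: PlateSpec,
    profile: ObjectiveProfile,
    nx: int,
    ny: int,
    excluded: Iterable[str] = (),
    start_anchor: Anchor = Anchor.MIN_CORNER,
    led_channel: str = DEFAULT_LED_CHANNEL,
) -> ScanPlan:
    """Whole-plate plan: wells row-major A1, A2, ... skipping exclusions."""
    excluded = frozenset(WellAddress.from_label(w).label for w in excluded)
    all_labels = {w.label for w in plate.wells()}
    unknown = excluded - all_labels
    if unknown:
        raise ValueError(f"excluded wells not on this plate: {sorted(unknown)}")
    positions: list[GridPosition] = []
    for well in plate.wells():
        if well.label in excluded:
            continue
        positions.extend(plan_well_scan(plate, well, profile, nx, ny, start_anchor))
    if not positions:
        warnings.warn("all wells excluded: empty scan plan", stacklevel=2)
    return ScanPlan(
        positions=tuple(positions),
        nx=nx,
        ny=ny,
        excluded_wells=excluded,
        start_anchor=start_anchor,
        led_channel=led_channel,
    )


def estimate_scan_duration_min(n_positions: int, image_format: str = "bmp") -> float:
    """Sweep duration estimate from the per-image acquisition cost."""
    fmt = image_format.lower()
    if fmt not in PER_IMAGE_COST_S:
        raise ValueError(f"unknown image format: {image_format!r}")
    return n_positions * PER_IMAGE_COST_S[fmt] / 60.0


def schedule_timelapse(
    n_scans: int, interval_min: float, estimated_scan_duration_min: float
) -> Schedule:
    """Start times for a time-lapse (start-to-start interval semantics).

    When the interval is at least the sweep duration, starts are exact
    multiples of the interval; otherwise scans run back to back (starts at
    multiples of the duration) and ``back_to_back`` is flagged so the caller
    knows the requested cadence cannot be honoured.
    """
    return Schedule(
        n_scans=n_scans,
        interval_min=interval_min,
        estimated_scan_duration_min=estimated_scan_duration_min,
    )


def save_image(raster: np.ndarray, path, image_format: str = "bmp") -> int:
    """Write a raster as 24-bit BMP or quality-95 JPEG; returns bytes written.

    Single-channel input is replicated to three channels so BMP files always
    use the 24-bit uncompressed dialect (row size padded to 4 bytes,
    bottom-up, BITMAPINFOHEADER).
    """
    arr = np.asarray(raster)
    if arr.size == 0:
        raise ValueError("cannot save an empty raster")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(float)), 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("raster must be HxW or HxWx3")
    fmt = image_format.lower()
    path = Path(path)
    img = Image.fromarray(arr, mode="RGB")
    if fmt == "bmp":
        img.save(path, format="BMP")
    elif fmt in ("jpeg", "jpg"):
        img.save(path, format="JPEG", quality=95)
    else:
        raise ValueError(f"unknown image format: {image_format!r}")
    return path.stat().st_size


def run_timelapse(
    stage: VirtualStage,
    camera: CameraConfig,
    specimen: SpecimenModel | Mapping[str, SpecimenModel],
    plan: ScanPlan,
    schedule: Schedule,
    folder,
    image_format: str = "bmp",
    autofocus_per_well: bool = False,
    autofocus_range_mm: tuple[float, float] = (-1.0, 1.0),
    autofocus_step_mm: float = 0.2,
    upload_hook: Callable[[Path], None] | None = None,
) -> pd.DataFrame:
    """Execute a full simulated time-lapse and return the manifest.

    For every scheduled sweep, every planned position is visited in order:
    move, settle, (optionally autofocus once per well over
    ``autofocus_range_mm``), render, save as
    ``<folder>/scan{S}/scan{S}_well{W}_x{i}_y{j}.{ext}``.  ``specimen`` may
    be a single model or a per-well-label mapping (wells not in the mapping
    fall back to the ``"*"`` entry).  The manifest records scan index, well,
    grid indices, stage pose, focus Z, file and the simulated timestamp.
    Scan starts follow the schedule on the stage's simulated clock.
    """
    if len(plan) == 0:
        raise ValueError("cannot run an empty scan plan")
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    ext = "jpg" if image_format.lower() in ("jpeg", "jpg") else image_format.lower()

    def specimen_for(well: str) -> SpecimenModel:
        if isinstance(specimen, SpecimenModel):
            return specimen
        return specimen.get(well) or specimen["*"]

    rows = []
    for s, start_min in enumerate(schedule.start_times_min):
        scan_dir = folder / f"scan{s}"
        scan_dir.mkdir(exist_ok=True)
        if stage.time < start_min * 60.0:
            stage.wait(start_min * 60.0 - stage.time)
        current_well = None
        for pos in plan.positions:
            stage.move_absolute(x=pos.x_mm, y=pos.y_mm)
            stage.settle(axes=("x", "y"))
            spec = specimen_for(pos.well)
            if autofocus_per_well and pos.well != current_well:
                autofocus_sweep(
                    stage,
                    camera,
                    spec,
                    z_min=autofocus_range_mm[0],
                    z_max=autofocus_range_mm[1],
                    z_step=autofocus_step_mm,
                )
            current_well = pos.well
            frame = render_frame(spec, camera, stage.pose)
            name = f"scan{s}_well{pos.well}_x{pos.i}_y{pos.j}.{ext}"
            file_path = scan_dir / name
            save_image(frame, file_path, image_format)
            if upload_hook is not None:
                upload_hook(file_path)
            pose = stage.pose
            rows.append(
                {
                    "scan": s,
                    "well": pos.well,
                    "i": pos.i,
                    "j": pos.j,
                    "x_mm": pose.x,
                    "y_mm": pose.y,
                    "z_mm": pose.z,
                    "file": str(file_path.relative_to(folder)),
                    "time_s": pose.time,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(folder / "manifest.csv", index=False)
    return manifest
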