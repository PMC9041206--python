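"""Motion-fidelity validation of the stage.

The workflow mirrors how a scanning stage is commissioned: command moves of
0.1–1.0 mm in 0.1 mm increments along X and Y, in both directions, ten
times each, imaging before and after every move (800 images for the default
protocol).  The pixel translation between each image pair is measured by
sub-pixel phase correlation, converted to mm with the pixel scale, and the
median observed motion per (axis, distance) is compared with the command:

* distances up to 1.0 mm pass when the median deviates by at most 5%;
* larger distances pass when the median absolute error is at most 13 µm;
* when any distance fails, the corrected firmware steps-per-mm is
  ``current x commanded / observed`` (an under-moving axis gets more steps
  per mm), which for a pure steps/mm miscalibration recovers the true value
  in a single cycle.

The module also covers stationary-drift analysis (deviation of a landmark
over a long unattended period, with an OLS trend test) and the minimum
rest-time determination (sharpness versus post-move delay, first delay at
95% of the plateau).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.registration import phase_cross_correlation

from .autofocus import SharpnessProfile, sharpness_score
from .camera import CameraConfig, SpecimenModel, render_frame
from .errors import LowConfidenceError
from .motion import AXES, StageConfig, VirtualStage

__all__ = [
    "MotionTrial",
    "TranslationEstimate",
    "ValidationSummary",
    "StabilityResult",
    "RestTimeResult",
    "build_motion_protocol",
    "run_motion_protocol",
    "measure_motion",
    "estimate_translation",
    "summarize_motion_fidelity",
    "apply_steps_correction",
    "stationary_stability_analysis",
    "rest_time_analysis",
]

DEFAULT_DISTANCES = tuple(round(0.1 * k, 1) for k in range(1, 11))
PERCENT_TOLERANCE = 5.0  # % deviation allowed for distances <= 1 mm
ABSOLUTE_TOLERANCE_UM = 13.0  # µm median error allowed beyond 1 mm


@dataclass(frozen=True)
class MotionTrial:
    """One commanded move: axis, signed direction, distance and repeat."""

    axis: str  # "x" or "y"
    direction: int  # +1 or -1
    distance: float  # mm, > 0
    repeat: int  # 1-based

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.repeat < 1:
            raise ValueError("repeat is 1-based")

    def filename(self, phase: str, ext: str = "bmp") -> str:
        """e.g. ``X_pos_0.300_r02_start.bmp``."""
        sign = "pos" if self.direction > 0 else "neg"
        return (
            f"{self.axis.upper()}_{sign}_{self.distance:.3f}_"
            f"r{self.repeat:02d}_{phase}.{ext}"
        )


@dataclass(frozen=True)
class TranslationEstimate:
    """Sub-pixel content displacement from image A to image B."""

    dx: float  # px, along image X
    dy: float  # px, along image Y
    confidence: float  # phase-correlation peak height, 1 for a pure shift


def build_motion_protocol(
    distances=DEFAULT_DISTANCES,
    axes=("x", "y"),
    directions=(1, -1),
    repeats: int = 10,
) -> list[MotionTrial]:
    """Full-factorial list of motion trials.

    Defaults (10 distances x 2 axes x 2 directions x 10 repeats) give 400
    trials and therefore 800 saved images.
    """
    distances = tuple(distances)
    if not distances:
        raise ValueError("distances must be non-empty")
    if any(d <= 0 for d in distances):
        raise ValueError("distances must be positive")
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    return [
        MotionTrial(axis=a, direction=s, distance=float(d), repeat=r)
        for a in axes
        for s in directions
        for d in distances
        for r in range(1, repeats + 1)
    ]


def _capture_pair(stage, camera, specimen, trial, return_home=True):
    """Start image, signed move, settle, end image (optional return move)."""
    start = render_frame(specimen, camera, stage.pose)
    delta = trial.direction * trial.distance
    stage.move_relative(**{f"d{trial.axis}": delta})
    stage.settle(axes=(trial.axis,))
    end = render_frame(specimen, camera, stage.pose)
    if return_home:
        stage.move_relative(**{f"d{trial.axis}": -delta})
        stage.settle(axes=(trial.axis,))
    return start, end


def run_motion_protocol(
    stage: VirtualStage,
    camera: CameraConfig,
    specimen: SpecimenModel,
    trials: list[MotionTrial],
    folder,
    image_format: str = "bmp",
    return_home: bool = True,
) -> pd.DataFrame:
    """Execute the trials on the virtual rig, saving every image pair.

    Each trial captures a start image, performs the signed move, waits the
    axis settle time, and captures the end image; with ``return_home`` the
    stage then retraces the move so the texture stays in the field of view
    for the whole protocol.  Returns the manifest (one row per image file,
    i.e. 2 x len(trials) rows), also written to ``manifest.csv``.
    """
    from .runtime import save_image  # local import to avoid a cycle

    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        start, end = _capture_pair(stage, camera, specimen, trial, return_home)
        for phase, img in (("start", start), ("end", end)):
            name = trial.filename(phase, image_format)
            save_image(img, folder / name, image_format)
            rows.append(
                {
                    "axis": trial.axis,
                    "direction": trial.direction,
                    "distance_mm": trial.distance,
                    "repeat": trial.repeat,
                    "phase": phase,
                    "file": name,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(folder / "manifest.csv", index=False)
    return manifest


def measure_motion(
    stage: VirtualStage,
    camera: CameraConfig,
    specimen: SpecimenModel,
    trials: list[MotionTrial],
    return_home: bool = True,
) -> pd.DataFrame:
    """Run the trials in memory and measure each pair's translation.

    Same acquisition loop as :func:`run_motion_protocol` but without disk
    I/O; returns one row per trial with the measured pixel shift.
    """
    rows = []
    for trial in trials:
        start, end = _capture_pair(stage, camera, specimen, trial, return_home)
        est = estimate_translation(start, end)
        rows.append(
            {
                "axis": trial.axis,
                "direction": trial.direction,
                "distance_mm": trial.distance,
                "repeat": trial.repeat,
                "dx_px": est.dx,
                "dy_px": est.dy,
                "confidence": est.confidence,
            }
        )
    return pd.DataFrame(rows)


def measure_saved_protocol(folder, manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Measure translations from a folder produced by :func:`run_motion_protocol`."""
    from imageio.v3 import imread

    folder = Path(folder)
    if manifest is None:
        manifest = pd.read_csv(folder / "manifest.csv")
    rows = []
    keys = ["axis", "direction", "distance_mm", "repeat"]
    for key, pair in manifest.groupby(keys, sort=False):
        files = dict(zip(pair["phase"], pair["file"]))
        a = np.asarray(imread(folder / files["start"]))
        b = np.asarray(imread(folder / files["end"]))
        if a.ndim == 3:
            a, b = a.mean(axis=2), b.mean(axis=2)
        est = estimate_translation(a, b)
        rows.append(dict(zip(keys, key)) | {
            "dx_px": est.dx, "dy_px": est.dy, "confidence": est.confidence,
        })
    return pd.DataFrame(rows)


def estimate_translation(
    image_a: np.ndarray,
    image_b: np.ndarray,
    upsample_factor: int = 10,
    confidence_threshold: float | None = None,
) -> TranslationEstimate:
    """Sub-pixel translation of content from image A to image B.

    Phase correlation with 10x upsampled peak refinement.  Confidence is the
    height of the normalized phase-correlation peak (1 for a pure cyclic
    shift, near 0 for unrelated images); estimates below
    ``confidence_threshold`` raise :class:`LowConfidenceError`.  The default
    threshold adapts to the image area as ``10 / sqrt(N)``, roughly twice
    the peak height two unrelated noise images produce.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if confidence_threshold is None:
        confidence_threshold = 10.0 / math.sqrt(a.size)

    # normalized cross-power peak as a match confidence
    fa, fb = np.fft.fft2(a - a.mean()), np.fft.fft2(b - b.mean())
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    surface = np.abs(np.fft.ifft2(cross / mag))
    confidence = float(surface.max())
    if confidence < confidence_threshold:
        raise LowConfidenceError(
            f"phase-correlation peak {confidence:.3f} below "
            f"{confidence_threshold}: images do not share content"
        )

    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample_factor)
    # skimage returns the (row, col) shift registering B onto A; content
    # displacement A -> B is its negation, reported as (dx, dy).
    return TranslationEstimate(
        dx=float(-shift[1]), dy=float(-shift[0]), confidence=confidence
    )


@dataclass(frozen=True)
class ValidationSummary:
    """Per-(axis, distance) motion fidelity plus corrective settings.

    ``per_distance`` has columns axis, distance_mm, commanded_mm,
    observed_mm (median over directions and repeats), percent_deviation and
    passed.  ``recommended_steps_per_mm`` equals the current setting for
    axes where every distance passed.
    """

    per_distance: pd.DataFrame
    current_steps_per_mm: dict[str, float]
    recommended_steps_per_mm: dict[str, float]

    @property
    def all_pass(self) -> bool:
        return bool(self.per_distance["passed"].all())

    def failed_axes(self) -> list[str]:
        f = self.per_distance[~self.per_distance["passed"]]
        return sorted(f["axis"].unique())

    def to_text(self) -> str:
        lines = ["Motion fidelity summary", "=" * 23]
        for _, row in self.per_distance.iterrows():
            lines.append(
                f"{row['axis'].upper()} {row['commanded_mm']:6.3f} mm -> "
                f"{row['observed_mm']:7.4f} mm "
                f"({row['percent_deviation']:+6.2f}%)  "
                f"{'PASS' if row['passed'] else 'FAIL'}"
            )
        for axis, rec in self.recommended_steps_per_mm.items():
            cur = self.current_steps_per_mm[axis]
            verdict = "unchanged" if math.isclose(rec, cur) else f"adjust to {rec:.3f}"
            lines.append(f"{axis.upper()} steps/mm: current {cur:.3f}, {verdict}")
        return "\n".join(lines)


def summarize_motion_fidelity(
    measurements: pd.DataFrame,
    pixels_per_um: float,
    current_steps_per_mm: dict[str, float],
) -> ValidationSummary:
    """Apply the 5%/13 µm acceptance rule and derive corrected steps/mm.

    ``measurements`` needs columns axis, distance_mm, dx_px, dy_px (one row
    per trial).  Observed motion per trial is the absolute pixel shift along
    the commanded axis divided by the pixel scale; medians pool directions
    and repeats.  When any distance on an axis fails, the recommendation is
    ``current x commanded/observed`` with the ratio taken as the median of
    the per-distance observed/commanded ratios.
    """
    if pixels_per_um is None or pixels_per_um <= 0:
        raise ValueError("a positive pixels_per_um scale is required")
    required = {"axis", "distance_mm", "dx_px", "dy_px"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")

    df = measurements.copy()
    shift_px = np.where(df["axis"] == "x", df["dx_px"], df["dy_px"])
    df["observed_mm"] = np.abs(shift_px) / pixels_per_um / 1000.0

    rows = []
    ratios: dict[str, list[float]] = {}
    for (axis, dist), grp in df.groupby(["axis", "distance_mm"]):
        observed = float(grp["observed_mm"].median())
        deviation_pct = (observed - dist) / dist * 100.0
        if dist <= 1.0:
            passed = abs(deviation_pct) <= PERCENT_TOLERANCE
        else:
            passed = abs(observed - dist) * 1000.0 <= ABSOLUTE_TOLERANCE_UM
        rows.append(
            {
                "axis": axis,
                "distance_mm": dist,
                "commanded_mm": dist,
                "observed_mm": observed,
                "percent_deviation": deviation_pct,
                "passed": passed,
            }
        )
        ratios.setdefault(axis, []).append(observed / dist)

    table = pd.DataFrame(rows).sort_values(["axis", "distance_mm"]).reset_index(drop=True)
    recommended = {}
    for axis, ratio_list in ratios.items():
        if axis not in current_steps_per_mm:
            raise ValueError(f"no current steps/mm given for axis {axis!r}")
        axis_failed = bool((~table.loc[table["axis"] == axis, "passed"]).any())
        ratio = float(np.median(ratio_list))
        current = float(current_steps_per_mm[axis])
        recommended[axis] = current / ratio if axis_failed else current
    return ValidationSummary(
        per_distance=table,
        current_steps_per_mm={a: float(v) for a, v in current_steps_per_mm.items()},
        recommended_steps_per_mm=recommended,
    )


def apply_steps_correction(
    config: StageConfig, summary: ValidationSummary
) -> StageConfig:
    """New stage config with the summary's recommended firmware steps/mm."""
    steps = list(config.firmware_steps_per_mm)
    for axis, value in summary.recommended_steps_per_mm.items():
        steps[AXES.index(axis)] = value
    return replace(config, firmware_steps_per_mm=tuple(steps))


@dataclass(frozen=True)
class StabilityResult:
    """Stationary-drift analysis of a landmark position over time."""

    deviations_um: np.ndarray  # (N, 2): deviation from the first sample
    max_deviation_um: tuple[float, float]
    slope_um_per_min: tuple[float, float]
    p_value: tuple[float, float]

    def drift_detected(self, alpha: float = 0.05) -> tuple[bool, bool]:
        return tuple(p <= alpha for p in self.p_value)

    @property
    def verdict(self) -> str:
        return (
            "no persistent drift"
            if not any(self.drift_detected())
            else "persistent drift detected"
        )


def stationary_stability_analysis(
    positions_um: np.ndarray, interval_s: float = 60.0
) -> StabilityResult:
    """Drift statistics from an XY landmark tracked at fixed intervals.

    Deviations are relative to the first sample.  Each axis gets an OLS
    regression of deviation on time; a two-sided trend p-value above 0.05
    means no evidence of persistent drift (random jitter only).
    """
    pos = np.asarray(positions_um, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must be an (N, 2) array of XY in µm")
    if pos.shape[0] < 3:
        raise ValueError("need at least 3 samples for a trend test")
    dev = pos - pos[0]
    t_min = np.arange(pos.shape[0]) * interval_s / 60.0
    slopes, pvals = [], []
    for axis in range(2):
        res = stats.linregress(t_min, dev[:, axis])
        slopes.append(float(res.slope))
        pvals.append(float(res.pvalue) if np.isfinite(res.pvalue) else 1.0)
    return StabilityResult(
        deviations_um=dev,
        max_deviation_um=tuple(float(v) for v in np.abs(dev).max(axis=0)),
        slope_um_per_min=tuple(slopes),
        p_value=tuple(pvals),
    )


@dataclass(frozen=True)
class RestTimeResult:
    """Minimum post-move delay before imaging, with the sharpness profile."""

    min_delay_s: float
    profile: SharpnessProfile
    stabilized: bool


def rest_time_analysis(
    stage: VirtualStage,
    camera: CameraConfig,
    specimen: SpecimenModel,
    axis: str = "x",
    sample_interval: float = 0.1,
    duration: float = 2.0,
    move_mm: float = 1.0,
    gaussian_radius: float = 1.0,
    plateau_fraction: float = 0.95,
) -> RestTimeResult:
    """Find the shortest settle delay after a move on one axis.

    Commands a 1 mm move, then images at ``sample_interval`` steps over
    ``duration`` seconds; sharpness recovers as the residual vibration
    decays.  The plateau is the median of the last five samples and the
    result is the first delay whose score reaches ``plateau_fraction`` of
    it.  If the score never stabilizes a warning is issued and ``duration``
    returned.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if duration <= sample_interval:
        raise ValueError("duration must exceed the sample interval")
    stage.move_relative(**{f"d{axis}": move_mm})
    t0 = stage.time
    delays = np.round(np.arange(0.0, duration + sample_interval / 2.0, sample_interval), 9)
    scores = []
    for d in delays:
        stage.time = t0 + float(d)
        frame = render_frame(specimen, camera, stage.pose)
        scores.append(sharpness_score(frame, gaussian_radius))
    scores = np.asarray(scores)
    profile = SharpnessProfile(z_values=delays, scores=scores)
    plateau = float(np.median(scores[-5:]))
    ok = np.nonzero(scores >= plateau_fraction * plateau)[0]
    if ok.size == 0:
        warnings.warn("sharpness never stabilized within the sampled window",
                      stacklevel=2)
        return RestTimeResult(min_delay_s=duration, profile=profile, stabilized=False)
    return RestTimeResult(
        min_delay_s=float(delays[ok[0]]), profile=profile, stabilized=True
    )
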