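"""Virtual microscope camera.

Renders synthetic frames at a given stage pose from a world-coordinate
specimen so that calibration, autofocus and motion-validation workflows can
run closed-loop without hardware.  The image model is:

1. an ideal, noise-free intensity pattern sampled at the pixel grid
   (world point ``(u, v)`` µm maps to pixel
   ``((u - x*1000)*scale + W/2, (v - y*1000)*scale + H/2)``, so driving the
   stage in +X shifts specimen content left in the image);
2. Gaussian defocus blur, sigma = ``defocus_blur_per_mm * |z - focal_plane_z|``;
3. Gaussian vibration blur, sigma = ``vibration_blur_gain *`` the stage's
   residual vibration amplitude (µm) at capture time;
4. an optional oblique-illumination gradient (x0.7 at the left edge to x1.0
   at the right);
5. additive Gaussian sensor noise, seeded deterministically from the camera
   seed and the pose so identical captures are byte-identical.

Output is a single-channel 8-bit raster (H x W).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np
from scipy import ndimage

from .motion import StagePose

__all__ = [
    "SpecimenKind",
    "SpecimenModel",
    "CameraConfig",
    "build_specimen",
    "render_frame",
]

MAX_RESOLUTION = (3280, 2464)


class SpecimenKind(str, Enum):
    CELLS = "cells"
    GRATICULE = "graticule"
    USAF_BARS = "usaf_bars"
    SLANT_EDGE = "slant_edge"
    UNIFORM = "uniform"


@dataclass(frozen=True)
class SpecimenModel:
    """A world-coordinate specimen: what exists on the (virtual) slide.

    ``objects`` is an (N, 4) array of blob parameters (x_um, y_um, sigma_um,
    amplitude) for the ``cells`` kind; other kinds are procedural and keep
    their parameters in ``params``.  ``focal_plane_z`` is the stage Z (mm)
    at which the specimen is in focus.
    """

    kind: SpecimenKind
    params: dict[str, Any] = field(default_factory=dict)
    objects: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    focal_plane_z: float = 0.0
    background: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.objects)):
            raise ValueError("specimen object coordinates must be finite")


@dataclass(frozen=True)
class CameraConfig:
    """Sensor geometry, optical gains and noise of the virtual camera."""

    resolution: tuple[int, int] = (1680, 1200)  # (width, height) px
    pixels_per_um: float = 1.292  # 1680 px across a 1300 µm field
    defocus_blur_per_mm: float = 25.0  # px of Gaussian sigma per mm off focus
    vibration_blur_gain: float = 0.5  # px of sigma per µm of amplitude
    illumination: str = "flat"  # or "oblique_gradient"
    noise_sd: float = 2.0  # 8-bit intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution[0] > MAX_RESOLUTION[0] or self.resolution[1] > MAX_RESOLUTION[1]:
            raise ValueError(f"resolution exceeds sensor maximum {MAX_RESOLUTION}")
        if min(self.resolution) <= 0 or self.pixels_per_um <= 0:
            raise ValueError("resolution and pixel scale must be positive")
        if self.defocus_blur_per_mm < 0 or self.vibration_blur_gain < 0 or self.noise_sd < 0:
            raise ValueError("gains must be non-negative")
        if self.illumination not in ("flat", "oblique_gradient"):
            raise ValueError("illumination must be 'flat' or 'oblique_gradient'")


def build_specimen(kind: SpecimenKind | str, seed: int = 0, **params) -> SpecimenModel:
    """Construct a specimen of the given kind; deterministic for a seed.

    Parameters by kind:

    cells
        ``n`` blobs (default 50) scattered without overlap in a rectangular
        world window of ``window_mm`` (default 5x5 mm) centred on
        ``center_mm`` (default the origin).  Blob sigma is drawn uniformly
        from ``size_um`` (default (3, 8) µm), amplitude from
        ``intensity`` (default (120, 180)).
    graticule
        parallel bright lines every ``spacing_um`` µm along world X,
        ``linewidth_um`` wide (default 2).
    usaf_bars
        a three-bar vertical triplet of ``lp_per_mm`` line pairs per mm
        centred at the origin.
    slant_edge
        a bright half-plane whose boundary is tilted ``angle_deg`` (default
        5) from the image-vertical, passing through the world origin.
    uniform
        background only.
    """
    kind = SpecimenKind(kind)
    focal_plane_z = float(params.pop("focal_plane_z", 0.0))
    background = float(params.pop("background", 40.0))
    rng = np.random.default_rng(seed)

    if kind is SpecimenKind.CELLS:
        n = int(params.pop("n", 50))
        window_mm = params.pop("window_mm", (5.0, 5.0))
        center_mm = params.pop("center_mm", (0.0, 0.0))
        size_um = params.pop("size_um", (3.0, 8.0))
        intensity = params.pop("intensity", (120.0, 180.0))
        _reject_unknown(params, kind)
        half_w = window_mm[0] * 500.0  # mm -> µm half-extent
        half_h = window_mm[1] * 500.0
        cx, cy = center_mm[0] * 1000.0, center_mm[1] * 1000.0
        objects = np.zeros((n, 4))
        placed = 0
        attempts = 0
        while placed < n and attempts < 200 * max(n, 1):
            attempts += 1
            x = rng.uniform(cx - half_w, cx + half_w)
            y = rng.uniform(cy - half_h, cy + half_h)
            s = rng.uniform(*size_um)
            if placed:
                d = np.hypot(objects[:placed, 0] - x, objects[:placed, 1] - y)
                if np.any(d < 3.0 * (objects[:placed, 2] + s)):
                    continue
            objects[placed] = (x, y, s, rng.uniform(*intensity))
            placed += 1
        return SpecimenModel(
            kind=kind,
            objects=objects[:placed],
            params={"window_mm": tuple(window_mm), "center_mm": tuple(center_mm)},
            focal_plane_z=focal_plane_z,
            background=background,
            seed=seed,
        )

    if kind is SpecimenKind.GRATICULE:
        p = {
            "spacing_um": float(params.pop("spacing_um", 10.0)),
            "linewidth_um": float(params.pop("linewidth_um", 2.0)),
            "amplitude": float(params.pop("amplitude", 160.0)),
        }
        if p["spacing_um"] <= 0:
            raise ValueError("graticule spacing must be positive")
        _reject_unknown(params, kind)
        return SpecimenModel(kind=kind, params=p, focal_plane_z=focal_plane_z,
                             background=background, seed=seed)

    if kind is SpecimenKind.USAF_BARS:
        p = {
            "lp_per_mm": float(params.pop("lp_per_mm", 228.1)),
            "amplitude": float(params.pop("amplitude", 180.0)),
        }
        if p["lp_per_mm"] <= 0:
            raise ValueError("line density must be positive")
        _reject_unknown(params, kind)
        return SpecimenModel(kind=kind, params=p, focal_plane_z=focal_plane_z,
                             background=background, seed=seed)

    if kind is SpecimenKind.SLANT_EDGE:
        p = {
            "angle_deg": float(params.pop("angle_deg", 5.0)),
            "amplitude": float(params.pop("amplitude", 180.0)),
        }
        _reject_unknown(params, kind)
        return SpecimenModel(kind=kind, params=p, focal_plane_z=focal_plane_z,
                             background=background, seed=seed)

    if kind is SpecimenKind.UNIFORM:
        _reject_unknown(params, kind)
        return SpecimenModel(kind=kind, focal_plane_z=focal_plane_z,
                             background=background, seed=seed)

    raise ValueError(f"unknown specimen kind: {kind}")


def _reject_unknown(params: dict, kind: SpecimenKind) -> None:
    if params:
        raise ValueError(f"unknown parameters for {kind.value}: {sorted(params)}")


def _ideal_image(
    specimen: SpecimenModel, camera: CameraConfig, pose: StagePose
) -> np.ndarray:
    """Noise- and blur-free pattern sampled at the pixel grid (float)."""
    w, h = camera.resolution
    scale = camera.pixels_per_um
    # world µm coordinate of each pixel column/row
    u = (np.arange(w) - w / 2.0) / scale + pose.x * 1000.0
    v = (np.arange(h) - h / 2.0) / scale + pose.y * 1000.0
    img = np.full((h, w), specimen.background, dtype=float)

    if specimen.kind is SpecimenKind.CELLS:
        for x0, y0, sigma, amp in specimen.objects:
            # render only the ±4 sigma patch around each blob
            j0 = np.searchsorted(u, x0 - 4 * sigma)
            j1 = np.searchsorted(u, x0 + 4 * sigma)
            i0 = np.searchsorted(v, y0 - 4 * sigma)
            i1 = np.searchsorted(v, y0 + 4 * sigma)
            if j0 >= j1 or i0 >= i1:
                continue
            du = (u[j0:j1] - x0) / sigma
            dv = (v[i0:i1] - y0) / sigma
            img[i0:i1, j0:j1] += amp * np.exp(
                -0.5 * (du[None, :] ** 2 + dv[:, None] ** 2)
            )
        return img

    if specimen.kind is SpecimenKind.GRATICULE:
        spacing = specimen.params["spacing_um"]
        halfline = specimen.params["linewidth_um"] / 2.0
        phase = np.abs(((u + spacing / 2.0) % spacing) - spacing / 2.0)
        line = phase <= halfline
        img[:, line] += specimen.params["amplitude"]
        return img

    if specimen.kind is SpecimenKind.USAF_BARS:
        lp = specimen.params["lp_per_mm"]
        bar_w = 500.0 / lp  # µm: one line pair = 2 bar widths = 1000/lp µm
        bar_len = 5.0 * bar_w
        inside_y = np.abs(v) <= bar_len / 2.0
        # three bars centred at -2w, 0, +2w
        ub = np.abs(((u + bar_w) % (2.0 * bar_w)) - bar_w) <= bar_w / 2.0
        ub &= np.abs(u) <= 2.5 * bar_w
        img[np.ix_(inside_y, ub)] += specimen.params["amplitude"]
        return img

    if specimen.kind is SpecimenKind.SLANT_EDGE:
        theta = np.deg2rad(specimen.params["angle_deg"])
        # signed distance (µm) from the edge line through the world origin
        dist_um = u[None, :] * np.cos(theta) - v[:, None] * np.sin(theta)
        dist_px = dist_um * scale
        # 1-px linear ramp for sub-pixel edge placement
        img += specimen.params["amplitude"] * np.clip(dist_px + 0.5, 0.0, 1.0)
        return img

    return img  # uniform


def render_frame(
    specimen: SpecimenModel, camera: CameraConfig, pose: StagePose
) -> np.ndarray:
    """Render one 8-bit frame at the given stage pose."""
    img = _ideal_image(specimen, camera, pose)

    sigma_defocus = camera.defocus_blur_per_mm * abs(pose.z - specimen.focal_plane_z)
    sigma_vib = camera.vibration_blur_gain * pose.vibration_amplitude
    sigma = float(np.hypot(sigma_defocus, sigma_vib))
    if sigma > 1e-3:
        img = ndimage.gaussian_filter(img, sigma, mode="nearest")

    if camera.illumination == "oblique_gradient":
        grad = np.linspace(0.7, 1.0, camera.resolution[0])
        img = img * grad[None, :]

    if camera.noise_sd > 0:
        rng = np.random.default_rng(_render_seed(camera.seed, pose))
        img = img + rng.normal(0.0, camera.noise_sd, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _render_seed(seed: int, pose: StagePose) -> int:
    """Deterministic per-capture noise seed from camera seed and pose."""
    payload = np.array(
        [pose.x, pose.y, pose.z, pose.time, pose.vibration_amplitude], dtype=np.float64
    ).tobytes()
    return (zlib.crc32(payload) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF
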