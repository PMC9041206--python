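"""Laplacian-based autofocus over a Z sweep.

Sharpness is the variance of the 3x3 discrete Laplacian response after an
optional Gaussian prefilter (radius = the Gaussian sigma in pixels; radius 1
is the default, radius 0 disables the prefilter).  The best focus of a
Z-stack is the slice maximizing that score; a full sweep acquires frames at
fixed Z intervals (0.2 mm by default), picks the best slice, returns the
stage there and redefines that height as Z0 with ``G92Z0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .camera import CameraConfig, SpecimenModel, render_frame
from .motion import VirtualStage

__all__ = [
    "SharpnessProfile",
    "sharpness_score",
    "best_focus_index",
    "autofocus_sweep",
]

# 3x3 discrete Laplacian (4-neighbour)
_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


@dataclass(frozen=True)
class SharpnessProfile:
    """Sharpness score as a function of Z (or of post-move delay)."""

    z_values: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.z_values) != len(self.scores):
            raise ValueError("z_values and scores must have equal length")
        if not np.all(np.isfinite(self.scores)) or np.any(np.asarray(self.scores) < 0):
            raise ValueError("scores must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z_values, "score": self.scores})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.scores))


def sharpness_score(image: np.ndarray, gaussian_radius: float = 1.0) -> float:
    """Variance of the Laplacian response, after Gaussian prefiltering.

    ``gaussian_radius`` is the prefilter sigma in pixels (kernel truncated at
    3 sigma); 0 skips the prefilter.  Constant images score exactly 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # collapse colour to luminance
        img = img.mean(axis=2)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("sharpness needs a 2-D image of at least 3x3 pixels")
    if gaussian_radius < 0:
        raise ValueError("gaussian_radius must be non-negative")
    if gaussian_radius > 0:
        img = ndimage.gaussian_filter(img, gaussian_radius, truncate=3.0)
    response = ndimage.convolve(img, _LAPLACIAN, mode="nearest")
    return float(response.var())


def best_focus_index(stack, gaussian_radius: float = 1.0) -> int:
    """Index of the sharpest slice; ties break toward the lowest index."""
    scores = [sharpness_score(frame, gaussian_radius) for frame in stack]
    if not scores:
        raise ValueError("empty stack")
    return int(np.argmax(scores))


def autofocus_sweep(
    stage: VirtualStage,
    camera: CameraConfig,
    specimen: SpecimenModel,
    z_min: float,
    z_max: float,
    z_step: float = 0.2,
    gaussian_radius: float = 1.0,
    zero_at_focus: bool = True,
) -> tuple[float, SharpnessProfile]:
    """Acquire a Z-stack, pick best focus, move there and re-zero Z.

    Steps through ``[z_min, z_max]`` at ``z_step`` (mm, firmware frame),
    waiting the configured settle time before each capture.  Returns the
    focus Z and the full sharpness profile; when ``zero_at_focus``, the
    stage is driven back to the best slice and ``G92Z0`` is emitted, making
    the focal height the new Z origin.

    Warns if the best focus lands on a sweep boundary (the true focal plane
    may lie outside the sweep).
    """
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    if not z_min < z_max:
        raise ValueError("z_min must be below z_max")
    z_values = np.arange(z_min, z_max + z_step / 2.0, z_step)
    scores = []
    for z in z_values:
        stage.move_absolute(z=float(z))
        stage.settle(axes=("z",))
        frame = render_frame(specimen, camera, stage.pose)
        scores.append(sharpness_score(frame, gaussian_radius))
    profile = SharpnessProfile(z_values=z_values, scores=np.asarray(scores))
    best = profile.best_index
    if best in (0, len(z_values) - 1):
        warnings.warn(
            "best focus at sweep boundary; focal plane may be out of range",
            stacklevel=2,
        )
    focus_z = float(z_values[best])
    if zero_at_focus:
        stage.move_absolute(z=focus_z)
        stage.settle(axes=("z",))
        stage.zero_z()
    return focus_z, profile
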