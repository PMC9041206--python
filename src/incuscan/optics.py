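"""Objective calibration and resolution metrics.

The pixel scale (px/µm) of an objective is measured from an image of a stage
graticule of known line spacing.  Scale plus sensor size gives the field of
view; multiplying the FOV by the overlap factor (default 0.8, leaving 20%
overlap between adjacent tiles for stitching) gives the X/Y step increments
used by the scan planner.

Two resolution metrics are provided: the USAF-1951 group/element line
density, and a slant-edge MTF computed from an oversampled edge-spread
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoEdgeError, NoGraticuleError

__all__ = [
    "ObjectiveProfile",
    "MtfCurve",
    "estimate_pixel_scale",
    "derive_profile",
    "usaf_lp_per_mm",
    "slant_edge_mtf",
]


@dataclass(frozen=True)
class ObjectiveProfile:
    """Calibrated optics: pixel scale, field of view and scan increments.

    ``fov_um`` is the sensor extent divided by the scale, componentwise;
    ``step_increment_um`` is the FOV scaled by ``overlap_factor`` — the
    stage step between adjacent tiles that leaves ``1 - overlap_factor`` of
    each frame overlapping its neighbour.
    """

    label: str
    pixels_per_um: float
    sensor_px: tuple[int, int]
    overlap_factor: float = 0.8
    fov_um: tuple[float, float] = field(init=False)
    step_increment_um: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.pixels_per_um <= 0:
            raise ValueError("pixels_per_um must be positive")
        if not (0 < self.overlap_factor <= 1):
            raise ValueError("overlap_factor must be in (0, 1]")
        if min(self.sensor_px) <= 0:
            raise ValueError("sensor_px must be positive")
        fov = (
            self.sensor_px[0] / self.pixels_per_um,
            self.sensor_px[1] / self.pixels_per_um,
        )
        object.__setattr__(self, "fov_um", fov)
        object.__setattr__(
            self,
            "step_increment_um",
            (fov[0] * self.overlap_factor, fov[1] * self.overlap_factor),
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "pixels_per_um": self.pixels_per_um,
            "sensor_px": list(self.sensor_px),
            "overlap_factor": self.overlap_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObjectiveProfile":
        return cls(
            label=str(d.get("label", "custom")),
            pixels_per_um=float(d["pixels_per_um"]),
            sensor_px=(int(d["sensor_px"][0]), int(d["sensor_px"][1])),
            overlap_factor=float(d.get("overlap_factor", 0.8)),
        )


@dataclass(frozen=True)
class MtfCurve:
    """Modulation transfer function samples.

    ``frequencies`` are in line pairs per mm when a pixel scale was supplied
    to :func:`slant_edge_mtf`, otherwise in cycles per pixel.  ``modulation``
    is normalized to 1 at zero frequency.
    """

    frequencies: np.ndarray
    modulation: np.ndarray
    units: str = "cycles/px"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f"frequency_{self.units.replace('/', '_per_')}": self.frequencies,
             "modulation": self.modulation}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def estimate_pixel_scale(image: np.ndarray, graticule_spacing_um: float) -> float:
    """Pixel scale (px/µm) from an image of a line graticule.

    The image is averaged down each axis to two line profiles; the dominant
    period of the more periodic profile is found at the first significant
    peak of its autocorrelation.  The scale is that period divided by the
    known line spacing.

    Raises :class:`NoGraticuleError` if neither profile shows significant
    periodicity (autocorrelation peak below 0.25).
    """
    if graticule_spacing_um <= 0:
        raise ValueError("graticule_spacing_um must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity raster")

    best_period, best_strength = None, 0.0
    for axis in (0, 1):
        profile = img.mean(axis=axis)
        profile = profile - profile.mean()
        if np.allclose(profile, 0):
            continue
        ac = np.correlate(profile, profile, mode="full")[profile.size - 1 :]
        ac = ac / ac[0]
        # first local maximum after the zero-lag peak has decayed
        lag = _first_autocorr_peak(ac)
        if lag is not None and ac[lag] > best_strength:
            best_period, best_strength = lag, ac[lag]
    if best_period is None or best_strength < 0.25:
        raise NoGraticuleError("no significant periodicity found in image")
    # parabolic sub-sample refinement around the peak
    period = float(best_period)
    return period / graticule_spacing_um


def _first_autocorr_peak(ac: np.ndarray) -> int | None:
    """Lag of the dominant periodicity: the autocorrelation's global maximum
    once the zero-lag lobe has decayed below 0.5."""
    below = np.nonzero(ac < 0.5)[0]
    if below.size == 0 or below[0] >= ac.size - 1:
        return None
    start = int(below[0])
    return start + int(np.argmax(ac[start:]))


def derive_profile(
    pixels_per_um: float,
    sensor_px: tuple[int, int],
    overlap_factor: float = 0.8,
    label: str = "custom",
) -> ObjectiveProfile:
    """Build an :class:`ObjectiveProfile` from a measured pixel scale."""
    return ObjectiveProfile(
        label=label,
        pixels_per_um=pixels_per_um,
        sensor_px=tuple(sensor_px),
        overlap_factor=overlap_factor,
    )


def usaf_lp_per_mm(group: int, element: int) -> float:
    """Line density (line pairs/mm) of a USAF-1951 target element.

    The chart is defined by ``2 ** (group + (element - 1) / 6)``; element
    must be 1–6.  Reported to one decimal place, the chart's printed
    precision (group 7 element 6 -> 228.1).
    """
    if not 1 <= int(element) <= 6:
        raise ValueError("USAF element must be in 1..6")
    return round(2.0 ** (group + (element - 1) / 6.0), 1)


def slant_edge_mtf(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    oversample: int = 4,
    pixels_per_um: float | None = None,
) -> MtfCurve:
    """Slant-edge MTF from a near-vertical step edge.

    Standard edge-gradient procedure: the edge crossing is located on each
    row (centroid of the row gradient), a straight line is fitted through
    the crossings, every pixel is projected onto the edge normal, and the
    projected samples are binned at ``1/oversample`` px to give an
    oversampled edge-spread function.  The ESF is differentiated to the
    line-spread function, Hann-windowed, and Fourier-transformed; the
    magnitude normalized at zero frequency is the MTF.

    ``roi`` is ``(row0, row1, col0, col1)``; the whole image by default.
    If ``pixels_per_um`` is given, frequencies are converted from cycles per
    pixel to line pairs per mm.

    Raises :class:`NoEdgeError` when no consistent edge is found.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity raster")
    if roi is not None:
        r0, r1, c0, c1 = roi
        img = img[r0:r1, c0:c1]
    h, w = img.shape
    if h < 8 or w < 8:
        raise NoEdgeError("ROI too small for edge analysis")

    # locate the edge on each row: centroid of |d/dx|
    grad = np.abs(np.diff(img, axis=1))
    total = grad.sum(axis=1)
    if np.any(total <= 0) or grad.max() < 1e-9:
        raise NoEdgeError("no intensity edge found in ROI")
    cols = np.arange(w - 1) + 0.5
    centers = (grad * cols).sum(axis=1) / total

    rows = np.arange(h, dtype=float)
    slope, intercept = np.polyfit(rows, centers, 1)
    residual = np.abs(centers - (slope * rows + intercept))
    if np.median(residual) > 2.0:
        raise NoEdgeError("edge crossings do not lie on a straight line")

    # signed distance of each pixel from the fitted edge, in px along the
    # edge normal (x - x_edge(y)) / sqrt(1 + slope^2)
    yy, xx = np.mgrid[0:h, 0:w]
    dist = (xx - (slope * yy + intercept)) / np.hypot(1.0, slope)

    # bin the projected samples into an oversampled ESF
    bin_width = 1.0 / oversample
    idx = np.floor(dist / bin_width).astype(int)
    idx -= idx.min()
    nbins = idx.max() + 1
    sums = np.bincount(idx.ravel(), weights=img.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    filled = counts > 0
    esf = np.interp(
        np.arange(nbins), np.nonzero(filled)[0], sums[filled] / counts[filled]
    )

    lsf = np.gradient(esf)
    # centre a Hann window on the LSF peak to suppress far-field noise
    peak = int(np.argmax(np.abs(lsf)))
    half = min(peak, lsf.size - 1 - peak)
    lsf = lsf[peak - half : peak + half + 1]
    lsf = lsf * np.hanning(lsf.size)

    spectrum = np.abs(np.fft.rfft(lsf))
    if spectrum[0] <= 0:
        raise NoEdgeError("degenerate edge: zero net intensity step")
    mtf = spectrum / spectrum[0]
    freqs = np.fft.rfftfreq(lsf.size, d=bin_width)  # cycles per original px

    keep = freqs <= 1.0  # beyond the original sampling rate is meaningless
    freqs, mtf = freqs[keep], mtf[keep]
    if pixels_per_um is not None:
        return MtfCurve(freqs * pixels_per_um * 1000.0, mtf, units="lp/mm")
    return MtfCurve(freqs, mtf, units="cycles/px")
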