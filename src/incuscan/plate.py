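"""Well-plate geometry from user-captured landmarks.

A plate is located on the stage by driving six landmarks of well A1 and its
neighbours into the centre of the field of view and recording the stage
coordinates: the top-, bottom-, left- and right-most points of well A1
(``a1_top``, ``a1_bottom``, ``a1_left``, ``a1_right``), the left-most point
of well A2 and the top-most point of well B1.  From these the well diameter
D, the well pitches dX (between columns) and dY (between rows) and the
centre of A1 are derived; every other well centre follows by integer
multiples of the pitches.

Stage frame: millimetres, X rightward, Y away from the door, origin at the
boot pose (the stage powers up at X0 Y0 Z0).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DegenerateLandmarksError, InconsistentLandmarksError

__all__ = [
    "PLATE_FORMATS",
    "WellLandmarks",
    "PlateSpec",
    "WellAddress",
    "Anchor",
    "calibrate_plate_from_landmarks",
    "well_position",
    "landmarks_from_spec",
]

#: rows x columns for the supported plate formats
PLATE_FORMATS: dict[int, tuple[int, int]] = {6: (2, 3), 24: (4, 6), 96: (8, 12)}

#: relative tolerance on the two independent well-diameter estimates
DIAMETER_TOLERANCE = 0.05


@dataclass(frozen=True)
class WellLandmarks:
    """Stage XY (mm) of the six calibration landmarks.

    ``a1_top``/``a1_bottom``/``a1_left``/``a1_right`` are the extreme points
    of well A1; ``a2_left`` is the left-most point of well A2 (one column
    over) and ``b1_top`` the top-most point of well B1 (one row down).
    """

    a1_top: tuple[float, float]
    a1_bottom: tuple[float, float]
    a1_left: tuple[float, float]
    a1_right: tuple[float, float]
    a2_left: tuple[float, float]
    b1_top: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.a1_bottom[1] > self.a1_top[1]):
            raise DegenerateLandmarksError(
                "a1_bottom must lie below a1_top (larger Y)"
            )
        if not (self.a1_right[0] > self.a1_left[0]):
            raise DegenerateLandmarksError(
                "a1_right must lie right of a1_left (larger X)"
            )
        if not (self.a2_left[0] > self.a1_left[0]):
            raise DegenerateLandmarksError("a2_left must lie right of a1_left")
        if not (self.b1_top[1] > self.a1_top[1]):
            raise DegenerateLandmarksError("b1_top must lie below a1_top")


@dataclass(frozen=True)
class PlateSpec:
    """Full plate geometry in the stage frame.

    ``well_diameter`` (D), ``pitch_x`` (dX, centre-to-centre between columns)
    and ``pitch_y`` (dY, between rows) are in mm; ``a1_center`` is the stage
    XY of the centre of well A1.
    """

    format: int
    well_diameter: float
    pitch_x: float
    pitch_y: float
    a1_center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.format not in PLATE_FORMATS:
            raise ValueError(f"unsupported plate format: {self.format}")
        if self.well_diameter <= 0:
            raise ValueError("well_diameter must be positive")
        if self.pitch_x < self.well_diameter or self.pitch_y < self.well_diameter:
            raise ValueError("well pitch cannot be smaller than the well diameter")

    @property
    def rows(self) -> int:
        return PLATE_FORMATS[self.format][0]

    @property
    def cols(self) -> int:
        return PLATE_FORMATS[self.format][1]

    def wells(self) -> Iterator["WellAddress"]:
        """All wells in acquisition order A1, A2, ... B1, B2, ... (row-major)."""
        for r in range(1, self.rows + 1):
            for c in range(1, self.cols + 1):
                yield WellAddress(row=r, col=c)

    def to_arrays(self) -> pd.DataFrame:
        """Config-facing five-column view of the plate.

        Columns: well label, default (centre) X and Y per well, and the
        row/column offsets from the A1 centre.  One row per well, in
        acquisition order.
        """
        rows = []
        for well in self.wells():
            x, y = well_position(self, well, Anchor.CENTER)
            rows.append(
                {
                    "label": well.label,
                    "default_x_mm": x,
                    "default_y_mm": y,
                    "row_offset_mm": (well.row - 1) * self.pitch_y,
                    "col_offset_mm": (well.col - 1) * self.pitch_x,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "format": self.format,
            "well_diameter": self.well_diameter,
            "pitch_x": self.pitch_x,
            "pitch_y": self.pitch_y,
            "a1_center": list(self.a1_center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateSpec":
        return cls(
            format=int(d["format"]),
            well_diameter=float(d["well_diameter"]),
            pitch_x=float(d["pitch_x"]),
            pitch_y=float(d["pitch_y"]),
            a1_center=(float(d["a1_center"][0]), float(d["a1_center"][1])),
        )


@dataclass(frozen=True)
class WellAddress:
    """1-based well coordinate: row 1 = A, col 1 = 1."""

    row: int
    col: int

    @classmethod
    def from_label(cls, label: str) -> "WellAddress":
        label = label.strip().upper()
        if len(label) < 2 or not label[0].isalpha() or not label[1:].isdigit():
            raise ValueError(f"malformed well label: {label!r}")
        return cls(row=ord(label[0]) - ord("A") + 1, col=int(label[1:]))

    @property
    def label(self) -> str:
        return f"{chr(ord('A') + self.row - 1)}{self.col}"


class Anchor(Enum):
    """Where in the well's bounding square an imaging sweep starts.

    ``MIN_CORNER`` is the default start: the minimum-X/minimum-Y corner, so
    the sweep enters the well from outside.  ``SEGMENT_1`` .. ``SEGMENT_9``
    are a 3x3 grid of anchors over the bounding square, row-major from the
    top-left corner (1) through the centre (5) to the bottom-right corner (9).
    """

    CENTER = "center"
    MIN_CORNER = "min_corner"
    SEGMENT_1 = "segment_1"
    SEGMENT_2 = "segment_2"
    SEGMENT_3 = "segment_3"
    SEGMENT_4 = "segment_4"
    SEGMENT_5 = "segment_5"
    SEGMENT_6 = "segment_6"
    SEGMENT_7 = "segment_7"
    SEGMENT_8 = "segment_8"
    SEGMENT_9 = "segment_9"


def _midpoint(*points: tuple[float, float]) -> tuple[float, float]:
    arr = np.asarray(points, dtype=float)
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def calibrate_plate_from_landmarks(
    landmarks: WellLandmarks, format: int
) -> PlateSpec:
    """Derive the plate geometry from the six captured landmarks.

    The well diameter is measured twice — vertically (a1_bottom - a1_top)
    and horizontally (a1_right - a1_left) — and the two estimates must agree
    within 5%; D is their mean.  dX is the left-edge spacing between A1 and
    A2, dY the top-edge spacing between A1 and B1, and the A1 centre is the
    midpoint of the four A1 landmarks.

    Raises
    ------
    InconsistentLandmarksError
        If the two diameter estimates disagree by more than 5%.
    DegenerateLandmarksError
        If any landmark pair has zero extent.
    """
    d_vertical = landmarks.a1_bottom[1] - landmarks.a1_top[1]
    d_horizontal = landmarks.a1_right[0] - landmarks.a1_left[0]
    if d_vertical <= 0 or d_horizontal <= 0:
        raise DegenerateLandmarksError("well landmarks have zero or negative extent")
    mean_d = 0.5 * (d_vertical + d_horizontal)
    if abs(d_vertical - d_horizontal) > DIAMETER_TOLERANCE * mean_d:
        raise InconsistentLandmarksError(
            f"vertical diameter {d_vertical:.3f} mm and horizontal diameter "
            f"{d_horizontal:.3f} mm disagree by more than "
            f"{DIAMETER_TOLERANCE:.0%}"
        )
    pitch_x = landmarks.a2_left[0] - landmarks.a1_left[0]
    pitch_y = landmarks.b1_top[1] - landmarks.a1_top[1]
    if pitch_x <= 0 or pitch_y <= 0:
        raise DegenerateLandmarksError("well pitches must be positive")
    return PlateSpec(
        format=format,
        well_diameter=mean_d,
        pitch_x=pitch_x,
        pitch_y=pitch_y,
        a1_center=_midpoint(
            landmarks.a1_top, landmarks.a1_bottom, landmarks.a1_left, landmarks.a1_right
        ),
    )


def landmarks_from_spec(plate: PlateSpec) -> WellLandmarks:
    """Synthesize the landmark set a perfect operator would capture.

    Inverse of :func:`calibrate_plate_from_landmarks`; used to round-trip
    geometry in tests and to seed simulated calibration sessions.
    """
    cx, cy = plate.a1_center
    r = plate.well_diameter / 2.0
    return WellLandmarks(
        a1_top=(cx, cy - r),
        a1_bottom=(cx, cy + r),
        a1_left=(cx - r, cy),
        a1_right=(cx + r, cy),
        a2_left=(cx - r + plate.pitch_x, cy),
        b1_top=(cx, cy - r + plate.pitch_y),
    )


def well_position(
    plate: PlateSpec, well: WellAddress, anchor: Anchor = Anchor.CENTER
) -> tuple[float, float]:
    """Stage XY (mm) of an anchor point of a well.

    ``CENTER`` is ``a1_center + ((col-1)*dX, (row-1)*dY)``; ``MIN_CORNER``
    subtracts half the diameter on each axis so a sweep starts outside the
    well; ``SEGMENT_k`` picks one of nine points on the 3x3 grid over the
    well's bounding square.
    """
    if not (1 <= well.row <= plate.rows and 1 <= well.col <= plate.cols):
        raise ValueError(
            f"well {well.label} outside a {plate.format}-well plate "
            f"({plate.rows}x{plate.cols})"
        )
    cx = plate.a1_center[0] + (well.col - 1) * plate.pitch_x
    cy = plate.a1_center[1] + (well.row - 1) * plate.pitch_y
    if anchor is Anchor.CENTER:
        return (cx, cy)
    half = plate.well_diameter / 2.0
    if anchor is Anchor.MIN_CORNER:
        return (cx - half, cy - half)
    k = int(anchor.value.rsplit("_", 1)[1]) - 1  # 0..8 row-major
    gx, gy = k % 3, k // 3  # grid column, grid row
    return (cx + (gx - 1) * half, cy + (gy - 1) * half)
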