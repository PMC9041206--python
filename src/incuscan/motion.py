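"""G-code stage control and the virtual stage.

The stage is a 3-axis gantry driven by GRBL-dialect G-code: ``G0`` moves,
``G90``/``G91`` absolute/relative mode, ``G92Z0`` to redefine the current Z
as zero, and ``$N=value`` lines for firmware settings (``$100``–``$102`` are
the per-axis steps-per-mm).

:class:`VirtualStage` simulates the physics needed to exercise the whole
pipeline without hardware: steps-per-mm miscalibration (the firmware
converts commanded mm to steps with its configured steps/mm, the "motor"
converts steps back to mm with the *true* steps/mm, so realized motion is
commanded x firmware/true), Gaussian positioning noise per move, a simulated
clock advanced by distance / max_speed, and a post-move vibration amplitude
that decays exponentially with time constant settle_time / 3 (so the
residual is below 5% of the initial amplitude once the settle time has
elapsed).  The stage powers up at X0 Y0 Z0.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import GCodeError, TravelLimitError

__all__ = [
    "Axis",
    "GCodeKind",
    "GCodeCommand",
    "StageConfig",
    "StagePose",
    "VirtualStage",
    "format_gcode",
    "parse_gcode",
    "render_grbl_setting",
    "parse_grbl_setting",
    "virtual_execute",
]

AXES = ("x", "y", "z")


class Axis(str, Enum):
    X = "x"
    Y = "y"
    Z = "z"


class GCodeKind(str, Enum):
    MOVE_ABSOLUTE = "move_absolute"
    MOVE_RELATIVE = "move_relative"
    ZERO_AXIS = "zero_axis"
    SETTING = "setting"


@dataclass(frozen=True)
class GCodeCommand:
    """A parsed or formatted G-code command.

    ``text`` is the exact serial payload; relative moves are three lines
    (``G91``, the move, ``G90``) so the stage is always restored to absolute
    mode.
    """

    text: str
    kind: GCodeKind
    coordinates: dict[str, float] = field(default_factory=dict)
    feed: float | None = None

    @property
    def lines(self) -> list[str]:
        return self.text.splitlines()


def _fmt(value: float) -> str:
    return f"{value:.3f}"


def format_gcode(
    kind: GCodeKind | str,
    coordinates: dict[str, float] | None = None,
    feed: float | None = None,
) -> GCodeCommand:
    """Render a move or zeroing command as deterministic G-code text.

    Moves print each given axis with 3-decimal coordinates in X, Y, Z order;
    zeroing Z emits exactly ``G92Z0``.  A move with no axes is an error.
    """
    kind = GCodeKind(kind)
    coordinates = {k.lower(): float(v) for k, v in (coordinates or {}).items()}
    for axis in coordinates:
        if axis not in AXES:
            raise GCodeError(f"unknown axis {axis!r}")
    if kind is GCodeKind.ZERO_AXIS:
        return GCodeCommand(text="G92Z0", kind=kind)
    if kind in (GCodeKind.MOVE_ABSOLUTE, GCodeKind.MOVE_RELATIVE):
        if not coordinates:
            raise GCodeError("a move needs at least one axis")
        move = "G0" + "".join(
            f"{a.upper()}{_fmt(coordinates[a])}" for a in AXES if a in coordinates
        )
        if feed is not None:
            move += f"F{_fmt(feed)}"
        if kind is GCodeKind.MOVE_RELATIVE:
            text = f"G91\n{move}\nG90"
        else:
            text = move
        return GCodeCommand(text=text, kind=kind, coordinates=coordinates, feed=feed)
    raise GCodeError(f"cannot format command of kind {kind}")


_MOVE_RE = re.compile(
    r"^G0"
    r"(?:X(?P<x>-?\d+(?:\.\d+)?))?"
    r"(?:Y(?P<y>-?\d+(?:\.\d+)?))?"
    r"(?:Z(?P<z>-?\d+(?:\.\d+)?))?"
    r"(?:F(?P<f>-?\d+(?:\.\d+)?))?$"
)


def parse_gcode(text: str) -> GCodeCommand:
    """Parse text produced by :func:`format_gcode` back into a command."""
    stripped = text.strip()
    if stripped == "G92Z0":
        return GCodeCommand(text="G92Z0", kind=GCodeKind.ZERO_AXIS)
    lines = stripped.splitlines()
    relative = False
    if len(lines) == 3 and lines[0] == "G91" and lines[2] == "G90":
        relative = True
        move_line = lines[1]
    elif len(lines) == 1:
        move_line = lines[0]
    else:
        raise GCodeError(f"unrecognized G-code block: {text!r}")
    m = _MOVE_RE.match(move_line)
    if m is None or not any(m.group(a) for a in AXES):
        raise GCodeError(f"unrecognized G-code line: {move_line!r}")
    coords = {a: float(m.group(a)) for a in AXES if m.group(a) is not None}
    feed = float(m.group("f")) if m.group("f") else None
    kind = GCodeKind.MOVE_RELATIVE if relative else GCodeKind.MOVE_ABSOLUTE
    return GCodeCommand(text=stripped, kind=kind, coordinates=coords, feed=feed)


def render_grbl_setting(index: int, value: float) -> str:
    """``(100, 80.0) -> "$100=80.0"`` — a GRBL settings line."""
    if index < 0:
        raise ValueError("GRBL setting index must be non-negative")
    return f"${int(index)}={float(value)}"


_SETTING_RE = re.compile(r"^\$(\d+)=(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)$")


def parse_grbl_setting(text: str) -> tuple[int, float]:
    """Inverse of :func:`render_grbl_setting`; raises GCodeError if malformed."""
    m = _SETTING_RE.match(text.strip())
    if m is None:
        raise GCodeError(f"malformed GRBL setting line: {text!r}")
    return int(m.group(1)), float(m.group(2))


def _triple(value, default: float) -> tuple[float, float, float]:
    if value is None:
        return (default, default, default)
    if np.isscalar(value):
        return (float(value),) * 3
    value = tuple(float(v) for v in value)
    if len(value) == 2:
        return (value[0], value[1], value[1])
    if len(value) != 3:
        raise ValueError("expected a scalar or a 2/3-vector per axis")
    return value


@dataclass(frozen=True)
class StageConfig:
    """Firmware settings and simulator ground truth for the virtual stage.

    ``firmware_steps_per_mm`` is what GRBL believes ($100/$101/$102);
    ``true_steps_per_mm`` is the physical value.  Realized motion per axis is
    commanded x firmware/true.  ``settle_time`` defaults to 0.6 s (X) and
    1.0 s (Y), the measured vibration-settling delays of the hardware the
    simulator stands in for.
    """

    firmware_steps_per_mm: tuple[float, float, float] = (80.0, 80.0, 400.0)
    true_steps_per_mm: tuple[float, float, float] = (80.0, 80.0, 400.0)
    max_speed: float = 130.0  # mm/s
    settle_time: tuple[float, float, float] = (0.6, 1.0, 0.6)  # s per axis
    position_noise_sd: float = 2.0  # µm per move, per commanded axis
    vibration_amplitude_um: float = 10.0  # A0 immediately after a move
    travel_limits: tuple[float, float] = (-250.0, 250.0)  # mm, all axes
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "firmware_steps_per_mm", _triple(self.firmware_steps_per_mm, 80.0)
        )
        object.__setattr__(
            self, "true_steps_per_mm", _triple(self.true_steps_per_mm, 80.0)
        )
        object.__setattr__(self, "settle_time", _triple(self.settle_time, 0.6))
        if min(self.firmware_steps_per_mm) <= 0 or min(self.true_steps_per_mm) <= 0:
            raise ValueError("steps/mm must be positive")
        if self.max_speed <= 0:
            raise ValueError("max_speed must be positive")
        if min(self.settle_time) < 0 or self.position_noise_sd < 0:
            raise ValueError("settle_time and noise must be non-negative")

    def settings_dump(self) -> str:
        """GRBL ``$$``-style dump of the steps-per-mm settings."""
        return "\n".join(
            render_grbl_setting(100 + i, self.firmware_steps_per_mm[i])
            for i in range(3)
        )


@dataclass(frozen=True)
class StagePose:
    """Snapshot of the simulated stage: true position, clock and vibration."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    time: float = 0.0
    last_move_time: tuple[float, float, float] = (-math.inf,) * 3
    vibration_amplitude: float = 0.0  # µm, at `time`


class VirtualStage:
    """Simulated 3-axis stage executing G-code against :class:`StageConfig`.

    Keeps two positions: the firmware coordinate (what absolute G-code
    targets refer to, shifted by ``G92Z0``) and the true physical position
    (what the camera sees).  Every executed command is appended to
    :attr:`gcode_log`, one line per serial line.
    """

    def __init__(self, config: StageConfig | None = None, seed: int | None = None):
        self.config = config or StageConfig()
        self.rng = np.random.default_rng(
            self.config.seed if seed is None else seed
        )
        self.firmware_pos = np.zeros(3)  # frame the G-code speaks in
        self.true_pos = np.zeros(3)  # physical, mm
        self.time = 0.0
        self._last_move = np.full(3, -math.inf)
        self.gcode_log: list[str] = []

    # -- state --------------------------------------------------------------

    @property
    def pose(self) -> StagePose:
        return StagePose(
            x=float(self.true_pos[0]),
            y=float(self.true_pos[1]),
            z=float(self.true_pos[2]),
            time=self.time,
            last_move_time=tuple(self._last_move),
            vibration_amplitude=self.vibration_amplitude(),
        )

    def vibration_amplitude(self, at_time: float | None = None) -> float:
        """Residual vibration (µm): A0 exp(-(t - t_move) / (settle/3)), the
        worst over axes moved so far."""
        t = self.time if at_time is None else at_time
        amp = 0.0
        for i in range(3):
            if math.isinf(self._last_move[i]):
                continue
            tau = self.config.settle_time[i] / 3.0
            dt = t - self._last_move[i]
            if dt < 0:
                continue
            decay = math.exp(-dt / tau) if tau > 0 else (1.0 if dt == 0 else 0.0)
            amp = max(amp, self.config.vibration_amplitude_um * decay)
        return amp

    def wait(self, dt: float) -> None:
        """Advance the simulated clock (e.g. the post-move settle delay)."""
        if dt < 0:
            raise ValueError("cannot wait a negative time")
        self.time += dt

    def settle(self, axes: Sequence[str] = AXES) -> None:
        """Wait the configured settle time of the slowest axis given."""
        self.wait(max(self.config.settle_time[AXES.index(a)] for a in axes))

    # -- execution ----------------------------------------------------------

    def execute(self, command: GCodeCommand) -> StagePose:
        """Apply a command to the simulated physics and log its text."""
        self.gcode_log.extend(command.lines)
        if command.kind is GCodeKind.ZERO_AXIS:
            self.firmware_pos[2] = 0.0
            return self.pose
        if command.kind is GCodeKind.MOVE_ABSOLUTE:
            delta = {
                a: command.coordinates[a] - self.firmware_pos[AXES.index(a)]
                for a in command.coordinates
            }
        elif command.kind is GCodeKind.MOVE_RELATIVE:
            delta = dict(command.coordinates)
        else:
            raise GCodeError(f"virtual stage cannot execute kind {command.kind}")
        self._apply_move(delta)
        return self.pose

    def _apply_move(self, delta: dict[str, float]) -> None:
        cfg = self.config
        commanded = np.zeros(3)
        for axis, d in delta.items():
            commanded[AXES.index(axis)] = d
        ratio = np.asarray(cfg.firmware_steps_per_mm) / np.asarray(
            cfg.true_steps_per_mm
        )
        physical = commanded * ratio
        moved = commanded != 0.0
        if moved.any():
            noise_mm = self.rng.normal(0.0, cfg.position_noise_sd / 1000.0, size=3)
            physical = physical + noise_mm * moved
        new_true = self.true_pos + physical
        lo, hi = cfg.travel_limits
        if np.any(new_true < lo) or np.any(new_true > hi):
            raise TravelLimitError(
                f"move to {new_true.round(3).tolist()} mm exceeds travel "
                f"limits [{lo}, {hi}]"
            )
        self.true_pos = new_true
        self.firmware_pos = self.firmware_pos + commanded
        self.time += float(np.linalg.norm(commanded)) / cfg.max_speed
        self._last_move[moved] = self.time

    # -- convenience wrappers -----------------------------------------------

    def move_absolute(self, x=None, y=None, z=None, feed=None) -> StagePose:
        coords = {a: v for a, v in zip(AXES, (x, y, z)) if v is not None}
        return self.execute(format_gcode(GCodeKind.MOVE_ABSOLUTE, coords, feed))

    def move_relative(self, dx=None, dy=None, dz=None, feed=None) -> StagePose:
        coords = {a: v for a, v in zip(AXES, (dx, dy, dz)) if v is not None}
        return self.execute(format_gcode(GCodeKind.MOVE_RELATIVE, coords, feed))

    def zero_z(self) -> StagePose:
        return self.execute(format_gcode(GCodeKind.ZERO_AXIS))

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.gcode_log) + "\n")


def virtual_execute(
    pose: StagePose, config: StageConfig, command: GCodeCommand
) -> StagePose:
    """Functional one-shot execution: apply one command to a pose.

    Builds a transient :class:`VirtualStage` whose firmware frame coincides
    with the pose's true position (as after a fresh calibration), executes,
    and returns the new pose.
    """
    stage = VirtualStage(config)
    stage.true_pos = np.array([pose.x, pose.y, pose.z], dtype=float)
    stage.firmware_pos = stage.true_pos.copy()
    stage.time = pose.time
    stage._last_move = np.array(pose.last_move_time, dtype=float)
    new = stage.execute(command)
    return replace(new)
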