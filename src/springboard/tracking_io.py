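"""Read, calibrate and canonicalize digitized two-point jump trajectories.

Video digitization software (e.g. Tracker) exports one delimited table per
tracked landmark with columns ``frame, t, x, y`` in pixel space.  This module
parses those exports, applies the ruler scale calibration, and bundles the
body-landmark series and the two-point tarsus series into a
:class:`JumpRecording` together with the per-jump metadata the downstream
kinematics need.

Coordinate convention: +x is the jump direction, +y is up, origin at the
undeflected platform surface beneath the animal.  Recordings filmed in the
opposite direction must be mirrored before they enter the pipeline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "TrackedSeries",
    "JumpRecording",
    "Morphometrics",
    "read_tracker_export",
    "calibrate",
    "ruler_scale",
    "write_jump_table",
    "read_jump_table",
    "JUMP_TABLE_COLUMNS",
]

#: Default muscle mass as a fraction of body mass.  Back-solved from the
#: control-jump means of the study population: a 1.13 g animal taking off at
#: 1.44 m s-1 carries KE = ½mv² = 1.17 mJ, and its printed kinetic-energy
#: density (per jumping-muscle mass) is 24.79 J kg-1, so
#: f = ½v²/KED = 0.5·1.44²/24.79 ≈ 0.0418.
DEFAULT_MUSCLE_FRACTION = 0.0418


@dataclass(frozen=True)
class TrackedSeries:
    """A time-stamped sequence of positions for one tracked landmark.

    Coordinates are pixels straight after parsing and metres after
    :func:`calibrate`.  Missing frames are represented as gaps in
    ``frame_index`` — they are never interpolated.
    """

    frame_index: np.ndarray
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        for name in ("frame_index", "time", "x", "y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.frame_index)
        if not (len(self.time) == len(self.x) == len(self.y) == n):
            raise ValidationError("tracked series columns have unequal lengths")
        if n and np.any(np.diff(self.frame_index) <= 0):
            raise ValidationError("frame indices must be strictly increasing")
        if n and np.any(self.frame_index < 0):
            raise ValidationError("frame indices must be non-negative")
        if n and not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("tracked coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frame_index)

    def has_frame(self, frame: int) -> bool:
        return bool(np.isin(frame, self.frame_index))

    def at_frame(self, frame: int) -> np.ndarray:
        """Position ``(x, y)`` at an exact frame; gap -> ValidationError."""
        idx = np.flatnonzero(self.frame_index == frame)
        if idx.size != 1:
            raise ValidationError(f"frame {frame} is missing from the tracked series")
        i = idx[0]
        return np.array([self.x[i], self.y[i]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame_index, "t": self.time, "x": self.x, "y": self.y}
        )


_COLUMN_ALIASES = {
    "frame": "frame",
    "frame_index": "frame",
    "step": "frame",
    "t": "t",
    "time": "t",
    "x": "x",
    "y": "y",
}


def read_tracker_export(
    path,
    frame_rate: float,
    *,
    delimiter: str | None = None,
    decimal: str = ".",
) -> TrackedSeries:
    """Parse a digitization export into a pixel-space :class:`TrackedSeries`.

    Parameters
    ----------
    path
        Delimited text file (comma or tab) with a header row containing at
        least ``frame`` (or ``t``), ``x`` and ``y`` columns.
    frame_rate
        Frames per second of the recording; used to (re)derive the time
        stamps as ``frame / frame_rate`` so all series share one clock.
    delimiter
        ``","`` or ``"\\t"``; sniffed from the header line when omitted.
    decimal
        Decimal mark of the export dialect (``"."`` or ``","``).
    """
    if frame_rate <= 0:
        raise ValidationError("frame_rate must be positive")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    header, _, _ = text.partition("\n")
    if delimiter is None:
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        df = pd.read_csv(
            io.StringIO(text),
            sep=delimiter,
            decimal=decimal,
            skip_blank_lines=False,
            float_precision="round_trip",
        )
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    df = df.rename(columns=_COLUMN_ALIASES)
    for needed in ("x", "y"):
        if needed not in df.columns:
            raise ParseError(f"{path}: missing required column {needed!r}")
    if "frame" not in df.columns:
        if "t" not in df.columns:
            raise ParseError(f"{path}: need a 'frame' or 't' column")
        frames = np.rint(df["t"].to_numpy(float) * frame_rate).astype(int)
    else:
        frames = df["frame"].to_numpy()

    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(float)))
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path}: malformed value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = vals
    try:
        frames = np.asarray(frames, dtype=int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer frame index") from exc
    if frames.size and np.any(np.diff(frames) <= 0):
        j = int(np.flatnonzero(np.diff(frames) <= 0)[0])
        raise ValidationError(
            f"{path}: frame indices not strictly increasing at line {j + 3} "
            f"(frame {frames[j + 1]} after {frames[j]})"
        )
    return TrackedSeries(
        frame_index=frames,
        time=frames / frame_rate,
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        calibrated=False,
    )


def calibrate(series: TrackedSeries, scale: float) -> TrackedSeries:
    """Scale pixel coordinates to metres; time stamps are untouched."""
    if not scale > 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    return replace(series, x=series.x * scale, y=series.y * scale, calibrated=True)


def ruler_scale(ruler_length_m: float, ruler_length_px: float) -> float:
    """Metres-per-pixel from a ruler of known length spanning a pixel count."""
    if ruler_length_m <= 0 or ruler_length_px <= 0:
        raise ValidationError("ruler lengths must be positive")
    return ruler_length_m / ruler_length_px


@dataclass(frozen=True)
class Morphometrics:
    """Per-animal measurements used by the kinematic and energetic formulas.

    ``femur_length`` defaults to ``tibia_length`` (the two segments are of
    similar length in grasshoppers, so the leg is treated as an isosceles
    two-bar linkage).  ``muscle_mass`` defaults to
    ``DEFAULT_MUSCLE_FRACTION × body_mass``.
    """

    animal_id: str
    body_mass: float  # kg
    tibia_length: float  # m
    takeoff_angle_deg: float  # femur–tibia joint angle at take-off
    femur_length: float | None = None  # m; defaults to tibia_length
    muscle_mass: float | None = None  # kg; defaults to fraction of body mass
    landmark: str = "metathoracic_joint"  # which body landmark was digitized

    def __post_init__(self) -> None:
        if self.femur_length is None:
            object.__setattr__(self, "femur_length", self.tibia_length)
        if self.muscle_mass is None:
            object.__setattr__(
                self, "muscle_mass", DEFAULT_MUSCLE_FRACTION * self.body_mass
            )
        for name in ("body_mass", "tibia_length", "femur_length", "muscle_mass"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.takeoff_angle_deg < 180:
            raise ValidationError("takeoff_angle_deg must lie in (0, 180)")


@dataclass(frozen=True)
class JumpRecording:
    """One calibrated jump: body landmark series, tarsus pair and metadata.

    The tarsus series holds exactly two points — the platform contact point
    at the first frame of visible metathoracic movement and at the last frame
    of tarsi–platform contact — and is ``None`` for control (rigid surface)
    jumps.  ``fixed_end_xy`` locates the clamped end of the platform in the
    calibrated frame; the line from it to the displaced tarsus point defines
    the deformed platform plane.
    """

    body_series: TrackedSeries
    frame_rate: float
    scale: float
    animal_id: str
    platform_id: str  # "control", "A" or "B"
    first_movement_frame: int
    last_contact_frame: int
    tarsus_series: TrackedSeries | None = None
    line_index: int | None = None
    fixed_end_xy: tuple[float, float] = (0.0, 0.0)
    post_takeoff_window_s: float = 0.010

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError("scale must be positive")
        if not self.frame_rate > 0:
            raise ValidationError("frame_rate must be positive")
        if self.first_movement_frame > self.last_contact_frame:
            raise ValidationError(
                "first_movement_frame must not exceed last_contact_frame"
            )
        n_window = self.post_takeoff_window_s * self.frame_rate
        if abs(n_window - round(n_window)) > 1e-9:
            raise ValidationError(
                f"post-take-off window of {self.post_takeoff_window_s} s is not an "
                f"integer number of frames at {self.frame_rate} fps"
            )
        for f in (self.last_contact_frame, self.takeoff_window_end_frame):
            if not self.body_series.has_frame(f):
                raise ValidationError(
                    f"body series of jump {self.animal_id}/{self.platform_id} lacks "
                    f"required frame {f}"
                )
        if self.tarsus_series is not None and len(self.tarsus_series) != 2:
            raise ValidationError("tarsus series must contain exactly 2 points")
        if self.platform_id != "control" and self.line_index is not None:
            if not 1 <= int(self.line_index) <= 10:
                raise ValidationError("line_index must be in 1..10")

    @property
    def takeoff_window_frames(self) -> int:
        return int(round(self.post_takeoff_window_s * self.frame_rate))

    @property
    def takeoff_window_end_frame(self) -> int:
        return self.last_contact_frame + self.takeoff_window_frames

    @property
    def is_control(self) -> bool:
        return self.platform_id == "control"


#: Canonical per-jump table: identity columns followed by the derived
#: kinematic/energetic record, all in SI units (angles in degrees).
JUMP_TABLE_COLUMNS = [
    "animal_id",
    "platform_id",
    "line_index",
    "time_to_takeoff",
    "velocity",
    "elevation",
    "platform_displacement",
    "platform_displacement_angle",
    "acceleration_distance",
    "acceleration",
    "kinetic_energy",
    "kinetic_energy_density",
    "power",
    "power_density",
    "k_g",
    "k_p",
    "stiffness_ratio",
    "mass_ratio",
]


def write_jump_table(df: pd.DataFrame, path) -> None:
    """Write the canonical jump table; floats at full round-trip precision."""
    missing = [c for c in JUMP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"jump table missing columns: {missing}")
    df.loc[:, JUMP_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_jump_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in JUMP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: jump table missing columns: {missing}")
    return df


def read_morphometrics(path) -> dict[str, Morphometrics]:
    """Load per-animal morphometrics from a CSV keyed by ``animal_id``.

    Expected columns: ``animal_id, body_mass_g, tibia_length_mm,
    takeoff_angle_deg`` with optional ``femur_length_mm, muscle_mass_g,
    landmark``.  Masses in grams and lengths in millimetres, as they are
    recorded at the bench; converted to SI here.
    """
    df = pd.read_csv(path)
    out: dict[str, Morphometrics] = {}
    for _, row in df.iterrows():
        femur = row.get("femur_length_mm")
        muscle = row.get("muscle_mass_g")
        out[str(row["animal_id"])] = Morphometrics(
            animal_id=str(row["animal_id"]),
            body_mass=float(row["body_mass_g"]) * 1e-3,
            tibia_length=float(row["tibia_length_mm"]) * 1e-3,
            takeoff_angle_deg=float(row["takeoff_angle_deg"]),
            femur_length=None if pd.isna(femur) else float(femur) * 1e-3,
            muscle_mass=None if pd.isna(muscle) else float(muscle) * 1e-3,
            landmark=str(row.get("landmark", "metathoracic_joint")),
        )
    return out


def write_series(series: TrackedSeries, path, *, delimiter: str = ",") -> None:
    """Write a series in the same dialect :func:`read_tracker_export` reads."""
    series.to_frame().to_csv(path, index=False, sep=delimiter, float_format="%.17g")
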