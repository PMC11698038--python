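"""Per-jump kinematic quantities from a calibrated two-point recording.

All quantities follow the two-position measurement protocol: the body
landmark is read at the last frame of tarsi–platform contact and again
10 ms later, and the take-off velocity is the chord between those two
positions divided by the window.  Elevation is measured relative to the
deformed platform plane — the line from the platform's fixed end to the
displaced tarsus point at last contact — so that jump direction is
comparable between rigid and sagging substrates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import energetics
from .errors import DomainError, ValidationError
from .tracking_io import JumpRecording, Morphometrics

__all__ = [
    "JumpVariables",
    "take_off_velocity",
    "time_to_takeoff",
    "platform_displacement",
    "elevation",
    "acceleration_distance",
    "acceleration",
    "extract_jump_variables",
]


@dataclass(frozen=True)
class JumpVariables:
    """The full derived kinematic/energetic record for one jump (SI units)."""

    animal_id: str
    platform_id: str
    line_index: int | None
    time_to_takeoff: float  # s
    velocity: float  # m s-1
    elevation: float  # deg, relative to the deformed platform plane
    platform_displacement: float  # m
    platform_displacement_angle: float  # deg
    acceleration_distance: float  # m
    acceleration: float  # m s-2
    kinetic_energy: float  # J
    kinetic_energy_density: float  # J per kg jumping muscle
    power: float  # W
    power_density: float  # W per kg jumping muscle
    k_g: float  # N m-1, effective leg-spring stiffness
    k_p: float | None  # N m-1, platform stiffness at the jumping line
    stiffness_ratio: float | None  # k_g / k_p
    mass_ratio: float | None  # m_g / m_p

    def __post_init__(self) -> None:
        if self.time_to_takeoff < 0:
            raise ValidationError("time_to_takeoff must be non-negative")
        if self.velocity < 0:
            raise ValidationError("velocity must be non-negative")


def take_off_velocity(recording: JumpRecording) -> float:
    """Chord speed: body displacement over the 10 ms post-contact window."""
    p0 = recording.body_series.at_frame(recording.last_contact_frame)
    p1 = recording.body_series.at_frame(recording.takeoff_window_end_frame)
    return float(np.hypot(*(p1 - p0)) / recording.post_takeoff_window_s)


def takeoff_displacement(recording: JumpRecording) -> np.ndarray:
    """Body displacement vector over the post-contact window (m)."""
    p0 = recording.body_series.at_frame(recording.last_contact_frame)
    p1 = recording.body_series.at_frame(recording.takeoff_window_end_frame)
    return p1 - p0


def time_to_takeoff(recording: JumpRecording) -> float:
    """Frames from first visible leg movement to last contact, as seconds."""
    n = recording.last_contact_frame - recording.first_movement_frame
    if n < 0:
        raise ValidationError("first_movement_frame exceeds last_contact_frame")
    if n == 0:
        warnings.warn(
            f"jump {recording.animal_id}/{recording.platform_id}: zero-frame "
            "take-off interval",
            stacklevel=2,
        )
    return n / recording.frame_rate


def platform_displacement(recording: JumpRecording) -> tuple[float, float]:
    """Tarsus-point displacement (m) and deformed-plane angle (degrees).

    The displacement is the Euclidean distance moved by the tarsus contact
    point between first movement and last contact; the plane angle is the
    angle below/above horizontal of the line from the platform's fixed end
    to the displaced point (negative when the board sags).
    """
    if recording.tarsus_series is None:
        return 0.0, 0.0
    if len(recording.tarsus_series) != 2:
        raise ValidationError("tarsus series must contain exactly 2 points")
    p0 = np.array([recording.tarsus_series.x[0], recording.tarsus_series.y[0]])
    p1 = np.array([recording.tarsus_series.x[1], recording.tarsus_series.y[1]])
    disp = float(np.hypot(*(p1 - p0)))
    fixed = np.asarray(recording.fixed_end_xy, float)
    rel = p1 - fixed
    angle = math.degrees(math.atan2(rel[1], rel[0]))
    return disp, angle


def elevation(recording: JumpRecording, plane_angle_deg: float) -> float:
    """Take-off elevation (degrees) relative to the deformed platform plane.

    Positive above the plane in the jump direction; wrapped to (−180, 180].
    """
    d = takeoff_displacement(recording)
    if np.hypot(*d) == 0:
        raise DomainError("zero take-off displacement: elevation undefined")
    absolute = math.degrees(math.atan2(d[1], d[0]))
    rel = absolute - plane_angle_deg
    rel = (rel + 180.0) % 360.0 - 180.0
    return rel


def acceleration_distance(morph: Morphometrics) -> float:
    """Centre-of-mass travel during leg extension, by the law of cosines.

    The femur and tibia form two sides of a triangle hinged at the knee;
    from fully flexed to an opening angle α at take-off, the body moves
    x = sqrt(L_f² + L_t² − 2·L_f·L_t·cos α).
    """
    lf, lt = morph.femur_length, morph.tibia_length
    alpha = math.radians(morph.takeoff_angle_deg)
    return math.sqrt(lf**2 + lt**2 - 2.0 * lf * lt * math.cos(alpha))


def acceleration(v: float, t: float) -> float:
    """Mean take-off acceleration v/t."""
    if t <= 0:
        raise DomainError("time to take-off must be positive")
    return v / t


def extract_jump_variables(
    recording: JumpRecording,
    morph: Morphometrics,
    *,
    k_p: float | None = None,
    platform_mass: float | None = None,
) -> JumpVariables:
    """Derive the full per-jump record from one recording.

    ``k_p`` is the platform stiffness at the jumping line (None for control
    jumps) and ``platform_mass`` the platform's total mass; the two ratios
    are only formed when these are supplied.
    """
    v = take_off_velocity(recording)
    t = time_to_takeoff(recording)
    disp, plane_angle = platform_displacement(recording)
    elev = elevation(recording, plane_angle)
    x = acceleration_distance(morph)
    ke = energetics.kinetic_energy(morph.body_mass, v)
    ked = energetics.kinetic_energy_density(ke, morph.muscle_mass)
    if t > 0:
        p = energetics.power(ke, t)
        a = acceleration(v, t)
        pd_ = energetics.power_density(p, morph.muscle_mass)
    else:  # degenerate zero-interval jump, flagged upstream
        p = a = pd_ = float("nan")
    k_g = energetics.grasshopper_stiffness(morph.body_mass, v, x)
    s_ratio = None if k_p is None else k_g / k_p
    m_ratio = (
        None if platform_mass is None else morph.body_mass / platform_mass
    )
    return JumpVariables(
        animal_id=recording.animal_id,
        platform_id=recording.platform_id,
        line_index=recording.line_index,
        time_to_takeoff=t,
        velocity=v,
        elevation=elev,
        platform_displacement=disp,
        platform_displacement_angle=plane_angle,
        acceleration_distance=x,
        acceleration=a,
        kinetic_energy=ke,
        kinetic_energy_density=ked,
        power=p,
        power_density=pd_,
        k_g=k_g,
        k_p=k_p,
        stiffness_ratio=s_ratio,
        mass_ratio=m_ratio,
    )
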