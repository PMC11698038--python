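"""Energy, power and the effective leg-spring stiffness of a jump.

The jumper is modelled as a mass launched by an ideal linear spring: the
effective stiffness k_g is the stiffness of the spring that, released over
the leg-extension stroke x, delivers the observed take-off kinetic energy,

    ½ k_g x² = ½ m_g v²   ⇒   k_g = m_g v² / x².

Gravity is excluded from all energy bookkeeping: over the millimetre-scale
stroke and gram-scale mass involved it amounts to only 1–2% of the budget.
Density quantities (kinetic-energy density, power density) are normalized by
jumping-muscle mass, not body mass.
"""

from __future__ import annotations

import math

from .errors import DomainError
from .tracking_io import DEFAULT_MUSCLE_FRACTION

__all__ = [
    "kinetic_energy",
    "kinetic_energy_density",
    "power",
    "power_density",
    "grasshopper_stiffness",
    "launch_speed",
    "muscle_mass_from_body",
    "DEFAULT_MUSCLE_FRACTION",
]


def kinetic_energy(m_g: float, v: float) -> float:
    """Take-off kinetic energy ½·m·v² (J)."""
    if m_g <= 0:
        raise DomainError("body mass must be positive")
    return 0.5 * m_g * v * v


def kinetic_energy_density(ke: float, muscle_mass: float) -> float:
    """Kinetic energy per kilogram of jumping muscle (J kg-1)."""
    if muscle_mass <= 0:
        raise DomainError("muscle mass must be positive")
    return ke / muscle_mass


def power(ke: float, t: float) -> float:
    """Mean mechanical power KE/t over the take-off interval (W)."""
    if t <= 0:
        raise DomainError("time to take-off must be positive")
    return ke / t


def power_density(p: float, muscle_mass: float) -> float:
    """Mean power per kilogram of jumping muscle (W kg-1)."""
    if muscle_mass <= 0:
        raise DomainError("muscle mass must be positive")
    return p / muscle_mass


def grasshopper_stiffness(m_g: float, v: float, x: float) -> float:
    """Effective leg-spring stiffness k_g = m·v²/x² (N m-1)."""
    if x <= 0:
        raise DomainError("acceleration distance must be positive")
    return m_g * v * v / (x * x)


def launch_speed(k: float, m: float, x: float) -> float:
    """Take-off speed x·sqrt(k/m) of a mass launched by a linear spring."""
    if m <= 0:
        raise DomainError("mass must be positive")
    if k < 0:
        raise DomainError("stiffness must be non-negative")
    return x * math.sqrt(k / m)


def muscle_mass_from_body(
    body_mass: float, fraction: float = DEFAULT_MUSCLE_FRACTION
) -> float:
    """Jumping-muscle mass as a fraction of body mass (default 0.0418)."""
    if body_mass <= 0 or fraction <= 0:
        raise DomainError("body mass and fraction must be positive")
    return fraction * body_mass
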