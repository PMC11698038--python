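"""Cantilever platform stiffness: calibration, synthesis and ratios.

The experimental platforms are basswood diving boards clamped at one end.
Marked lines at 0.05 m spacing along the free length give a set of jumping
positions; the local stiffness at each line is measured by hanging a
calibrated weight and reading the deflection, k = m·g/δ.  For synthetic
platforms the same profile is generated from the Euler–Bernoulli end-loaded
cantilever formula k(L) = 3EI/L³.

The dimensionless stiffness and mass ratios (jumper over platform) are the
two numbers that govern whether jump energy is lost to, or recovered from,
the substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "GRAVITY",
    "LoadDeflectionTable",
    "PlatformSpec",
    "StiffnessProfile",
    "stiffness_from_load_deflection",
    "cantilever_tip_stiffness",
    "effective_tip_mass",
    "stiffness_ratio",
    "mass_ratio",
    "synthetic_stiffness_profile",
    "read_load_deflection_csv",
    "PLATFORM_A",
    "PLATFORM_B",
]

GRAVITY = 9.81  # m s-2

#: Calibrated weights available for load–deflection measurement, in kg.
CALIBRATION_MASSES_KG = (0.001, 0.002, 0.010, 0.020, 0.050, 0.100)

#: First-mode Rayleigh lumping coefficient for a uniform end-loaded cantilever.
RAYLEIGH_TIP_MASS_COEFF = 33.0 / 140.0


@dataclass(frozen=True)
class LoadDeflectionTable:
    """Load–deflection calibration entries for one marked line."""

    line_index: int
    entries: tuple[tuple[float, float], ...]  # (applied_mass kg, deflection m)

    def __post_init__(self) -> None:
        if not 1 <= self.line_index <= 10:
            raise ValidationError("line_index must be in 1..10")
        if not self.entries:
            raise ValidationError("load–deflection table needs at least one entry")
        for m, d in self.entries:
            if m <= 0:
                raise ValidationError("applied mass must be positive")
            if d <= 0:
                raise ValidationError("deflection must be positive")


@dataclass(frozen=True)
class PlatformSpec:
    """Geometry and mass of one (synthetic) cantilever platform."""

    platform_id: str
    length: float  # m
    width: float  # m
    thickness: float  # m
    total_mass: float  # kg
    elastic_modulus: float  # Pa

    def __post_init__(self) -> None:
        for name in ("length", "width", "thickness", "total_mass", "elastic_modulus"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")


#: The two experimental boards, with an effective elastic modulus chosen so
#: the ten-line profile of A brackets the study's stated stiffness span
#: (least-stiff line ≈ 30% of the jumper's ~3.4 N m-1 effective stiffness).
PLATFORM_A = PlatformSpec("A", length=0.61, width=0.025, thickness=0.002,
                          total_mass=6.34e-3, elastic_modulus=2.5e9)
PLATFORM_B = PlatformSpec("B", length=0.124, width=0.025, thickness=0.002,
                          total_mass=1.01e-3, elastic_modulus=2.5e9)


def stiffness_from_load_deflection(
    entries: Iterable[tuple[float, float]],
    *,
    g: float = GRAVITY,
    method: str = "mean",
) -> float:
    """Stiffness (N m-1) from (applied mass kg, deflection m) pairs.

    ``method="mean"`` averages the per-entry k = m·g/δ (robust to one bad
    entry, and exact division for a single entry); ``method="ols"`` fits a
    least-squares line through the origin, k = Σ(F·δ)/Σδ².
    """
    entries = list(entries)
    if not entries:
        raise ValidationError("need at least one load–deflection entry")
    masses = np.array([m for m, _ in entries], float)
    defl = np.array([d for _, d in entries], float)
    if np.any(masses <= 0):
        raise ValidationError("applied masses must be positive")
    if np.any(defl <= 0):
        raise ValidationError("deflections must be positive")
    forces = masses * g
    if method == "mean":
        return float(np.mean(forces / defl))
    if method == "ols":
        return float(np.sum(forces * defl) / np.sum(defl**2))
    raise ValidationError(f"unknown method {method!r}")


def cantilever_tip_stiffness(
    elastic_modulus: float, width: float, thickness: float, free_length: float
) -> float:
    """End-load tip stiffness 3EI/L³ of a rectangular-section cantilever."""
    if free_length <= 0:
        raise DomainError("free_length must be positive")
    for name, v in (("elastic_modulus", elastic_modulus), ("width", width),
                    ("thickness", thickness)):
        if v <= 0:
            raise ValidationError(f"{name} must be positive")
    second_moment = width * thickness**3 / 12.0
    return 3.0 * elastic_modulus * second_moment / free_length**3


def effective_tip_mass(
    platform: PlatformSpec,
    free_length: float,
    *,
    coefficient: float = RAYLEIGH_TIP_MASS_COEFF,
) -> float:
    """Lump the overhanging board into an equivalent tip mass.

    A uniform cantilever vibrating in its first mode carries 33/140 of the
    overhang mass at the tip; the coefficient is configurable for
    sensitivity analysis.
    """
    if free_length < 0 or free_length > platform.length:
        raise ValidationError("free_length must lie within the platform length")
    overhang_mass = platform.total_mass * free_length / platform.length
    return coefficient * overhang_mass


def stiffness_ratio(k_g: float, k_p: float) -> float:
    """Jumper-over-platform stiffness quotient k_g/k_p."""
    if k_p <= 0:
        raise DomainError("platform stiffness must be positive")
    return k_g / k_p


def mass_ratio(m_g: float, m_p: float) -> float:
    """Jumper-over-platform mass quotient m_g/m_p."""
    if m_p <= 0:
        raise DomainError("platform mass must be positive")
    return m_g / m_p


@dataclass(frozen=True)
class StiffnessProfile:
    """Per-line platform stiffness at marked positions from the fixed end."""

    platform_id: str
    line_index: np.ndarray  # 1-based, increasing with distance from clamp
    position: np.ndarray  # m from the fixed end
    k_p: np.ndarray  # N m-1

    def __post_init__(self) -> None:
        for name in ("line_index", "position", "k_p"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.line_index) == len(self.position) == len(self.k_p)):
            raise ValidationError("profile columns have unequal lengths")
        if np.any(self.k_p <= 0):
            raise ValidationError("all line stiffnesses must be positive")
        order = np.argsort(self.position)
        if np.any(np.diff(self.k_p[order]) >= 0):
            raise ValidationError(
                "line stiffness must decrease strictly with distance from the clamp"
            )

    def k_at_line(self, line: int) -> float:
        idx = np.flatnonzero(self.line_index == line)
        if idx.size != 1:
            raise ValidationError(
                f"platform {self.platform_id} has no line {line}"
            )
        return float(self.k_p[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "platform_id": self.platform_id,
                "line_index": self.line_index,
                "position_m": self.position,
                "k_N_per_m": self.k_p,
            }
        )


def synthetic_stiffness_profile(
    platform: PlatformSpec,
    n_lines: int = 10,
    spacing: float = 0.05,
) -> StiffnessProfile:
    """Generate a marked-line stiffness profile from beam theory.

    Line ``i`` sits ``i × spacing`` metres from the clamp; its stiffness is
    the tip stiffness of a cantilever of that free length.
    """
    if n_lines < 1:
        raise ValidationError("need at least one line")
    lines = np.arange(1, n_lines + 1)
    positions = lines * spacing
    if positions[-1] > platform.length:
        raise ValidationError(
            f"{n_lines} lines at {spacing} m spacing exceed the "
            f"{platform.length} m platform"
        )
    k = np.array(
        [
            cantilever_tip_stiffness(
                platform.elastic_modulus, platform.width, platform.thickness, L
            )
            for L in positions
        ]
    )
    return StiffnessProfile(platform.platform_id, lines, positions, k)


def read_load_deflection_csv(path, *, method: str = "mean") -> dict[str, StiffnessProfile]:
    """Build stiffness profiles from a calibration CSV.

    Expected columns: ``platform_id, line_index, applied_mass_g,
    deflection_mm`` (bench units); multiple rows per line are combined by
    ``method``.  Line positions are assigned at 0.05 m spacing.
    """
    df = pd.read_csv(path)
    needed = {"platform_id", "line_index", "applied_mass_g", "deflection_mm"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: calibration CSV missing columns {sorted(missing)}")
    profiles: dict[str, StiffnessProfile] = {}
    for pid, group in df.groupby("platform_id"):
        lines, ks = [], []
        for line, sub in group.groupby("line_index"):
            entries = [
                (m * 1e-3, d * 1e-3)
                for m, d in zip(sub["applied_mass_g"], sub["deflection_mm"])
            ]
            lines.append(int(line))
            ks.append(stiffness_from_load_deflection(entries, method=method))
        lines = np.array(lines)
        order = np.argsort(lines)
        profiles[str(pid)] = StiffnessProfile(
            str(pid), lines[order], lines[order] * 0.05, np.array(ks)[order]
        )
    return profiles


def write_stiffness_profiles(profiles: dict[str, StiffnessProfile], path) -> None:
    pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )
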