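"""Coupled jumper–platform launch simulator and synthetic recording renderer.

The jumper is a point mass m_g driven by a pre-loaded linear leg spring of
stiffness k_g and stroke x_true; the platform tip is a lumped spring–mass
(k_p, m_p_eff, light viscous damping) representing the overhanging cantilever.
Dynamics are one-dimensional along the leg-thrust axis (positions s measured
along that axis):

    m_g s̈_g = F_leg
    m_p s̈_p = −k_p s_p − c ṡ_p − F_leg

with F_leg = k_g (x_true − (s_g − s_p)) while the leg extension is below
x_true.  Contact is unilateral — the leg cannot pull — and with this force
law the contact force reaches zero exactly at full extension, which defines
take-off; flight is ballistic (gravity excluded, consistent with the energy
bookkeeping of the analysis).  The elevation angle is resolved geometrically
when the 1-D solution is rendered into the camera plane.

:func:`render_recording` turns a simulation into the same artefact the video
digitization step produces — a body-landmark series sampled at the camera
frame rate and a two-point tarsus series — with seeded Gaussian digitization
noise, so the whole measurement pipeline can be exercised against known
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import SpringboardError, ValidationError
from .tracking_io import JumpRecording, TrackedSeries

__all__ = ["SimConfig", "SimResult", "simulate", "render_recording", "sweep"]

#: Platform-tip excursions below this (m) are treated as "no visible motion"
#: when flagging a recoil-before-take-off event; 0.01 mm is an order of
#: magnitude below typical digitization noise.
RECOIL_DISPLACEMENT_FLOOR = 1e-5


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated jump.

    Defaults instantiate the study system: a 1.13 g fifth-instar jumper with
    effective leg-spring stiffness 3.42 N m-1 released over a 26 mm stroke
    at 45° elevation, filmed at 1000 frames s-1 with 0.1 mm digitization
    noise.  ``k_p`` may be ``inf`` for a perfectly rigid substrate.
    """

    m_g: float = 1.13e-3  # kg
    k_g_true: float = 3.42  # N m-1
    x_true: float = 0.026  # m, leg-extension stroke
    force_profile: str = "leg_linkage"  # or "linear_spring"
    onset_fraction: float = 0.1  # d/x_true of the leg_linkage profile
    elevation_true: float = 45.0  # deg above the platform plane
    k_p: float = 24.0  # N m-1 (inf = rigid)
    m_p_eff: float = 2.5e-4  # kg, lumped tip mass
    platform_damping_ratio: float = 0.02
    frame_rate: float = 1000.0  # frames s-1
    noise_sd: float = 1e-4  # m, per coordinate per frame
    seed: int = 0
    rtol: float = 1e-9
    atol: float = 1e-12
    t_max: float = 1.0  # s, integration guard

    def __post_init__(self) -> None:
        for name in ("m_g", "k_g_true", "x_true", "m_p_eff", "frame_rate"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not self.k_p > 0:
            raise ValidationError("k_p must be positive (inf allowed)")
        if not 0 < self.elevation_true < 180:
            raise ValidationError("elevation_true must lie in (0, 180) deg")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.platform_damping_ratio < 0:
            raise ValidationError("damping ratio must be non-negative")
        if self.force_profile not in ("leg_linkage", "linear_spring"):
            raise ValidationError(
                "force_profile must be 'leg_linkage' or 'linear_spring'"
            )
        if not self.onset_fraction > 0:
            raise ValidationError("onset_fraction must be positive")

    def leg_force(self, ext: float):
        """Contact force as a function of leg extension (vectorized).

        ``linear_spring`` is the textbook pre-compressed spring,
        F = k_g (x_true − ext): the full force appears as a step at release.
        ``leg_linkage`` (default) folds in the varying mechanical advantage
        of the extending leg, F = C (x_true − ext)(ext + d) with
        d = onset_fraction·x_true and C chosen so the work over the stroke
        is exactly ½ k_g x_true²: the ground force rises from a small value
        at full flexion, peaks mid-stroke and falls to zero at take-off, as
        measured ground-reaction profiles of spring-actuated jumps do.
        Both profiles are conservative and store the same total energy.
        """
        k, x, d = self.k_g_true, self.x_true, self.onset_fraction * self.x_true
        if self.force_profile == "linear_spring":
            return k * (x - ext)
        c = k / (x / 3.0 + d)
        return c * (x - ext) * (ext + d)

    def leg_potential(self, ext: float):
        """Elastic energy remaining in the leg spring at a given extension."""
        k, x, d = self.k_g_true, self.x_true, self.onset_fraction * self.x_true
        ext = np.clip(ext, 0.0, x)
        if self.force_profile == "linear_spring":
            return 0.5 * k * (x - ext) ** 2
        c = k / (x / 3.0 + d)
        e0 = 0.5 * k * x * x
        work = c * (x * ext**2 / 2.0 + x * d * ext - ext**3 / 3.0 - d * ext**2 / 2.0)
        return e0 - work

    @property
    def rigid(self) -> bool:
        return math.isinf(self.k_p)

    @property
    def damping_coefficient(self) -> float:
        if self.rigid:
            return 0.0
        return 2.0 * self.platform_damping_ratio * math.sqrt(self.k_p * self.m_p_eff)

    @property
    def rigid_takeoff_speed(self) -> float:
        """Closed-form speed x·sqrt(k/m) of the rigid-substrate launch."""
        return self.x_true * math.sqrt(self.k_g_true / self.m_g)


@dataclass
class SimResult:
    """Trajectories, energy ledger and event log of one simulated jump."""

    config: SimConfig
    time: np.ndarray  # frame-aligned sample times, s
    s_g: np.ndarray  # jumper position along the thrust axis, m
    v_g: np.ndarray
    s_p: np.ndarray  # platform-tip position along the thrust axis, m
    v_p: np.ndarray
    ledger: pd.DataFrame  # leg_spring_pe, jumper_ke, platform_pe, platform_ke, dissipated
    takeoff_time: float
    takeoff_speed: float  # jumper speed along the thrust axis at separation
    takeoff_velocity: np.ndarray  # 2-D (horizontal, vertical) velocity, m s-1
    max_platform_displacement: float  # m, magnitude of the largest sag
    t_max_platform_displacement: float | None
    recoil_before_takeoff: bool
    momentum_residual: float  # |system momentum − integrated wall impulse|
    _state_interp: object = field(repr=False, default=None)

    @property
    def initial_energy(self) -> float:
        return 0.5 * self.config.k_g_true * self.config.x_true**2

    @property
    def energy_drift(self) -> float:
        """Max |total ledger energy − initial stored energy| over all samples."""
        total = (
            self.ledger[
                ["leg_spring_pe", "jumper_ke", "platform_pe", "platform_ke", "dissipated"]
            ]
            .sum(axis=1)
            .to_numpy()
        )
        return float(np.max(np.abs(total - self.initial_energy)))

    def state_at(self, t: float) -> np.ndarray:
        """State vector (s_g, v_g, s_p, v_p) at an arbitrary time."""
        return self._state_interp(t)


def _rhs(t, y, cfg: SimConfig, contact: bool):
    s_g, v_g, s_p, v_p, e_diss, j_imp = y
    c = cfg.damping_coefficient
    ext = s_g - s_p
    f_leg = max(float(cfg.leg_force(ext)), 0.0) if contact else 0.0
    if cfg.rigid:
        # platform frozen; the wall transmits the full reaction
        return [v_g, f_leg / cfg.m_g, 0.0, 0.0, 0.0, f_leg]
    wall = -cfg.k_p * s_p - c * v_p
    a_p = (wall - f_leg) / cfg.m_p_eff
    return [v_g, f_leg / cfg.m_g, v_p, a_p, c * v_p * v_p, wall]


def simulate(config: SimConfig, *, post_takeoff_s: float = 0.020) -> SimResult:
    """Integrate one launch and return frame-aligned trajectories + ledger.

    The contact phase ends at the take-off event (leg extension reaching
    the stroke, equivalently contact force crossing zero); the solution then
    continues ballistically for ``post_takeoff_s`` so the post-contact
    measurement window is always covered.
    """
    cfg = config

    def takeoff_event(t, y, *args):
        return (y[0] - y[2]) - cfg.x_true

    takeoff_event.terminal = True
    takeoff_event.direction = 1

    def platform_min_event(t, y, *args):
        return y[3]  # v_p upward zero-crossing = bottom of the sag

    platform_min_event.terminal = False
    platform_min_event.direction = 1

    y0 = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    events = [takeoff_event] if cfg.rigid else [takeoff_event, platform_min_event]
    sol1 = solve_ivp(
        _rhs,
        (0.0, cfg.t_max),
        y0,
        args=(cfg, True),
        method="LSODA",
        events=events,
        dense_output=True,
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    if not sol1.success:
        raise SpringboardError(f"contact-phase integration failed: {sol1.message}; {cfg}")
    if not sol1.t_events[0].size:
        raise SpringboardError(f"no take-off within t_max={cfg.t_max}s; {cfg}")
    t_sep = float(sol1.t_events[0][0])
    y_sep = sol1.sol(t_sep)

    t_end = t_sep + post_takeoff_s
    sol2 = solve_ivp(
        _rhs,
        (t_sep, t_end),
        y_sep,
        args=(cfg, False),
        method="LSODA",
        dense_output=True,
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    if not sol2.success:
        raise SpringboardError(f"flight-phase integration failed: {sol2.message}; {cfg}")

    def state_at(t):
        t = np.asarray(t, float)
        out = np.where(t <= t_sep, sol1.sol(np.minimum(t, t_sep)), sol2.sol(np.maximum(t, t_sep)))
        return out

    # frame-aligned sampling at the camera rate
    n_frames = int(math.floor(t_end * cfg.frame_rate)) + 1
    t_frames = np.arange(n_frames) / cfg.frame_rate
    states = state_at(t_frames)
    s_g, v_g, s_p, v_p, e_diss, j_imp = states

    in_contact = t_frames <= t_sep
    ext = np.where(in_contact, s_g - s_p, cfg.x_true)
    leg_pe = cfg.leg_potential(ext)
    ledger = pd.DataFrame(
        {
            "time": t_frames,
            "leg_spring_pe": leg_pe,
            "jumper_ke": 0.5 * cfg.m_g * v_g**2,
            "platform_pe": 0.0 if cfg.rigid else 0.5 * cfg.k_p * s_p**2,
            "platform_ke": 0.5 * cfg.m_p_eff * v_p**2,
            "dissipated": e_diss,
        }
    )

    v_to = float(y_sep[1])
    theta = math.radians(cfg.elevation_true)
    v_vec = v_to * np.array([math.cos(theta), math.sin(theta)])

    # platform event bookkeeping (contact phase only)
    if cfg.rigid:
        max_disp, t_min = 0.0, None
    else:
        min_events = sol1.t_events[1]
        t_grid = np.linspace(0.0, t_sep, 2001)
        sp_grid = sol1.sol(t_grid)[2]
        i_min = int(np.argmin(sp_grid))
        max_disp = float(-sp_grid[i_min])
        if min_events.size:
            # deepest local minimum of the tip trajectory
            depths = sol1.sol(min_events)[2]
            t_min = float(min_events[int(np.argmin(depths))])
        elif max_disp > 0 and 0 < i_min < len(t_grid) - 1:
            t_min = float(t_grid[i_min])
        else:
            t_min = None
    recoil = (
        not cfg.rigid
        and max_disp > RECOIL_DISPLACEMENT_FLOOR
        and t_min is not None
        and t_min < t_sep
        and float(y_sep[3]) > 0.0
    )

    if cfg.rigid:
        momentum_residual = abs(cfg.m_g * y_sep[1] - y_sep[5])
    else:
        momentum_residual = abs(cfg.m_g * y_sep[1] + cfg.m_p_eff * y_sep[3] - y_sep[5])

    return SimResult(
        config=cfg,
        time=t_frames,
        s_g=s_g,
        v_g=v_g,
        s_p=s_p,
        v_p=v_p,
        ledger=ledger,
        takeoff_time=t_sep,
        takeoff_speed=v_to,
        takeoff_velocity=v_vec,
        max_platform_displacement=max_disp,
        t_max_platform_displacement=t_min,
        recoil_before_takeoff=bool(recoil),
        momentum_residual=float(momentum_residual),
        _state_interp=state_at,
    )


def render_recording(
    result: SimResult,
    *,
    animal_id: str = "sim",
    platform_id: str = "A",
    line_index: int | None = None,
    pre_roll_frames: int = 5,
    tip_distance: float = 0.30,
    rng: np.random.Generator | None = None,
) -> tuple[JumpRecording, dict]:
    """Render a simulation into a calibrated two-point :class:`JumpRecording`.

    The body landmark moves along the thrust axis from the origin (the
    undeflected platform surface beneath the animal); the tarsus contact
    point rides the platform tip.  Positions are sampled at the camera
    frame rate, ``pre_roll_frames`` stationary frames are prepended, and
    independent Gaussian noise of sd ``config.noise_sd`` is added to every
    coordinate.  Returns the recording plus a ground-truth dictionary.
    """
    cfg = result.config
    fps = cfg.frame_rate
    window_s = 0.010
    if result.time[-1] < result.takeoff_time + window_s:
        raise ValidationError(
            "simulation too short: does not cover last contact + 10 ms"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    theta = math.radians(cfg.elevation_true)
    u = np.array([math.cos(theta), math.sin(theta)])

    platform_label = "control" if cfg.rigid and platform_id == "control" else platform_id
    first_movement = pre_roll_frames
    last_contact = pre_roll_frames + int(math.floor(result.takeoff_time * fps))
    n_window = int(round(window_s * fps))
    n_frames = last_contact + n_window + 3

    frames = np.arange(n_frames)
    t_sim = np.clip((frames - pre_roll_frames) / fps, 0.0, None)
    states = result.state_at(t_sim)
    body = np.outer(states[0], u)  # origin at the undeflected tip surface
    body += rng.normal(0.0, cfg.noise_sd, size=body.shape)
    body_series = TrackedSeries(
        frame_index=frames,
        time=frames / fps,
        x=body[:, 0],
        y=body[:, 1],
        calibrated=True,
    )

    tarsus_series = None
    if not cfg.rigid:
        t_pair = np.array(
            [0.0, (last_contact - pre_roll_frames) / fps]
        )
        sp_pair = result.state_at(t_pair)[2]
        pts = np.outer(sp_pair, u)  # tarsus starts at the origin
        pts += rng.normal(0.0, cfg.noise_sd, size=pts.shape)
        tarsus_series = TrackedSeries(
            frame_index=np.array([first_movement, last_contact]),
            time=np.array([first_movement, last_contact]) / fps,
            x=pts[:, 0],
            y=pts[:, 1],
            calibrated=True,
        )

    recording = JumpRecording(
        body_series=body_series,
        tarsus_series=tarsus_series,
        frame_rate=fps,
        scale=1.0,
        animal_id=animal_id,
        platform_id=platform_label,
        line_index=line_index,
        first_movement_frame=first_movement,
        last_contact_frame=last_contact,
        fixed_end_xy=(-tip_distance, 0.0),
    )
    truth = {
        "animal_id": animal_id,
        "platform_id": platform_label,
        "line_index": line_index,
        "takeoff_time": result.takeoff_time,
        "takeoff_speed": result.takeoff_speed,
        "elevation_true": cfg.elevation_true,
        "k_g_true": cfg.k_g_true,
        "x_true": cfg.x_true,
        "k_p": cfg.k_p,
        "m_p_eff": cfg.m_p_eff,
        "max_platform_displacement": result.max_platform_displacement,
        "recoil_before_takeoff": result.recoil_before_takeoff,
    }
    return recording, truth


def sweep(
    base: SimConfig,
    k_p_values: Sequence[float],
    m_p_values: Sequence[float],
) -> pd.DataFrame:
    """Simulate a (k_p × m_p) grid and tabulate relative take-off performance.

    ``rel_speed`` and ``rel_KE`` are relative to the rigid-substrate launch
    of the same jumper; ``recoil_before_takeoff`` marks configurations where
    the platform bottoms out and moves back upward while the jumper is still
    in contact (the energy-recovery condition).
    """
    if not len(k_p_values) or not len(m_p_values):
        raise ValidationError("sweep grids must be non-empty")
    v_rigid = base.rigid_takeoff_speed
    rows = []
    for k_p in k_p_values:
        for m_p in m_p_values:
            cfg = replace(base, k_p=float(k_p), m_p_eff=float(m_p))
            res = simulate(cfg)
            rel = res.takeoff_speed / v_rigid
            rows.append(
                {
                    "k_p": float(k_p),
                    "m_p_eff": float(m_p),
                    "k_ratio": base.k_g_true / k_p,
                    "m_ratio": base.m_g / m_p,
                    "rel_speed": rel,
                    "rel_KE": rel * rel,
                    "recoil_before_takeoff": int(res.recoil_before_takeoff),
                }
            )
    return pd.DataFrame(rows)
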