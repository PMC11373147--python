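"""Pursuer-evader engagement simulation with APN guidance.

The piloted aircraft (pursuer) chases an autonomous target (evader) modeled
as a point mass.  The pursuer carries a tracking radar with limited
coverage (1.2 km) and an acquisition/processing latency (400 ms nominal,
800 ms degraded), and steers with augmented proportional navigation:

    a_N = N * V_c * lambda_dot + a_Nt * N / 2

where N is the navigation constant (3), V_c = V_p - V_e the closing
velocity, lambda_dot the line-of-sight (LOS) rotation rate, and a_Nt the
target acceleration.  The commanded acceleration is applied normal to the
pursuer's velocity vector.

Axes follow the engagement convention: X lateral, Y altitude, Z forward
range.  Two evader behaviors are provided: ``agent1`` flies a constant
forward speed with a sinusoidally varying altitude and ignores the
pursuer; ``los_proportional`` flees along the LOS with speed proportional
to the LOS rate (kept above the pursuer's speed).

A reward evaluator scores an engagement geometry for the evader with three
advantage conditions (distance band, deviation-angle limit, aspect-angle
limit); it is the reward function a reinforcement-learning evader would be
trained against, exposed here as a standalone evaluator.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

__all__ = [
    "EngagementState",
    "LOSGeometry",
    "GuidanceConfig",
    "RewardThresholds",
    "los_geometry",
    "apn_accel",
    "radar_observe",
    "simulate_engagement",
    "rl_reward",
]


def _wrap_deg(a: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclasses.dataclass
class EngagementState:
    """Instantaneous pursuer/evader kinematic state.

    Positions are metres (x lateral, y altitude, z forward); headings are
    degrees in the x-z plane measured from the +z axis toward +x.
    """

    pos_p: np.ndarray
    pos_e: np.ndarray
    v_p: float
    v_e: float
    psi_p: float
    psi_e: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.pos_p = np.asarray(self.pos_p, float)
        self.pos_e = np.asarray(self.pos_e, float)
        if self.pos_p.shape != (3,) or self.pos_e.shape != (3,):
            raise ValueError("positions must be 3-vectors")
        if not (np.all(np.isfinite(self.pos_p)) and np.all(np.isfinite(self.pos_e))):
            raise ValueError("positions must be finite")
        if self.v_p < 0 or self.v_e < 0:
            raise ValueError("speeds must be non-negative")


@dataclasses.dataclass
class LOSGeometry:
    """Line-of-sight geometry between pursuer and evader.

    ``lam`` is the LOS (Euclidean) distance; ``lambda_dot`` the LOS
    rotation rate in rad/s (None when no previous state was supplied);
    ``v_c`` the closing speed V_p - V_e; ``d_t`` the distance entering the
    reward conditions (identical to ``lam``); ``mu``/``eta`` the deviation
    and aspect angles in degrees, NaN-flagged when the aircraft coincide.
    """

    lam: float
    lambda_dot: float | None
    v_c: float
    d_t: float
    mu: float
    eta: float
    defined: bool = True


@dataclasses.dataclass(frozen=True)
class GuidanceConfig:
    """Pursuer guidance and radar model parameters."""

    nav_constant: float = 3.0
    a_nt: float = 0.0                 # target acceleration fed forward, m/s^2
    radar_latency: float = 0.4        # s (0.8 in the degraded conditions)
    radar_range: float = 1200.0       # m
    step: float = 0.01                # s, integration step
    evader_los_gain: float = 2.0e4    # (m/s) per (rad/s) for los_proportional
    evader_speed_margin: float = 10.0 # keeps V_e > V_p when fleeing
    max_accel: float = 100.0          # m/s^2 lateral clamp (~10 g)
    lambda_dot_convention: str = "angle"  # "angle" (LOS rate) or "range"

    def __post_init__(self) -> None:
        if self.radar_latency < 0:
            raise ValueError("radar latency must be >= 0")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.lambda_dot_convention not in ("angle", "range"):
            raise ValueError("lambda_dot_convention must be 'angle' or 'range'")


@dataclasses.dataclass(frozen=True)
class RewardThresholds:
    """Advantage-condition thresholds for the evader reward."""

    d_min: float
    d_max: float
    mu_max: float
    eta_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.d_min < self.d_max):
            raise ValueError("need 0 <= d_min < d_max")
        if self.mu_max <= 0 or self.eta_max <= 0:
            raise ValueError("angle limits must be positive")


def los_geometry(
    s: EngagementState, prev: EngagementState | None = None
) -> LOSGeometry:
    """LOS distance, rate, closing speed and reward angles for a state.

    ``lambda_dot`` needs a previous state (finite difference); by default
    it is the rotation rate of the LOS unit vector (rad/s, the quantity a
    proportional-navigation law consumes).  ``mu`` (deviation) and ``eta``
    (aspect) use the two-argument arctangent of the lateral over forward
    separation, wrapped to (-180, 180].
    """
    r = s.pos_e - s.pos_p
    lam = float(np.linalg.norm(r))
    v_c = s.v_p - s.v_e
    if lam == 0.0:
        return LOSGeometry(0.0, None, v_c, 0.0, math.nan, math.nan, defined=False)
    dx_pe = s.pos_p[0] - s.pos_e[0]
    dz_pe = s.pos_p[2] - s.pos_e[2]
    mu = _wrap_deg(180.0 + s.psi_p - math.degrees(math.atan2(dx_pe, dz_pe)))
    eta = _wrap_deg(s.psi_e - math.degrees(math.atan2(-dx_pe, -dz_pe)))
    lambda_dot = None
    if prev is not None:
        dt = s.time - prev.time
        if dt <= 0:
            raise ValueError("previous state must be strictly earlier")
        r_prev = prev.pos_e - prev.pos_p
        lam_prev = float(np.linalg.norm(r_prev))
        if lam_prev > 0:
            u_now = r / lam
            u_prev = r_prev / lam_prev
            cosang = float(np.clip(np.dot(u_now, u_prev), -1.0, 1.0))
            sinang = float(np.linalg.norm(np.cross(u_prev, u_now)))
            lambda_dot = math.atan2(sinang, cosang) / dt
    return LOSGeometry(lam, lambda_dot, v_c, lam, mu, eta)


def apn_accel(g: LOSGeometry, c: GuidanceConfig) -> float:
    """Augmented proportional-navigation acceleration command, m/s^2."""
    if g.lambda_dot is None:
        raise ValueError("geometry has no LOS rate; supply a previous state")
    return c.nav_constant * g.v_c * g.lambda_dot + c.a_nt * c.nav_constant / 2.0


def radar_observe(
    history: list[EngagementState], t: float, c: GuidanceConfig
) -> EngagementState | None:
    """Latency-delayed, range-limited evader observation.

    Returns the recorded state at ``t - latency`` (the most recent record
    not newer than that time) when the evader was within radar coverage at
    that instant; None when the history does not reach back far enough or
    the target was outside the 1.2 km coverage.
    """
    if not history:
        return None
    t_obs = t - c.radar_latency
    if t_obs < history[0].time - 1e-12:
        return None
    # history is appended in time order; scan back for the newest state <= t_obs
    state = None
    for rec in reversed(history):
        if rec.time <= t_obs + 1e-12:
            state = rec
            break
    if state is None:
        return None
    rng = float(np.linalg.norm(state.pos_e - state.pos_p))
    if rng > c.radar_range:
        return None
    return state


def _heading_vec(psi_deg: float) -> np.ndarray:
    rad = math.radians(psi_deg)
    return np.array([math.sin(rad), 0.0, math.cos(rad)])


def _psi_of(vel: np.ndarray) -> float:
    return math.degrees(math.atan2(vel[0], vel[2]))


@dataclasses.dataclass
class EngagementResult:
    """Trajectory table plus closest-approach summary."""

    trajectory: pd.DataFrame
    min_lambda: float
    t_closest: float


def simulate_engagement(
    initial: EngagementState,
    c: GuidanceConfig,
    evader_mode: str = "agent1",
    duration: float = 20.0,
    pursuer_mode: str = "apn",
    altitude_amplitude: float = 50.0,
    altitude_period: float = 20.0,
    thresholds: RewardThresholds | None = None,
) -> EngagementResult:
    """Fixed-step point-mass engagement between pursuer and evader.

    The pursuer holds constant speed; with ``pursuer_mode="apn"`` its
    velocity direction is steered each step by the APN command computed
    from radar-delayed observations of the evader (it flies straight while
    no observation is available); ``pursuer_mode="straight"`` is the
    unguided baseline.  Evader modes: ``agent1`` (constant forward speed,
    sinusoidal altitude, unaware of the pursuer) or ``los_proportional``
    (flees along the LOS at a speed proportional to the LOS rate, never
    slower than the pursuer).
    """
    if duration <= 0 or c.step <= 0:
        raise ValueError("duration and step must be positive")
    n_steps = round(duration / c.step)
    if abs(n_steps * c.step - duration) > 1e-9:
        raise ValueError("step must divide duration")
    if evader_mode not in ("agent1", "los_proportional"):
        raise ValueError(f"unknown evader mode {evader_mode!r}")
    if pursuer_mode not in ("apn", "straight"):
        raise ValueError(f"unknown pursuer mode {pursuer_mode!r}")

    dt = c.step
    pos_p = initial.pos_p.astype(float).copy()
    pos_e = initial.pos_e.astype(float).copy()
    v_p = float(initial.v_p)
    vel_p = v_p * _heading_vec(initial.psi_p)
    v_e = float(initial.v_e)
    e_dir = _heading_vec(initial.psi_e)
    alt0 = float(pos_e[1])

    history: list[EngagementState] = []
    u_obs_prev: np.ndarray | None = None
    lam_obs_prev: float | None = None
    rows = []
    prev_state: EngagementState | None = None

    for k in range(n_steps + 1):
        t = k * dt
        state = EngagementState(
            pos_p.copy(), pos_e.copy(), v_p, v_e, _psi_of(vel_p), _psi_of(e_dir), t
        )
        history.append(state)
        geo = los_geometry(state, prev_state)
        prev_state = state

        # --- pursuer guidance ---
        a_vec = np.zeros(3)
        a_n = 0.0
        if pursuer_mode == "apn":
            obs = radar_observe(history, t, c)
            if obs is not None:
                r_obs = obs.pos_e - pos_p
                lam_obs = float(np.linalg.norm(r_obs))
                if lam_obs > 0:
                    u_obs = r_obs / lam_obs
                    if u_obs_prev is not None:
                        cosang = float(np.clip(np.dot(u_obs, u_obs_prev), -1, 1))
                        axis = np.cross(u_obs_prev, u_obs)
                        sinang = float(np.linalg.norm(axis))
                        ld = math.atan2(sinang, cosang) / dt
                        if c.lambda_dot_convention == "range" and lam_obs_prev is not None:
                            ld = abs(lam_obs - lam_obs_prev) / dt
                        v_hat = vel_p / max(np.linalg.norm(vel_p), 1e-12)
                        if sinang > 1e-12:
                            omega = axis / sinang * ld
                            steer = np.cross(omega, v_hat)
                            sn = np.linalg.norm(steer)
                            if sn > 1e-12:
                                a_n = c.nav_constant * geo.v_c * ld \
                                    + c.a_nt * c.nav_constant / 2.0
                                a_n = float(np.clip(a_n, -c.max_accel, c.max_accel))
                                a_vec = a_n * steer / sn
                    u_obs_prev = u_obs
                    lam_obs_prev = lam_obs

        row = {
            "t": t,
            "xp": pos_p[0], "yp": pos_p[1], "zp": pos_p[2],
            "xe": pos_e[0], "ye": pos_e[1], "ze": pos_e[2],
            "lambda": geo.lam,
            "lambda_dot": geo.lambda_dot if geo.lambda_dot is not None else math.nan,
            "a_n": a_n,
        }
        if thresholds is not None:
            row["reward"] = rl_reward(geo, thresholds)[0]
        rows.append(row)
        if k == n_steps:
            break

        # --- integrate pursuer ---
        vel_p = vel_p + a_vec * dt
        nv = np.linalg.norm(vel_p)
        if nv > 0:
            vel_p = vel_p * (v_p / nv)  # constant-speed point mass
        pos_p = pos_p + vel_p * dt

        # --- integrate evader ---
        if evader_mode == "agent1":
            pos_e = pos_e + v_e * e_dir * dt
            pos_e[1] = alt0 + altitude_amplitude * math.sin(
                2.0 * math.pi * (t + dt) / altitude_period
            )
        else:  # los_proportional
            away = pos_e - pos_p
            d = np.linalg.norm(away)
            if d > 0:
                flee = away / d
                flee[1] = 0.0  # altitude hold while fleeing
                fn = np.linalg.norm(flee)
                if fn > 0:
                    e_dir = flee / fn
            ld_mag = geo.lambda_dot if geo.lambda_dot is not None else 0.0
            v_e = max(v_p + c.evader_speed_margin, c.evader_los_gain * abs(ld_mag))
            pos_e = pos_e + v_e * e_dir * dt

    traj = pd.DataFrame(rows)
    i_min = int(traj["lambda"].idxmin())
    return EngagementResult(
        trajectory=traj,
        min_lambda=float(traj["lambda"].iloc[i_min]),
        t_closest=float(traj["t"].iloc[i_min]),
    )


def rl_reward(
    g: LOSGeometry,
    r: RewardThresholds,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[float, tuple[bool, bool, bool]]:
    """Evader advantage reward for a geometry.

    Three strict-inequality conditions: the distance lies in
    ``(d_min, d_max)``, the deviation-angle magnitude is below ``mu_max``
    and the aspect-angle magnitude below ``eta_max``.  The reward is the
    weighted count of satisfied conditions (unit weights by default).
    Undefined geometries (coincident aircraft) satisfy nothing.
    """
    if not g.defined:
        return 0.0, (False, False, False)
    f_dist = r.d_min < g.d_t < r.d_max
    f_mu = abs(_wrap_deg(g.mu)) < r.mu_max
    f_eta = abs(_wrap_deg(g.eta)) < r.eta_max
    flags = (bool(f_dist), bool(f_mu), bool(f_eta))
    reward = float(sum(w for w, f in zip(weights, flags) if f))
    return reward, flags
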