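"""Seeded synthetic gaze / pupil / EEG / stick sessions.

Emulates the data streams of a participants-by-conditions flight-simulator
workload study so that every analysis stage is testable without recorded
data.  Each condition carries a latent task-difficulty scalar in [0, 1];
the generator plants linear difficulty effects with the direction pattern
the workload literature reports:

* pupil diameter and its slow (< 0.5 Hz) variability increase,
* fixation rate increases and mean fixation duration decreases,
* gaze dispersion (NNI) decreases as scanning concentrates on the target,
* frontal theta rises and parietal alpha falls (task-load index up),
* frontal beta falls (task-engagement index down),
* stick bursts become more frequent and more aggressive (PIW up).

Participant heterogeneity enters as log-normal multipliers on each effect
channel, drawn once per participant and held fixed across that
participant's conditions.  The first 5 s of every stream is a quiet
resting baseline (used downstream for pupil normalization).  Blink gaps of
100-400 ms arrive at Poisson times and are marked invalid; they are
planted inside fixation plateaus so the planted fixation structure stays
well defined.

Streams run on independent clocks (eye 120 Hz, EEG 128 Hz, stick 120 Hz)
sharing the session's t = 0; nothing is cross-resampled.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import signal as sps

from .eeg import BANDS, ELECTRODES_32, TEI_MONTAGES, TLI_ALPHA_SET, TLI_THETA_SET
from .inceptor import StickSeries
from .ocular import GazeSeries

__all__ = [
    "StudyDesign",
    "EffectProfile",
    "SessionData",
    "participant_multipliers",
    "generate_session",
    "generate_study",
]

BASELINE_S = 5.0


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Shape of the study: who, how many conditions, how long, how sampled."""

    n_participants: int = 12
    condition_difficulties: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    session_duration: float = 60.0
    eye_rate: float = 120.0
    eeg_rate: float = 128.0
    stick_rate: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not all(0.0 <= d <= 1.0 for d in self.condition_difficulties):
            raise ValueError("condition difficulties must lie in [0, 1]")
        if min(self.eye_rate, self.eeg_rate, self.stick_rate) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.session_duration <= BASELINE_S:
            raise ValueError(
                f"session duration must exceed the {BASELINE_S} s baseline window"
            )

    @property
    def n_conditions(self) -> int:
        return len(self.condition_difficulties)


@dataclasses.dataclass(frozen=True)
class EffectProfile:
    """Planted difficulty effects and participant heterogeneity.

    Signs are constrained so the generated study reproduces the expected
    direction pattern (see module docstring); magnitudes are free
    parameters of the generator.
    """

    pd_drift_gain: float = 0.15            # mm of slow drift per unit difficulty
    fixation_duration_base: float = 0.60   # s at difficulty 0
    fixation_duration_slope: float = -0.35 # s per unit difficulty (negative)
    gaze_dispersion_slope: float = -0.55   # focus-fraction slope (negative)
    frontal_theta_gain: float = 1.0        # amplitude scale per unit difficulty
    parietal_alpha_gain: float = -0.4
    beta_gain: float = -0.3
    stick_burst_rate_gain: float = 0.08    # bursts/s per unit difficulty
    stick_amplitude_gain: float = 1.5      # relative amplitude per unit difficulty
    participant_sd: float = 0.2            # log-scale between-participant sd
    blink_rate: float = 0.15               # blinks/s after the baseline window
    stick_burst_rate_base: float = 0.10    # bursts/s at difficulty 0
    stick_amplitude_base: float = 6.0      # deg
    stick_delta_max: float = 20.0          # deg
    focus_fraction_base: float = 0.25      # fraction of fixations on target at d=0

    def __post_init__(self) -> None:
        if self.pd_drift_gain <= 0:
            raise ValueError("pd_drift_gain must be positive (PD rises with load)")
        if self.fixation_duration_slope >= 0:
            raise ValueError("fixation_duration_slope must be negative")
        if self.gaze_dispersion_slope >= 0:
            raise ValueError("gaze_dispersion_slope must be negative (NNI falls)")
        if self.frontal_theta_gain <= 0:
            raise ValueError("frontal_theta_gain must be positive (TLI rises)")
        if self.parietal_alpha_gain >= 0:
            raise ValueError("parietal_alpha_gain must be negative (TLI rises)")
        if self.beta_gain > 0:
            raise ValueError("beta_gain must be <= 0 (TEI falls)")
        if self.stick_burst_rate_gain <= 0 or self.stick_amplitude_gain <= 0:
            raise ValueError("stick gains must be positive (PIW rises)")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be >= 0")
        base = self.fixation_duration_base
        if base + self.fixation_duration_slope <= 0.05:
            raise ValueError("fixation duration would collapse at difficulty 1")


@dataclasses.dataclass
class SessionData:
    """One simulated session: all three streams plus planted ground truth."""

    participant: int
    condition: int
    difficulty: float
    gaze: GazeSeries
    eeg: pd.DataFrame
    stick: StickSeries
    planted: dict


def participant_multipliers(design: StudyDesign, participant: int) -> dict[str, float]:
    """Log-normal per-participant effect multipliers, stable across conditions."""
    rng = np.random.default_rng([design.seed, 777, participant])
    z = rng.standard_normal(6)  # scaled by effects.participant_sd at use sites
    keys = ["pd", "fixdur", "dispersion", "eeg", "stick", "pd_baseline"]
    return {k: float(v) for k, v in zip(keys, z)}


def _mult(z: float, sd: float) -> float:
    return math.exp(sd * z)


# ---------------------------------------------------------------------------
# gaze + pupil stream


def _angular_sep_deg(a: np.ndarray, b: np.ndarray) -> float:
    va = np.array([a[0], a[1], 1.0])
    vb = np.array([b[0], b[1], 1.0])
    va /= np.linalg.norm(va)
    vb /= np.linalg.norm(vb)
    dot = float(np.clip(np.dot(va, vb), -1.0, 1.0))
    return math.degrees(math.acos(dot))


def _draw_center(
    rng: np.random.Generator,
    d_eff: float,
    effects: EffectProfile,
    m_disp: float,
    prev: np.ndarray | None,
) -> np.ndarray:
    """Next fixation centre in plane coordinates, >= 1.2 deg from prev."""
    focus_frac = float(
        np.clip(
            effects.focus_fraction_base - effects.gaze_dispersion_slope * d_eff * m_disp,
            0.0,
            0.92,
        )
    )
    focus_center = np.array([0.03, 0.02])
    for _ in range(50):
        if rng.uniform() < focus_frac:
            c = focus_center + rng.normal(0.0, 0.008, size=2)
        else:
            c = rng.uniform(-0.22, 0.22, size=2)
        if prev is None or _angular_sep_deg(c, prev) >= 1.2:
            return c
    # fall back: push away from prev along a random direction
    direction = rng.normal(size=2)
    direction /= np.linalg.norm(direction)
    return prev + direction * 0.025


def _gen_gaze_pupil(
    rng: np.random.Generator,
    design: StudyDesign,
    effects: EffectProfile,
    d: float,
    mults: dict[str, float],
) -> tuple[GazeSeries, dict]:
    sd = effects.participant_sd
    m_fix = _mult(mults["fixdur"], sd)
    m_disp = _mult(mults["dispersion"], sd)
    m_pd = _mult(mults["pd"], sd)

    rate = design.eye_rate
    n = round(design.session_duration * rate)
    t = np.arange(n) / rate
    plane = np.empty((n, 2))

    # --- fixation plateau / saccade alternation ---
    segments: list[tuple[int, int]] = []  # plateau [start, end] sample indices
    durations_planted: list[float] = []
    jitter_sd = 0.0004  # plane units, ~0.02 deg sample-to-sample
    idx = 0
    center = _draw_center(rng, 0.0, effects, m_disp, None)
    while idx < n:
        d_eff = 0.0 if t[idx] < BASELINE_S else d
        mean_dur = (
            effects.fixation_duration_base + effects.fixation_duration_slope * d_eff
        ) * m_fix
        dur_fix = max(0.12, rng.normal(mean_dur, 0.15 * effects.fixation_duration_base))
        n_fix = max(3, round(dur_fix * rate))
        end = min(idx + n_fix - 1, n - 1)
        plane[idx : end + 1] = center + rng.normal(0.0, jitter_sd, size=(end - idx + 1, 2))
        segments.append((idx, end))
        durations_planted.append((end - idx) / rate)
        idx = end + 1
        if idx >= n:
            break
        # saccade to the next centre: linear sweep fast enough that every
        # inter-sample interval exceeds the 30 deg/s I-VT threshold
        new_center = _draw_center(rng, d_eff, effects, m_disp, center)
        sep = _angular_sep_deg(center, new_center)
        n_int = max(1, min(8, int(sep * 3)))
        n_sacc = n_int - 1
        for j in range(n_sacc):
            if idx >= n:
                break
            frac = (j + 1) / n_int
            plane[idx] = center + frac * (new_center - center)
            idx += 1
        center = new_center

    dirs = np.column_stack([plane[:, 0], plane[:, 1], np.ones(n)])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    # --- blinks: invalid gaps planted inside plateaus ---
    valid = np.ones(n, dtype=bool)
    margin = 3  # samples kept valid at each plateau edge
    n_blinks = rng.poisson(effects.blink_rate * (design.session_duration - BASELINE_S))
    arrivals = np.sort(
        rng.uniform(BASELINE_S, design.session_duration, size=n_blinks)
    )
    used: set[int] = set()
    blink_samples = 0
    for arr in arrivals:
        gap = rng.uniform(0.10, 0.40)
        gap_n = round(gap * rate)
        placed = False
        for si, (s0, s1) in enumerate(segments):
            if si in used or t[s0] < BASELINE_S:
                continue
            interior0, interior1 = s0 + margin, s1 - margin
            if interior1 <= interior0 or interior1 >= n:
                continue  # plateau too short (or truncated at series end)
            if t[interior0] < arr - 1.0:
                continue  # only consider plateaus near/after the arrival
            if interior1 - interior0 + 1 >= gap_n:
                start = interior0 + rng.integers(0, interior1 - interior0 + 2 - gap_n)
                valid[start : start + gap_n] = False
                blink_samples += gap_n
                used.add(si)
                placed = True
                break
        if not placed:
            continue

    # --- pupil diameter ---
    base_pd = 3.5 * (1.0 + 0.06 * mults["pd_baseline"])
    ramp = np.clip((t - BASELINE_S) / 2.0, 0.0, 1.0)
    freqs = rng.uniform(0.05, 0.35, size=4)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
    amps = rng.uniform(0.5, 1.0, size=4)
    slow = np.zeros(n)
    for f, ph, a in zip(freqs, phases, amps):
        slow += a * np.sin(2.0 * np.pi * f * t + ph)
    slow /= max(np.std(slow), 1e-12)  # unit-RMS slow fluctuation
    drift_amp = d * effects.pd_drift_gain * m_pd
    level = drift_amp * (0.6 + 0.55 * slow) * ramp

    def _eye_trace(seed_shift: float) -> np.ndarray:
        hippus = 0.02 * np.sin(2.0 * np.pi * 1.2 * t + seed_shift)
        noise = rng.normal(0.0, 0.008, size=n)
        return base_pd + level + hippus + noise

    pd_left = _eye_trace(rng.uniform(0, 2 * np.pi))
    pd_right = 0.98 * base_pd + 0.95 * level + 0.02 * np.sin(
        2.0 * np.pi * 1.15 * t + rng.uniform(0, 2 * np.pi)
    ) + rng.normal(0.0, 0.008, size=n)

    # tracker reports zeros while the pupil is lost
    pd_left[~valid] = 0.0
    pd_right[~valid] = 0.0

    gaze = GazeSeries(t=t, dir=dirs, pd_left=pd_left, pd_right=pd_right, valid=valid)
    planted = {
        "n_fixations": len(segments),
        "mean_plateau_duration": float(np.mean(durations_planted)),
        "pd_drift_amplitude": drift_amp,
        "blink_samples": blink_samples,
        "n_blinks_placed": len(used),
    }
    return gaze, planted


# ---------------------------------------------------------------------------
# EEG stream


_BAND_BASE_RMS = {"theta": 4.0, "alpha": 5.0, "beta": 3.0, "gamma": 1.5}  # uV


def _gen_eeg(
    rng: np.random.Generator,
    design: StudyDesign,
    effects: EffectProfile,
    d: float,
    mults: dict[str, float],
) -> tuple[pd.DataFrame, dict]:
    sd = effects.participant_sd
    m_eeg = _mult(mults["eeg"], sd)
    fs = design.eeg_rate
    n = round(design.session_duration * fs)
    t = np.arange(n) / fs
    n_e = len(ELECTRODES_32)
    ramp = np.clip((t - BASELINE_S) / 2.0, 0.0, 1.0)

    frontal_idx = [ELECTRODES_32.index(e) for e in TLI_THETA_SET]
    parietal_idx = [ELECTRODES_32.index(e) for e in TLI_ALPHA_SET]

    scales = {band: np.ones((n, n_e)) for band in BANDS}
    theta_gain = 1.0 + effects.frontal_theta_gain * d * m_eeg
    alpha_gain = 1.0 + effects.parietal_alpha_gain * d
    beta_gain = 1.0 + effects.beta_gain * d
    scales["theta"][:, frontal_idx] = 1.0 + (theta_gain - 1.0) * ramp[:, None]
    scales["alpha"][:, parietal_idx] = 1.0 + (alpha_gain - 1.0) * ramp[:, None]
    scales["beta"][:, frontal_idx] = 1.0 + (beta_gain - 1.0) * ramp[:, None]

    data = rng.normal(0.0, 1.0, size=(n, n_e))  # broadband floor, 1 uV RMS
    for band, (lo, hi) in BANDS.items():
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        comp = sps.sosfiltfilt(sos, rng.standard_normal((n, n_e)), axis=0)
        comp /= np.maximum(comp.std(axis=0, keepdims=True), 1e-12)
        data += _BAND_BASE_RMS[band] * scales[band] * comp

    eeg = pd.DataFrame(data, columns=list(ELECTRODES_32))
    eeg.insert(0, "t", t)
    planted = {
        "theta_scale": theta_gain,
        "alpha_scale": alpha_gain,
        "beta_scale": beta_gain,
    }
    return eeg, planted


# ---------------------------------------------------------------------------
# stick stream


def _gen_stick(
    rng: np.random.Generator,
    design: StudyDesign,
    effects: EffectProfile,
    d: float,
    mults: dict[str, float],
) -> tuple[StickSeries, dict]:
    sd = effects.participant_sd
    m_stick = _mult(mults["stick"], sd)
    rate = design.stick_rate
    dur = design.session_duration
    n = round(dur * rate)
    t = np.arange(n) / rate
    delta = np.zeros(n)
    active = t >= BASELINE_S
    delta[active] += rng.normal(0.0, 0.02, size=int(active.sum()))

    n_bursts = max(1, round(
        (effects.stick_burst_rate_base + effects.stick_burst_rate_gain * d)
        * (dur - BASELINE_S)
    ))
    slot_edges = np.linspace(BASELINE_S + 0.3, dur - 0.3, n_bursts + 1)
    amp_nominal = effects.stick_amplitude_base * (1.0 + effects.stick_amplitude_gain * d)
    amps = []
    for b in range(n_bursts):
        width = rng.uniform(0.3, 0.6)
        lo, hi = slot_edges[b], slot_edges[b + 1] - width
        if hi <= lo:
            continue
        t0 = rng.uniform(lo, hi)
        amp = amp_nominal * m_stick * rng.uniform(0.85, 1.15)
        amp = min(amp, 0.95 * effects.stick_delta_max)
        amp *= rng.choice([-1.0, 1.0])
        sel = (t >= t0) & (t < t0 + width)
        delta[sel] += amp * np.sin(np.pi * (t[sel] - t0) / width) ** 2
        amps.append(abs(amp))

    np.clip(delta, -effects.stick_delta_max, effects.stick_delta_max, out=delta)
    stick = StickSeries(t=t, delta=delta, delta_max=effects.stick_delta_max)
    planted = {
        "n_bursts": len(amps),
        "mean_burst_amplitude": float(np.mean(amps)) if amps else 0.0,
    }
    return stick, planted


# ---------------------------------------------------------------------------
# sessions and studies


def generate_session(
    design: StudyDesign,
    effects: EffectProfile,
    participant: int,
    condition: int,
    seed: int | None = None,
) -> SessionData:
    """One session's three streams for (participant, condition).

    Deterministic in ``(design, effects, seed, participant, condition)``;
    the participant's effect multipliers depend only on the seed and the
    participant index, so they are shared across that participant's
    conditions.
    """
    if not (0 <= participant < design.n_participants):
        raise ValueError(f"participant index {participant} outside the design")
    if not (0 <= condition < design.n_conditions):
        raise ValueError(f"condition index {condition} outside the design")
    if seed is None:
        seed = design.seed
    d = design.condition_difficulties[condition]
    mults = participant_multipliers(
        dataclasses.replace(design, seed=seed), participant
    )

    rng_gaze = np.random.default_rng([seed, 11, participant, condition])
    rng_eeg = np.random.default_rng([seed, 22, participant, condition])
    rng_stick = np.random.default_rng([seed, 33, participant, condition])

    gaze, planted_g = _gen_gaze_pupil(rng_gaze, design, effects, d, mults)
    eeg, planted_e = _gen_eeg(rng_eeg, design, effects, d, mults)
    stick, planted_s = _gen_stick(rng_stick, design, effects, d, mults)

    planted = {"difficulty": d, **planted_g, **planted_e, **planted_s}
    return SessionData(
        participant=participant,
        condition=condition,
        difficulty=d,
        gaze=gaze,
        eeg=eeg,
        stick=stick,
        planted=planted,
    )


def generate_study(
    design: StudyDesign, effects: EffectProfile | None = None
) -> list[SessionData]:
    """All participants x conditions sessions.

    Condition order is randomized independently per participant (order-
    effect nullification); the randomized position is recorded in
    ``planted["order_index"]`` while rows stay identified by their true
    condition index.
    """
    if effects is None:
        effects = EffectProfile()
    sessions: list[SessionData] = []
    for p in range(design.n_participants):
        order_rng = np.random.default_rng([design.seed, 555, p])
        order = order_rng.permutation(design.n_conditions)
        for pos, c in enumerate(order):
            s = generate_session(design, effects, p, int(c))
            s.planted["order_index"] = pos
            sessions.append(s)
    return sessions
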