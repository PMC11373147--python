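"""Inceptor-control workload: duty cycle, aggressiveness and PIW.

The pilot's stick time history is the task-difficulty baseline the
physiological metrics are validated against.  Two standard handling-
qualities statistics are computed from the deflection stream:

* **Duty cycle (DC)** — the percentage of time the stick is actively used.
  A sample increment counts as active when the per-increment deflection
  change meets the noise threshold (0.5 % of the inceptor's total
  displacement range, i.e. ``2 * delta_max``, per time increment) or the
  stick is at full deflection.
* **Aggressiveness** — the RMS rate of change of stick deflection (deg/s);
  abrupt, high-bandwidth inputs raise it.

**PIW** (pilot inceptor workload) is their product; it rises directly with
task difficulty.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "StickSeries",
    "duty_cycle",
    "aggressiveness",
    "piw",
    "compute_inceptor_metrics",
]

NOISE_THRESHOLD_FRACTION = 0.005  # of total displacement range, per increment


@dataclasses.dataclass
class StickSeries:
    """Timestamped stick deflections (degrees) with displacement limits."""

    t: np.ndarray
    delta: np.ndarray
    delta_max: float
    noise_threshold: float = NOISE_THRESHOLD_FRACTION

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.delta = np.asarray(self.delta, float)
        if self.t.size != self.delta.size:
            raise ValueError("t and delta must have one length")
        if self.t.size < 2:
            raise ValueError("need at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.delta_max <= 0:
            raise ValueError("delta_max must be positive")
        if np.any(np.abs(self.delta) > self.delta_max + 1e-9):
            raise ValueError("deflections exceed delta_max")

    def __len__(self) -> int:
        return self.t.size


def _activity(s: StickSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-increment activity indicator x_i (i = 2..n) and increments dt."""
    dt = np.diff(s.t)
    dd = np.abs(np.diff(s.delta))
    # 0.5 % of the total displacement range (both stick directions) per
    # time increment, compared against the per-increment deflection change
    thresh = s.noise_threshold * (2.0 * s.delta_max)
    at_limit = np.abs(s.delta[1:]) >= s.delta_max
    x = (dd >= thresh) | at_limit
    return x, dt


def duty_cycle(s: StickSeries, method: str = "time") -> float:
    """Duty cycle: percentage of time with active stick inputs.

    With ``method="time"`` (default) each active increment contributes its
    own time increment and the result is active time over total measured
    time, a true percentage bounded by 100.  ``method="count"`` is the
    literal indicator-count reading, ``100 * sum(x_i) / (n - 1)``; the two
    agree on a uniform sampling grid.
    """
    x, dt = _activity(s)
    if dt.sum() <= 0:
        raise ValueError("degenerate time span")
    if method == "time":
        return 100.0 * float(dt[x].sum() / dt.sum())
    if method == "count":
        return 100.0 * float(x.mean())
    raise ValueError(f"unknown duty-cycle method {method!r}")


def aggressiveness(s: StickSeries) -> float:
    """RMS rate of stick deflection change, deg/s."""
    dt = np.diff(s.t)
    rates = np.diff(s.delta) / dt
    return float(np.sqrt(np.mean(rates**2)))


def piw(dc: float, agg: float) -> float:
    """Pilot inceptor workload: duty cycle x aggressiveness."""
    if not (np.isfinite(dc) and np.isfinite(agg)):
        raise ValueError("duty cycle and aggressiveness must be finite")
    if dc < 0 or agg < 0:
        raise ValueError("duty cycle and aggressiveness must be non-negative")
    return dc * agg


def compute_inceptor_metrics(s: StickSeries) -> dict[str, float]:
    """Duty cycle, aggressiveness and PIW for one session."""
    dc = duty_cycle(s)
    agg = aggressiveness(s)
    return {"duty_cycle": dc, "aggressiveness": agg, "piw": piw(dc, agg)}
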