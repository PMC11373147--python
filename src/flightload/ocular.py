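"""Ocular cognitive-load metrics.

Three families of measures are computed from a head-mounted eye tracker
stream (nominal 120 Hz):

* **Low-frequency pupil-diameter variability** (``StdDevPD``) — the pupil
  trace is cleaned (invalid frames removed and cubic-spline interpolated),
  normalized against a 5-second resting baseline to percent change
  (``%PD``), decomposed with a 7-level Haar discrete wavelet transform, and
  the sample standard deviation of the level-7 approximation component is
  reported.  At 120 Hz the level-7 approximation covers roughly 0–0.47 Hz,
  i.e. the slow dilation dynamics associated with mental effort.
* **Fixation statistics** — I-VT (velocity-threshold) fixation detection at
  30 deg/s on the gaze-direction vectors, yielding fixation rate and mean
  fixation duration.
* **Nearest-neighbour index (NNI)** — the spatial dispersion of gaze,
  defined as the mean nearest-neighbour distance of gaze points over the
  expected mean distance under complete spatial randomness
  (Clark–Evans: ``0.5 * sqrt(area / n)``).  Values below 1 indicate
  clustered scanning; high workload typically tightens the scanpath.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

__all__ = [
    "GazeSeries",
    "NormalizedPupilSeries",
    "MRAComponents",
    "FixationList",
    "preprocess_pupil",
    "normalize_pupil",
    "haar_mra",
    "pd_lowfreq_std",
    "angular_velocity",
    "detect_fixations",
    "fixation_stats",
    "project_gaze",
    "fixation_centroids",
    "nni",
    "compute_ocular_metrics",
]

VELOCITY_THRESHOLD_DEG_S = 30.0
BASELINE_WINDOW_S = 5.0
MRA_LEVELS = 7


@dataclasses.dataclass
class GazeSeries:
    """One session of eye-tracker output.

    ``dir`` holds unit gaze-direction vectors (x lateral, y vertical,
    z forward, HMD frame), one row per sample; pupil diameters are in mm.
    ``valid`` flags frames where the tracker had a pupil lock (blinks and
    tracking losses are False).
    """

    t: np.ndarray
    dir: np.ndarray
    pd_left: np.ndarray
    pd_right: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dir = np.asarray(self.dir, dtype=float)
        self.pd_left = np.asarray(self.pd_left, dtype=float)
        self.pd_right = np.asarray(self.pd_right, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if self.dir.shape != (n, 3):
            raise ValueError(f"dir must be (n, 3); got {self.dir.shape} for n={n}")
        if not (self.pd_left.size == self.pd_right.size == self.valid.size == n):
            raise ValueError("all GazeSeries fields must share one length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        norms = np.linalg.norm(self.dir[self.valid], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gaze directions must be unit vectors on valid samples")

    def __len__(self) -> int:
        return self.t.size


@dataclasses.dataclass
class NormalizedPupilSeries:
    """Baseline-normalized pupil diameter in percent change (``%PD``)."""

    t: np.ndarray
    pct_pd: np.ndarray
    baseline: float
    eye: str


@dataclasses.dataclass
class MRAComponents:
    """Additive multiresolution decomposition of a 1-D signal.

    ``approx`` is the deepest-level approximation component and
    ``details[j]`` the level ``j+1`` detail component (finest first), all
    reconstructed on the original sample grid so they sum back to the
    input.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    wavelet: str
    levels: int
    mode: str

    def reconstruct(self) -> np.ndarray:
        return self.approx + np.sum(self.details, axis=0)


@dataclasses.dataclass
class FixationList:
    """Ordered, non-overlapping fixation events as (start, end) seconds."""

    events: list[tuple[float, float]]
    threshold: float
    task_duration: float

    def __post_init__(self) -> None:
        for (s, e) in self.events:
            if e <= s:
                raise ValueError(f"fixation end must exceed start: ({s}, {e})")
        starts = [s for s, _ in self.events]
        ends = [e for _, e in self.events]
        if any(s2 < e1 for e1, s2 in zip(ends, starts[1:])):
            raise ValueError("fixation events must be ordered and non-overlapping")

    def durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.events])

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# pupil preprocessing and normalization


def preprocess_pupil(g: GazeSeries, eye: str = "left") -> np.ndarray:
    """Clean one eye's pupil trace: drop invalid frames, spline-fill gaps.

    Invalid samples (blinks, tracking loss) are replaced by a natural cubic
    spline fitted through the valid samples and evaluated on the original
    timestamp grid.  Samples outside the valid support (gaps touching either
    series edge) take the nearest valid value — cubic extrapolation of pupil
    data is unstable.

    Returns the cleaned diameter array aligned with ``g.t``.
    """
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    raw = g.pd_left if eye == "left" else g.pd_right
    valid = g.valid
    n_valid = int(valid.sum())
    if n_valid < 4:
        raise ValueError(
            f"cannot interpolate pupil trace ({eye} eye): only {n_valid} valid "
            f"samples of {len(g)} (need >= 4)"
        )
    if valid.all():
        return raw.astype(float).copy()
    tv = g.t[valid]
    spline = CubicSpline(tv, raw[valid], bc_type="natural")
    out = raw.astype(float).copy()
    gaps = ~valid
    tt = g.t[gaps]
    filled = spline(tt)
    # nearest-valid extension outside the valid support
    filled[tt < tv[0]] = raw[valid][0]
    filled[tt > tv[-1]] = raw[valid][-1]
    out[gaps] = filled
    return out


def normalize_pupil(
    t: np.ndarray,
    pd_clean: np.ndarray,
    baseline_window: float = BASELINE_WINDOW_S,
    eye: str = "left",
) -> NormalizedPupilSeries:
    """Percent-change pupil diameter against a resting-state baseline.

    The baseline is the maximum cleaned diameter over the first
    ``baseline_window`` seconds of the session (the participant rests during
    that window), and every sample maps to
    ``(PD_raw - PD_baseline) / PD_baseline * 100``.
    """
    t = np.asarray(t, float)
    pd_clean = np.asarray(pd_clean, float)
    if t[-1] - t[0] <= baseline_window:
        raise ValueError(
            f"series ({t[-1] - t[0]:.2f} s) not longer than the "
            f"{baseline_window} s baseline window"
        )
    in_window = t <= t[0] + baseline_window
    baseline = float(pd_clean[in_window].max())
    if baseline <= 0:
        raise ValueError(f"nonpositive pupil baseline {baseline}; data corrupt")
    pct = (pd_clean - baseline) / baseline * 100.0
    return NormalizedPupilSeries(t=t, pct_pd=pct, baseline=baseline, eye=eye)


# ---------------------------------------------------------------------------
# wavelet multiresolution analysis


def haar_mra(
    x: Sequence[float],
    levels: int = MRA_LEVELS,
    wavelet: str = "haar",
    mode: str | None = None,
) -> MRAComponents:
    """Multiresolution analysis: additive wavelet components of ``x``.

    Each decomposition level halves the frequency band (downsampling by 2);
    the level-``levels`` approximation holds the lowest band.  Components
    are reconstructed back on the input grid, so
    ``approx + sum(details) == x`` to machine precision.

    ``mode`` selects the boundary extension; the default is
    ``"periodization"`` for power-of-two lengths (an orthonormal transform,
    so coefficient energy equals signal energy) and ``"symmetric"``
    otherwise (avoids edge ringing on arbitrary-length sessions).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("haar_mra expects a 1-D series")
    if x.size < 2**levels:
        raise ValueError(
            f"series of length {x.size} is too short for a {levels}-level "
            f"decomposition (needs >= {2**levels}); lower `levels`"
        )
    if mode is None:
        is_dyadic = x.size & (x.size - 1) == 0
        mode = "periodization" if is_dyadic else "symmetric"
    comps = pywt.mra(x, wavelet, level=levels, transform="dwt", mode=mode)
    approx = comps[0]
    details = list(reversed(comps[1:]))  # finest (level 1) first
    return MRAComponents(
        approx=approx, details=details, wavelet=wavelet, levels=levels, mode=mode
    )


def haar_dwt_coeffs(
    x: Sequence[float], levels: int = MRA_LEVELS, mode: str = "periodization"
) -> list[np.ndarray]:
    """Raw DWT coefficient arrays ``[cA_levels, cD_levels, ..., cD1]``.

    Offered for the coefficient-domain variant of the low-frequency pupil
    statistic; the default path works on reconstructed components.
    """
    x = np.asarray(x, dtype=float)
    return pywt.wavedec(x, "haar", mode=mode, level=levels)


def pd_lowfreq_std(
    np_series: NormalizedPupilSeries,
    levels: int = MRA_LEVELS,
    on_coefficients: bool = False,
) -> float:
    """``StdDevPD``: sample std of the low-frequency %PD component.

    The normalized pupil trace is decomposed to ``levels`` Haar levels and
    the sample standard deviation (N-1 denominator) of the deepest
    approximation is returned, in percent.  With ``on_coefficients`` the
    statistic is taken over the downsampled approximation coefficients
    instead of the reconstructed component.
    """
    x = np.asarray(np_series.pct_pd, dtype=float)
    if x.size < 2:
        raise ValueError("degenerate series: need >= 2 samples for a std")
    if on_coefficients:
        approx = haar_dwt_coeffs(x, levels=levels)[0]
    else:
        approx = haar_mra(x, levels=levels).approx
    if approx.size < 2:
        raise ValueError("approximation too short for a sample std")
    return float(np.std(approx, ddof=1))


# ---------------------------------------------------------------------------
# fixation detection (I-VT)


def angular_velocity(g: GazeSeries, use_valid_only: bool = True):
    """Angular gaze velocity per inter-sample interval, deg/s.

    The angle between consecutive gaze-direction vectors is divided by the
    time increment.  With ``use_valid_only`` (default) velocities are
    computed between consecutive *valid* samples, skipping blink frames; the
    returned times are the interval start/end pairs actually used.

    Returns ``(t_pairs, vel)`` where ``t_pairs`` is ``(m, 2)`` and ``vel``
    is ``(m,)``.
    """
    if use_valid_only:
        idx = np.flatnonzero(g.valid)
    else:
        idx = np.arange(len(g))
    if idx.size < 2:
        raise ValueError("need at least 2 (valid) samples for angular velocity")
    t = g.t[idx]
    d = g.dir[idx]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    dots = np.einsum("ij,ij->i", d[:-1], d[1:])
    crosses = np.linalg.norm(np.cross(d[:-1], d[1:]), axis=1)
    ang = np.degrees(np.arctan2(crosses, dots))
    vel = ang / dt
    t_pairs = np.column_stack([t[:-1], t[1:]])
    return t_pairs, vel


def detect_fixations(
    g: GazeSeries, threshold: float = VELOCITY_THRESHOLD_DEG_S
) -> FixationList:
    """I-VT fixation detection at a velocity threshold (default 30 deg/s).

    Intervals with angular velocity below the threshold are fixation
    intervals; maximal runs of successive fixation intervals merge into one
    fixation event spanning from the first to the last sample of the run.
    """
    t_pairs, vel = angular_velocity(g)
    is_fix = vel < threshold
    events: list[tuple[float, float]] = []
    i = 0
    m = is_fix.size
    while i < m:
        if is_fix[i]:
            j = i
            while j + 1 < m and is_fix[j + 1]:
                j += 1
            events.append((float(t_pairs[i, 0]), float(t_pairs[j, 1])))
            i = j + 1
        else:
            i += 1
    return FixationList(
        events=events, threshold=threshold, task_duration=float(g.t[-1] - g.t[0])
    )


def fixation_stats(f: FixationList) -> tuple[float, float]:
    """(fixation rate in 1/s, mean fixation duration in s).

    Rate is the number of fixations over the task duration; mean duration is
    total fixation time over the count.  With zero fixations the rate is 0
    and the mean duration is NaN (flagged missing, excluded downstream).
    """
    if f.task_duration <= 0:
        raise ValueError("task duration must be positive")
    n = len(f)
    rate = n / f.task_duration
    mean_dur = float(f.durations().mean()) if n else float("nan")
    return rate, mean_dur


# ---------------------------------------------------------------------------
# gaze dispersion (nearest-neighbour index)


def project_gaze(dirs: np.ndarray) -> np.ndarray:
    """Project unit gaze directions onto the unit-forward plane (x/z, y/z)."""
    dirs = np.asarray(dirs, float)
    z = dirs[:, 2]
    if np.any(z <= 0):
        raise ValueError("gaze direction behind the viewing plane (z <= 0)")
    return np.column_stack([dirs[:, 0] / z, dirs[:, 1] / z])


def fixation_centroids(g: GazeSeries, f: FixationList) -> np.ndarray:
    """Mean projected gaze point of each fixation event, ``(n_fix, 2)``."""
    pts = []
    for (s, e) in f.events:
        sel = (g.t >= s) & (g.t <= e) & g.valid
        if sel.any():
            pts.append(project_gaze(g.dir[sel]).mean(axis=0))
    return np.array(pts) if pts else np.empty((0, 2))


def nni(points: np.ndarray, area: float | None = None) -> float:
    """Nearest-neighbour index of a planar point pattern.

    Ratio of the mean observed nearest-neighbour distance to the mean
    distance expected under complete spatial randomness over the reference
    region, ``0.5 * sqrt(area / n)``.  When ``area`` is omitted the
    bounding-box area of the points is used.  1 indicates random scatter,
    < 1 clustering, with a maximum of ~2.15 for regular packings.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = points.shape[0]
    if n < 2:
        raise ValueError("NNI needs at least 2 points")
    if area is None:
        spans = points.max(axis=0) - points.min(axis=0)
        area = float(spans[0] * spans[1])
    if area <= 0:
        raise ValueError("reference area must be positive")
    d, _ = cKDTree(points).query(points, k=2)
    mean_nn = float(d[:, 1].mean())
    expected = 0.5 * np.sqrt(area / n)
    return mean_nn / expected


# ---------------------------------------------------------------------------
# session-level convenience


def compute_ocular_metrics(
    g: GazeSeries,
    threshold: float = VELOCITY_THRESHOLD_DEG_S,
    baseline_window: float = BASELINE_WINDOW_S,
    levels: int = MRA_LEVELS,
    nni_points: str = "centroids",
) -> dict[str, float]:
    """All ocular metrics for one session.

    ``nni_points`` selects the point pattern for the dispersion index:
    ``"centroids"`` (fixation centroids, default) or ``"samples"`` (every
    valid gaze sample).
    """
    out: dict[str, float] = {}
    for eye in ("left", "right"):
        cleaned = preprocess_pupil(g, eye)
        norm = normalize_pupil(g.t, cleaned, baseline_window, eye)
        out[f"stddev_pd_{eye}"] = pd_lowfreq_std(norm, levels=levels)
    fixations = detect_fixations(g, threshold)
    rate, mean_dur = fixation_stats(fixations)
    out["fixation_rate"] = rate
    out["mean_fixation_duration"] = mean_dur
    if nni_points == "centroids":
        pts = fixation_centroids(g, fixations)
    elif nni_points == "samples":
        pts = project_gaze(g.dir[g.valid])
    else:
        raise ValueError(f"unknown nni_points mode {nni_points!r}")
    out["nni"] = nni(pts) if pts.shape[0] >= 2 else float("nan")
    return out
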