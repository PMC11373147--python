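"""EEG band powers and the task-load / task-engagement indices.

Raw EEG (32 electrodes, microvolts, 128 Hz) is reduced to per-electrode
average band power with a sliding 256-sample Hann window advanced 16
samples per step; each window's one-sided power spectral density (uV^2/Hz)
is averaged over the canonical bands theta 4-8 Hz, alpha 8-12 Hz, beta
16-25 Hz and gamma 25-45 Hz (the 12-16 Hz gap between alpha and beta is
deliberate and not filled).

Two scalar indices summarize a session:

* **TLI** (task-load index): frontal-midline theta power over parietal
  alpha power.  Rises with working-memory and analytic load.
* **TEI** (task-engagement index): beta / (alpha + theta) on a frontal
  montage (F3, F4, F7, F8 by default; four alternative literature montages
  are selectable).  Tracks attentional resource allocation.

Powers are aggregated across a montage's electrodes by the arithmetic
mean before the ratio, which keeps the indices invariant to montage size.
The session value of each index is the mean of the per-window values.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "ELECTRODES_32",
    "IndexMontage",
    "TEI_MONTAGES",
    "BandPowerSeries",
    "band_power",
    "tli",
    "tei",
    "bandpass_filter",
    "compute_eeg_metrics",
]

EEG_RATE_HZ = 128.0
WINDOW_SAMPLES = 256
HOP_SAMPLES = 16

#: Band edges in Hz; bins are assigned half-open [low, high) so adjacent
#: bands never share a bin.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (16.0, 25.0),
    "gamma": (25.0, 45.0),
}

#: 32-channel saline headset layout (10-20 names).
ELECTRODES_32: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)

TLI_THETA_SET: tuple[str, ...] = (
    "Fz", "Fp1", "Fp2", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5", "FC6",
)
TLI_ALPHA_SET: tuple[str, ...] = ("P7", "P3", "Pz", "P4", "P8")

#: The five engagement-index montages evaluated in the workload literature.
TEI_MONTAGES: dict[str, tuple[str, ...]] = {
    "frontal": ("F3", "F4", "F7", "F8"),
    "parietal_cz": ("Pz", "P3", "P4", "Cz"),
    "parietal_frontal_c3": ("Pz", "P3", "Fz", "C3"),
    "fp1": ("Fp1",),
    "parietal_frontal_c4": ("Pz", "P4", "Fz", "C4"),
}


@dataclasses.dataclass(frozen=True)
class IndexMontage:
    """Electrode sets feeding the two indices."""

    tli_theta_set: tuple[str, ...] = TLI_THETA_SET
    tli_alpha_set: tuple[str, ...] = TLI_ALPHA_SET
    tei_set: tuple[str, ...] = TEI_MONTAGES["frontal"]

    def __post_init__(self) -> None:
        for group in (self.tli_theta_set, self.tli_alpha_set, self.tei_set):
            unknown = set(group) - set(ELECTRODES_32)
            if unknown:
                raise ValueError(f"montage names outside the layout: {sorted(unknown)}")


@dataclasses.dataclass
class BandPowerSeries:
    """Sliding-window band powers: ``power[band]`` is (n_windows, n_electrodes)."""

    window_start: np.ndarray
    electrodes: list[str]
    power: dict[str, np.ndarray]
    window: int = WINDOW_SAMPLES
    hop: int = HOP_SAMPLES

    def electrode_index(self, names) -> np.ndarray:
        missing = [n for n in names if n not in self.electrodes]
        if missing:
            raise KeyError(f"missing montage electrode(s): {missing}")
        return np.array([self.electrodes.index(n) for n in names])


def band_power(
    eeg: pd.DataFrame,
    fs: float = EEG_RATE_HZ,
    window: int = WINDOW_SAMPLES,
    hop: int = HOP_SAMPLES,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandPowerSeries:
    """Sliding Hann-window FFT band power for every electrode column.

    ``eeg`` is a frame with a ``t`` column (seconds) plus one column per
    electrode (uV).  Each length-``window`` frame, advanced by ``hop``
    samples, is Hann-tapered and Fourier transformed; the one-sided PSD is
    compensated for the window power so units are uV^2/Hz, and averaged over
    each band's frequency bins.
    """
    if bands is None:
        bands = BANDS
    if "t" not in eeg.columns:
        raise ValueError("EEG frame must have a 't' column")
    t = eeg["t"].to_numpy(float)
    names = [c for c in eeg.columns if c != "t"]
    if len(t) >= 2:
        rate = 1.0 / np.median(np.diff(t))
        if abs(rate - fs) > 0.5:
            raise ValueError(
                f"sampling rate {rate:.1f} Hz does not match the expected "
                f"{fs:g} Hz; band-to-bin mapping is fixed"
            )
    values = eeg[names].to_numpy(float)
    n = values.shape[0]
    if n < window:
        raise ValueError(f"need >= {window} samples per channel; got {n}")

    n_windows = (n - window) // hop + 1
    win = np.hanning(window)
    # frames: (n_windows, window, n_electrodes)
    starts = np.arange(n_windows) * hop
    frames = np.lib.stride_tricks.sliding_window_view(values, window, axis=0)
    frames = frames[starts]  # (n_windows, n_electrodes, window)
    spec = np.fft.rfft(frames * win, axis=-1)
    # one-sided PSD with Hann power compensation (uV^2/Hz)
    scale = 1.0 / (fs * np.sum(win**2))
    psd = (np.abs(spec) ** 2) * scale
    psd[..., 1:-1] *= 2.0  # all bins except DC and Nyquist
    freqs = np.fft.rfftfreq(window, d=1.0 / fs)

    # psd is (n_windows, n_electrodes, n_bins); band power = mean over bins
    power: dict[str, np.ndarray] = {}
    for band, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            raise ValueError(f"band {band} has no FFT bins at fs={fs}")
        power[band] = psd[..., sel].mean(axis=-1)
    return BandPowerSeries(
        window_start=t[starts],
        electrodes=names,
        power=power,
        window=window,
        hop=hop,
    )


def _montage_mean(bp: BandPowerSeries, band: str, names) -> np.ndarray:
    idx = bp.electrode_index(names)
    return bp.power[band][:, idx].mean(axis=1)


def tli(
    bp: BandPowerSeries, montage: IndexMontage | None = None
) -> tuple[float, np.ndarray]:
    """Task-load index: frontal theta power over parietal alpha power.

    Per window, the mean theta power across the 11 frontal electrodes is
    divided by the mean alpha power across the 5 parietal electrodes; the
    session value is the mean over windows.  Windows with a zero denominator
    are dropped (count logged).
    """
    m = montage or IndexMontage()
    num = _montage_mean(bp, "theta", m.tli_theta_set)
    den = _montage_mean(bp, "alpha", m.tli_alpha_set)
    ok = den > 0
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("TLI: dropped %d zero-denominator windows", dropped)
    series = num[ok] / den[ok]
    if series.size == 0:
        raise ValueError("TLI undefined: every window had zero parietal alpha power")
    return float(series.mean()), series


def tei(
    bp: BandPowerSeries, montage: str | tuple[str, ...] = "frontal"
) -> tuple[float, np.ndarray]:
    """Task-engagement index: beta / (alpha + theta) on a frontal montage.

    ``montage`` is one of the five literature montage names in
    ``TEI_MONTAGES`` or an explicit electrode tuple.  Band powers are
    montage-averaged before the ratio; the session value is the mean over
    windows, dropping zero-denominator windows.
    """
    names = TEI_MONTAGES[montage] if isinstance(montage, str) else tuple(montage)
    beta = _montage_mean(bp, "beta", names)
    alpha = _montage_mean(bp, "alpha", names)
    theta = _montage_mean(bp, "theta", names)
    den = alpha + theta
    ok = den > 0
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("TEI: dropped %d zero-denominator windows", dropped)
    series = beta[ok] / den[ok]
    if series.size == 0:
        raise ValueError("TEI undefined: every window had zero alpha+theta power")
    return float(series.mean()), series


def bandpass_filter(
    eeg: pd.DataFrame,
    low: float = 0.2,
    high: float = 45.0,
    fs: float = EEG_RATE_HZ,
    order: int = 4,
) -> pd.DataFrame:
    """Optional zero-phase band-pass for input that arrives unfiltered.

    Saline consumer headsets apply an onboard 0.2-45 Hz chain before
    streaming, so this stage is off by default in the pipeline.
    """
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    out = eeg.copy()
    cols = [c for c in eeg.columns if c != "t"]
    out[cols] = sps.sosfiltfilt(sos, eeg[cols].to_numpy(float), axis=0)
    return out


def compute_eeg_metrics(
    eeg: pd.DataFrame,
    montage: IndexMontage | None = None,
    tei_montage: str = "frontal",
) -> dict[str, float]:
    """Session TLI and TEI from a raw EEG frame."""
    bp = band_power(eeg)
    tli_val, _ = tli(bp, montage)
    tei_val, _ = tei(bp, tei_montage)
    return {"tli": tli_val, "tei": tei_val}
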