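"""Spectral analysis and waveform comparison.

Supports the rhythm workflows (where a jittered-burst drive at, say,
10 bursts/s should put the aggregate-dipole spectral peak in the alpha
band) and the evoked-response fitting loop (windowed RMSE against a
target source waveform in nAm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

#: default Welch segment length, ms
SEGMENT_MS = 1000.0
#: minimum usable segment, samples
MIN_SEGMENT_SAMPLES = 64


class RecordTooShortError(ValueError):
    pass


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # (nAm)²/Hz
    segment_samples: int = 0
    window: str = "hamming"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def psd(dipole, fmin: float = 0.0, fmax: Optional[float] = None,
        segment_ms: float = SEGMENT_MS) -> PowerSpectrum:
    """Welch-averaged periodogram of the detrended aggregate dipole.

    Segments default to 1 s (or the largest window the record allows),
    50% overlap, Hamming taper, linear detrend.  The record must hold at
    least two overlapped segments of a usable length.
    """
    x = np.asarray(dipole.aggregate, dtype=float)
    dt_s = dipole.dt / 1000.0
    fs = 1.0 / dt_s
    n = len(x)
    nperseg = int(round(segment_ms / 1000.0 * fs))
    if n < 1.5 * nperseg:
        nperseg = int(np.floor(n / 1.5))
    if nperseg < MIN_SEGMENT_SAMPLES:
        raise RecordTooShortError(
            f"record of {n} samples is too short for spectral analysis; "
            f"need at least {int(np.ceil(1.5 * MIN_SEGMENT_SAMPLES))} samples")
    freqs, power = sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                             noverlap=nperseg // 2, detrend="linear")
    if fmax is None:
        fmax = freqs[-1]
    mask = (freqs >= fmin) & (freqs <= fmax)
    return PowerSpectrum(freqs=freqs[mask], power=power[mask],
                         segment_samples=nperseg)


def peak_frequency(spectrum: PowerSpectrum, band: Tuple[float, float]) -> float:
    """Frequency of maximum power within ``band`` (inclusive).

    Ties break toward the lower frequency.
    """
    lo, hi = band
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no spectral bins")
    freqs = spectrum.freqs[mask]
    power = spectrum.power[mask]
    return float(freqs[np.argmax(power)])


def rmse(dipole, target_times: Sequence[float], target_values: Sequence[float],
         window: Optional[Tuple[float, float]] = None) -> float:
    """Root-mean-squared difference (nAm) between the aggregate dipole and
    a target waveform over a time window.

    The target is resampled onto the dipole's time grid by linear
    interpolation; the window is intersected with the overlap of the two
    supports.
    """
    t = np.asarray(dipole.times, dtype=float)
    x = np.asarray(dipole.aggregate, dtype=float)
    tt = np.asarray(target_times, dtype=float)
    tv = np.asarray(target_values, dtype=float)
    if tt.ndim != 1 or tt.size < 2:
        raise ValueError("target needs at least two samples")
    lo = max(t[0], tt[0])
    hi = min(t[-1], tt[-1])
    if window is not None:
        lo = max(lo, window[0])
        hi = min(hi, window[1])
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError("empty overlap between dipole, target and window")
    resampled = np.interp(t[mask], tt, tv)
    return float(np.sqrt(np.mean((x[mask] - resampled) ** 2)))
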