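"""Frequency-domain heart-rate-variability analysis.

RR-interval series are resampled to an evenly spaced tachogram (4 Hz,
cubic interpolation), mean-removed, and their periodogram integrated
over the standard short-term bands:

    VLF  0.003-0.04 Hz      LF  0.04-0.15 Hz      HF  0.15-0.4 Hz

Absolute powers are reported in ms^2; percentage powers are relative to
the three-band total, so they always close to 100%.  A sliding-window
variant tracks the band composition over a recording.  HF indexes
parasympathetic activity; VLF is read here as autonomic arousal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "BANDS",
    "RRSeries",
    "HRVResult",
    "band_powers",
    "sliding_hrv",
    "rr_from_ecg",
]

#: frequency bands (Hz), half-open [low, high)
BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

#: plausible-RR range (s); intervals outside are dropped during cleaning
RR_RANGE = (0.3, 2.0)

HRV_VARIABLES = ("vlf", "lf", "hf", "vlf_pct", "lf_pct", "hf_pct")


@dataclass
class RRSeries:
    """Successive R-R intervals in seconds."""

    intervals: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rr = np.asarray(self.intervals, dtype=float)
        if rr.ndim != 1 or rr.size < 2:
            raise ValueError("RR series needs >= 2 intervals")
        lo, hi = RR_RANGE
        bad = ~((rr > lo) & (rr < hi) & np.isfinite(rr))
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} RR interval(s) outside ({lo}, {hi}) s",
                stacklevel=2,
            )
            rr = rr[~bad]
        if rr.size < 2:
            raise ValueError("fewer than 2 valid RR intervals after cleaning")
        self.intervals = rr

    @property
    def span(self) -> float:
        """Total duration covered by the series (s)."""
        return float(self.intervals.sum())

    @property
    def beat_times(self) -> np.ndarray:
        """Time of each beat (s), starting after the first interval."""
        return np.cumsum(self.intervals)


@dataclass
class HRVResult:
    """Band powers (ms^2) and their percentage composition."""

    vlf: float
    lf: float
    hf: float

    @property
    def total(self) -> float:
        return self.vlf + self.lf + self.hf

    @property
    def vlf_pct(self) -> float:
        return 100.0 * self.vlf / self.total if self.total > 0 else float("nan")

    @property
    def lf_pct(self) -> float:
        return 100.0 * self.lf / self.total if self.total > 0 else float("nan")

    @property
    def hf_pct(self) -> float:
        return 100.0 * self.hf / self.total if self.total > 0 else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in HRV_VARIABLES}


def _tachogram(rr: RRSeries, fs: float = 4.0) -> tuple[np.ndarray, float]:
    """Evenly resampled RR tachogram in ms via cubic-spline interpolation."""
    t = rr.beat_times
    x_ms = rr.intervals * 1000.0
    spline = CubicSpline(t, x_ms)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    return spline(grid), fs


def band_powers(rr: RRSeries, fs_resample: float = 4.0) -> HRVResult:
    """Integrated VLF/LF/HF spectral powers of an RR series.

    The series must span at least 60 s.  The tachogram is mean-removed
    and its periodogram integrated over each half-open band [low, high);
    percentages (on :class:`HRVResult`) are relative to the three-band sum.
    """
    if rr.span < 60.0:
        raise ValueError(f"RR series spans {rr.span:.1f} s; need >= 60 s")
    tacho, fs = _tachogram(rr, fs_resample)
    tacho = tacho - tacho.mean()
    freqs, pxx = sps.periodogram(tacho, fs=fs, window="boxcar", detrend=False)
    df = freqs[1] - freqs[0]
    powers = {}
    for name, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        powers[name] = float(pxx[mask].sum() * df)
    return HRVResult(**powers)


def sliding_hrv(rr: RRSeries, window_s: float = 180.0, step_s: float = 10.0) -> pd.DataFrame:
    """Band powers over a sliding window; one row per window.

    Windows are anchored at successive ``step_s`` offsets from the start
    of the series; the ``t_end`` column timestamps each window by its
    end.  A series shorter than ``window_s`` falls back to a single
    whole-series window with a warning.
    """
    span = rr.span
    t = rr.beat_times
    if span < window_s:
        warnings.warn(
            f"series spans {span:.1f} s < window {window_s:g} s; "
            "computing a single whole-series window",
            stacklevel=2,
        )
        starts = [0.0]
        window_s = span
    else:
        n_windows = int(np.floor((span - window_s) / step_s)) + 1
        starts = [k * step_s for k in range(n_windows)]
    rows = []
    for start in starts:
        stop = start + window_s
        mask = (t >= start) & (t <= stop + 1e-9)
        sub = RRSeries(rr.intervals[mask], meta=dict(rr.meta))
        res = band_powers(sub)
        rows.append({"t_end": stop, **res.as_dict()})
    return pd.DataFrame(rows)


def rr_from_ecg(ecg: np.ndarray, fs: float = 500.0, meta: dict | None = None) -> RRSeries:
    """R-peak detection on a single-channel ECG, returning RR intervals.

    QRS energy is isolated with a 5-15 Hz band-pass, squared, and peaks
    are picked as local maxima above an adaptive threshold with a 0.3-s
    refractory period.  Intended as a convenience input stage; the
    statistically analysed object is the RR series.
    """
    if fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    x = np.asarray(ecg, dtype=float)
    if x.ndim != 1 or x.size < int(fs):
        raise ValueError("ECG must be a 1-D array of at least 1 s")
    sos = sps.butter(4, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x - x.mean())
    energy = filt**2
    if energy.max() <= 0:
        raise ValueError("flat ECG signal: no R peaks detectable")
    height = 0.3 * np.quantile(energy, 0.999)
    peaks, _ = sps.find_peaks(energy, height=height, distance=int(0.3 * fs))
    if peaks.size < 2:
        raise ValueError(f"found {peaks.size} R peak(s); need >= 2")
    return RRSeries(np.diff(peaks) / fs, meta=meta or {})
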