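"""Micromovement feature variables.

For each AU and each time section the pipeline computes three feature
variables from the frame-to-frame change (delta) of the AU centroid:

* ``mean_delta`` — mean per-frame displacement magnitude (px/frame), the
  degree of movement;
* ``sd_delta`` — standard deviation of the displacement magnitude
  (population convention by default), the variance of movement;
* ``dominant_peak_hz`` — frequency of the largest spectral component of
  the mean-removed delta-magnitude series, the vibration level.

Deltas follow the previous-minus-current convention:
``dx[n] = x[n-1] - x[n]``, ``dy[n] = y[n-1] - y[n]``.  The spectral peak
is searched between 2 Hz and Nyquist because micromovement vibration
periods span 0.04-0.5 s; the DC bin is always excluded (the series is
mean-removed) and ties break toward the lower frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .au import AUTrajectory, LandmarkStream, extract_analysis_window, extract_au_trajectories
from .config import DEFAULT_CONFIG, PipelineConfig
from .segmentation import (
    Section,
    global_onset,
    detect_onset,
    movement_signal,
    segment,
)

__all__ = [
    "DeltaSeries",
    "FeatureSet",
    "frame_deltas",
    "summary_features",
    "dominant_peak_frequency",
    "feature_table",
    "MIN_SPECTRUM_FRAMES",
]

#: sections shorter than this many frames yield no spectral estimate
MIN_SPECTRUM_FRAMES = 8

SECTION_ORDER = ("pre", "t+0.5", "t+1", "t+4")
FEATURE_NAMES = ("mean_delta", "sd_delta", "dominant_peak_hz")


@dataclass
class DeltaSeries:
    """Frame-to-frame coordinate differences of one AU over one section."""

    dx: np.ndarray
    dy: np.ndarray
    magnitude: np.ndarray
    fps: float

    def __len__(self) -> int:
        return self.magnitude.size


@dataclass
class FeatureSet:
    """The three feature variables for one AU x section."""

    au: str
    section: str
    mean_delta: float
    sd_delta: float
    dominant_peak_hz: float | None
    truncated: bool = False


def frame_deltas(positions: np.ndarray, fps: float = 30.0) -> DeltaSeries:
    """Per-frame deltas of a centroid position sequence (prev - curr)."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must be an (n, 2) array")
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 frames to form deltas")
    diff = pos[:-1] - pos[1:]
    dx, dy = diff[:, 0], diff[:, 1]
    return DeltaSeries(dx=dx, dy=dy, magnitude=np.hypot(dx, dy), fps=fps)


def summary_features(deltas: DeltaSeries, ddof: int = 0, axis: str = "magnitude") -> tuple[float, float]:
    """Mean and SD of the delta series.

    By default both are computed on the Euclidean magnitude; ``axis`` may
    select ``"dx"`` or ``"dy"`` for per-axis summaries.  ``ddof=0`` gives
    the population SD convention.
    """
    series = getattr(deltas, axis)
    if series.size == 0:
        raise ValueError("empty delta series")
    return float(series.mean()), float(series.std(ddof=ddof))


def dominant_peak_frequency(
    deltas: DeltaSeries,
    band_low_hz: float = 2.0,
    band_high_hz: float | None = None,
    hann: bool = False,
) -> float | None:
    """Frequency (Hz) of the largest spectral bin of the delta magnitude.

    The magnitude series is mean-removed and transformed with a real FFT
    (no taper: sections are short and the estimate is a peak location,
    not a power).  The peak is the maximum-amplitude bin with
    ``band_low_hz <= f <= band_high_hz`` (default Nyquist); the first such
    bin wins ties, i.e. ties break toward the lower frequency.  Returns
    ``None`` when the series is too short, the spectrum is identically
    zero, or no bin falls inside the band.
    """
    x = deltas.magnitude
    if x.size < MIN_SPECTRUM_FRAMES:
        return None
    x = x - x.mean()
    if hann:  # optional taper for leakage-sensitive use; off by default
        x = x * np.hanning(x.size)
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / deltas.fps)
    mask = freqs >= band_low_hz
    if band_high_hz is not None:  # None: up to Nyquist, i.e. all rfft bins
        mask &= freqs <= band_high_hz
    if not mask.any():
        return None
    in_band = spectrum[mask]
    if np.all(in_band == 0.0):
        return None
    return float(freqs[mask][np.argmax(in_band)])


def _section_features(
    traj: AUTrajectory, section: Section, config: PipelineConfig
) -> FeatureSet:
    name = section.name
    if len(section) < 2:
        return FeatureSet(traj.au.name, name, np.nan, np.nan, None, truncated=section.truncated)
    pos = traj.positions[section.start : section.stop]
    deltas = frame_deltas(pos, fps=traj.fps)
    axis = "magnitude" if not config.per_axis else "dx"
    mean, sd = summary_features(deltas, ddof=config.sd_ddof, axis=axis)
    peak = dominant_peak_frequency(deltas, band_low_hz=config.band_low_hz, hann=config.hann)
    return FeatureSet(traj.au.name, name, mean, sd, peak, truncated=section.truncated)


def feature_table(
    stream: LandmarkStream,
    config: PipelineConfig = DEFAULT_CONFIG,
    apply_window: bool = True,
) -> pd.DataFrame:
    """Full pipeline: landmark stream -> per-AU, per-section feature rows.

    Steps: trailing analysis window -> 11 AU centroid trajectories ->
    movement signals -> onset (global median by default) -> pre / t+0.5 /
    t+1 / t+4 sections -> delta features.  Returns a tidy DataFrame with
    one row per AU x section (44 rows), carrying the stream metadata,
    onset frame and truncation flags.  Sections too short for a feature
    hold NaN / missing values rather than unstable estimates.
    """
    if apply_window:
        stream = extract_analysis_window(stream, config.window_s)
    if config.normalize_width is not None:
        width = stream.frames[0, :, 0].max() - stream.frames[0, :, 0].min()
        if width > 0:
            stream = LandmarkStream(
                frames=stream.frames * (config.normalize_width / width),
                fps=stream.fps,
                meta=dict(stream.meta),
                start_index=stream.start_index,
            )
    trajectories = extract_au_trajectories(stream)
    signals = [movement_signal(t, baseline_s=config.baseline_s) for t in trajectories]

    onsets: list[int]
    if config.global_onset:
        t0 = global_onset(signals, smooth_window=config.smooth_window)
        onsets = [t0] * len(trajectories)
    else:
        onsets = [detect_onset(s, smooth_window=config.smooth_window) for s in signals]

    meta = stream.meta
    rows = []
    for traj, onset in zip(trajectories, onsets):
        seg = segment(traj, onset)
        for name in SECTION_ORDER:
            fs = _section_features(traj, seg.sections[name], config)
            rows.append(
                {
                    "subject": meta.get("subject"),
                    "emotion": meta.get("emotion"),
                    "authenticity": meta.get("authenticity"),
                    "au": traj.au.name,
                    "side": traj.au.side,
                    "section": name,
                    "onset_frame": onset,
                    "mean_delta": fs.mean_delta,
                    "sd_delta": fs.sd_delta,
                    "dominant_peak_hz": np.nan if fs.dominant_peak_hz is None else fs.dominant_peak_hz,
                    "truncated": fs.truncated,
                }
            )
    return pd.DataFrame(rows)
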