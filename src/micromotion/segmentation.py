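"""Expression onset detection and time segmentation.

The onset of a cued facial expression is found per AU from a scalar
movement signal: the Euclidean displacement of the AU centroid from a
neutral baseline (mean position over the first second of the analysis
window).  The onset threshold is the mid-range of the signal,

    threshold = (max + min) / 2,

and the onset is the first frame whose (optionally smoothed) movement
strictly exceeds it.  Around the onset t the pipeline cuts four
sections: the pre-onset micromovement section [window start, t) and
three overlapping post-onset sections starting at t of 0.5 s and 1 s
(micromovement) and 4 s (macromovement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .au import AUTrajectory

__all__ = [
    "MovementSignal",
    "Section",
    "SegmentedTrajectory",
    "OnsetNotFoundError",
    "movement_signal",
    "minmax_threshold",
    "detect_onset",
    "global_onset",
    "segment",
    "POST_SECTIONS",
]

#: post-onset section durations in seconds, keyed by report label
POST_SECTIONS: dict[str, float] = {"t+0.5": 0.5, "t+1": 1.0, "t+4": 4.0}


class OnsetNotFoundError(ValueError):
    """No onset exists (e.g. the movement signal is constant)."""


@dataclass
class MovementSignal:
    """Per-frame scalar movement (pixels) of one AU."""

    values: np.ndarray
    fps: float
    au: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("movement signal needs >= 2 samples")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("movement values must be finite and non-negative")
        self.values = v

    @property
    def degenerate(self) -> bool:
        """True when the signal is constant, so no mid-range crossing exists."""
        return bool(self.values.max() == self.values.min())


def movement_signal(
    traj: AUTrajectory,
    baseline: np.ndarray | None = None,
    baseline_s: float = 1.0,
) -> MovementSignal:
    """Displacement-from-baseline movement signal of an AU trajectory.

    ``baseline`` defaults to the mean AU position over the first
    ``baseline_s`` seconds of the trajectory (the neutral posture at the
    start of the analysis window).
    """
    pos = traj.positions
    if pos.shape[0] == 0:
        raise ValueError("empty trajectory")
    if baseline is None:
        n_base = max(1, int(round(baseline_s * traj.fps)))
        baseline = pos[:n_base].mean(axis=0)
    baseline = np.asarray(baseline, dtype=float)
    if not np.all(np.isfinite(baseline)):
        raise ValueError("baseline must be finite")
    values = np.linalg.norm(pos - baseline, axis=1)
    return MovementSignal(values=values, fps=traj.fps, au=traj.au.name)


def minmax_threshold(signal: MovementSignal) -> float:
    """Mid-range onset threshold (max + min) / 2 of the movement signal.

    For a constant (degenerate) signal the constant itself is returned;
    callers should check :attr:`MovementSignal.degenerate` because no
    frame can strictly exceed that value.
    """
    v = signal.values
    return float((v.max() + v.min()) / 2.0)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed series keeps its length and edges
    pad = window // 2
    padded = np.pad(values, (pad, window - 1 - pad), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def detect_onset(signal: MovementSignal, smooth_window: int = 1) -> int:
    """First frame whose movement strictly exceeds the mid-range threshold.

    ``smooth_window`` > 1 applies a centred moving average before
    thresholding to suppress single-frame jitter crossings; the threshold
    is computed on the smoothed signal so min/max and crossing refer to
    the same series.
    """
    values = _smooth(signal.values, smooth_window)
    vmax, vmin = values.max(), values.min()
    if vmax == vmin:
        raise OnsetNotFoundError(
            f"constant movement signal for {signal.au or 'AU'}: no onset exists"
        )
    threshold = (vmax + vmin) / 2.0
    above = np.nonzero(values > threshold)[0]
    # a non-degenerate signal always attains its max, which exceeds midrange
    return int(above[0])


def global_onset(signals: list[MovementSignal], smooth_window: int = 1) -> int:
    """Shared onset across AUs: the median of the per-AU onset frames.

    The cue paradigm produces one expression event per recording, so a
    single onset t is the natural anchor for all AUs; the median is robust
    to AUs that barely move and cross their (noise-dominated) mid-range at
    an arbitrary frame.  Degenerate AUs are skipped.
    """
    onsets = []
    for sig in signals:
        try:
            onsets.append(detect_onset(sig, smooth_window))
        except OnsetNotFoundError:
            continue
    if not onsets:
        raise OnsetNotFoundError("no AU produced a detectable onset")
    return int(np.median(onsets))


@dataclass(frozen=True)
class Section:
    """Half-open frame range [start, stop) relative to the analysis window."""

    name: str
    start: int
    stop: int
    truncated: bool = False

    def __len__(self) -> int:
        return self.stop - self.start

    @property
    def empty(self) -> bool:
        return self.stop <= self.start


@dataclass
class SegmentedTrajectory:
    """Onset anchor plus the pre-onset and three post-onset sections."""

    au: str
    fps: float
    onset: int
    pre: Section
    post: dict[str, Section] = field(default_factory=dict)

    @property
    def sections(self) -> dict[str, Section]:
        return {"pre": self.pre, **self.post}


def segment(traj: AUTrajectory, onset: int) -> SegmentedTrajectory:
    """Cut pre-onset and t+0.5 / t+1 / t+4 sections around the onset.

    The three post sections share the start frame t and nest inside one
    another; at 30 fps their nominal lengths are 15, 30 and 120 frames.
    A section running past the end of the trajectory is truncated and
    flagged; an onset at frame 0 yields an empty, flagged pre section.
    Truncated/empty sections are retained so downstream stages can decide
    whether to analyse or exclude them.
    """
    n = traj.n_frames
    if not (0 <= onset < n):
        raise ValueError(f"onset {onset} outside trajectory of {n} frames")
    pre = Section("pre", 0, onset, truncated=(onset == 0))
    if onset == 0:
        warnings.warn("onset at window start: empty pre-onset section", stacklevel=2)
    post: dict[str, Section] = {}
    for name, dur_s in POST_SECTIONS.items():
        stop = onset + int(round(dur_s * traj.fps))
        truncated = stop > n
        if truncated:
            warnings.warn(
                f"section {name} truncated at trajectory end "
                f"({stop - n} frames missing)",
                stacklevel=2,
            )
        post[name] = Section(name, onset, min(stop, n), truncated=truncated)
    return SegmentedTrajectory(au=traj.au.name, fps=traj.fps, onset=onset, pre=pre, post=post)
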