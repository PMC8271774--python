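"""Facial action-unit geometry.

Maps 68-point facial landmark streams onto the 11 action-unit (AU)
centroid trajectories used throughout the package.  Each AU is the
centroid of three landmarks in the standard 68-point annotation scheme
(0-based indices: jaw 0-16, brows 17-26, nose 27-35, eyes 36-47,
lips 48-67).  Coordinates are pixels in image space with y increasing
downward; no normalisation is applied by default because the movement
features downstream are reported in raw pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "N_LANDMARKS",
    "AUDefinition",
    "LandmarkFrame",
    "LandmarkStream",
    "AUTrajectory",
    "au_definitions",
    "compute_au_centroid",
    "extract_au_trajectories",
    "extract_analysis_window",
]

N_LANDMARKS = 68


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


@dataclass(frozen=True)
class AUDefinition:
    """One action unit: a named triple of landmark indices.

    ``side`` is derived from the ``_L`` / ``_R`` / ``_M`` suffix of the
    AU name and drives the left/right placement in report grids.
    """

    name: str
    description: str
    landmarks: tuple[int, int, int]
    side: str  # "left" | "right" | "middle"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "middle"):
            raise ValidationError(f"invalid side {self.side!r}")
        if len(self.landmarks) != 3 or any(
            not (0 <= i < N_LANDMARKS) for i in self.landmarks
        ):
            raise ValidationError(f"landmark triple out of range: {self.landmarks}")


def _side_from_name(name: str) -> str:
    return {"L": "left", "R": "right", "M": "middle"}[name.rsplit("_", 1)[1]]


# The 11 AU definitions: (name, description, landmark triple).  Indices are
# 0-based positions in the 68-point scheme.  Names and indices, not the
# description strings, drive all computation.
_AU_TABLE: tuple[tuple[str, str, tuple[int, int, int]], ...] = (
    ("AU4_M", "Brow depressor", (21, 22, 27)),
    ("AU5_L", "Upper lid raiser", (23, 25, 44)),
    ("AU5_R", "Upper lid raiser", (18, 20, 37)),
    ("AU6_L", "Cheek raiser", (15, 26, 45)),
    ("AU6_R", "Cheek raiser", (1, 17, 36)),
    ("AU12_L", "Lip corner puller", (14, 35, 54)),
    ("AU12_R", "Lip corner puller", (2, 31, 48)),
    ("AU15_L", "Lip corner depressor", (10, 11, 54)),
    ("AU15_R", "Lip corner depressor", (5, 6, 48)),
    ("AU23_L", "Lip tightener", (52, 53, 63)),
    ("AU23_R", "Lip tightener", (49, 50, 61)),
)

AU_NAMES: tuple[str, ...] = tuple(name for name, _, _ in _AU_TABLE)


def au_definitions() -> list[AUDefinition]:
    """The 11 action-unit definitions, in canonical order."""
    return [
        AUDefinition(name, desc, triple, _side_from_name(name))
        for name, desc, triple in _AU_TABLE
    ]


_AU_BY_NAME = {d.name: d for d in au_definitions()}


def au_definition(name: str) -> AUDefinition:
    """Look up a single AU definition by name."""
    try:
        return _AU_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown AU {name!r}; known: {', '.join(AU_NAMES)}") from None


@dataclass(frozen=True)
class LandmarkFrame:
    """A single frame: 68 (x, y) pixel coordinates."""

    index: int
    points: np.ndarray  # (68, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"frame {self.index}: expected {N_LANDMARKS} (x, y) points, "
                f"got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"frame {self.index}: non-finite coordinates")
        if self.index < 0:
            raise ValidationError("frame index must be non-negative")
        object.__setattr__(self, "points", pts)


@dataclass
class LandmarkStream:
    """An ordered sequence of landmark frames with sampling metadata.

    ``frames`` is an (n_frames, 68, 2) float array; ``start_index`` is the
    original index of the first frame (non-zero after window extraction).
    ``meta`` carries subject / emotion / authenticity labels.
    """

    frames: np.ndarray
    fps: float
    meta: dict = field(default_factory=dict)
    start_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 3 or arr.shape[1:] != (N_LANDMARKS, 2):
            raise ValidationError(
                f"frames must have shape (n, {N_LANDMARKS}, 2), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("landmark stream contains non-finite coordinates")
        if not self.fps > 0:
            raise ValidationError("fps must be positive")
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Stream duration in seconds."""
        return self.n_frames / self.fps

    def frame(self, i: int) -> LandmarkFrame:
        return LandmarkFrame(index=self.start_index + i, points=self.frames[i])

    def __iter__(self) -> Iterator[LandmarkFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class AUTrajectory:
    """Per-frame centroid positions of one action unit."""

    au: AUDefinition
    positions: np.ndarray  # (n_frames, 2)
    fps: float

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def compute_au_centroid(p1: Sequence[float], p2: Sequence[float], p3: Sequence[float]) -> np.ndarray:
    """Centroid of three landmarks: the componentwise arithmetic mean.

    For landmarks A(x1, y1), B(x2, y2), C(x3, y3) the AU position is
    P((x1+x2+x3)/3, (y1+y2+y3)/3), which always lies in their convex hull.
    """
    pts = np.asarray([p1, p2, p3], dtype=float)
    if pts.shape != (3, 2):
        raise ValidationError("each point must be a 2-D coordinate")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("non-finite coordinates in centroid input")
    return pts.mean(axis=0)


def trajectory_array(frames: np.ndarray) -> np.ndarray:
    """Vectorised AU extraction: (n, 68, 2) frames -> (11, n, 2) centroids.

    Row order matches :func:`au_definitions`.
    """
    idx = np.array([d.landmarks for d in au_definitions()])  # (11, 3)
    return frames[:, idx, :].mean(axis=2).transpose(1, 0, 2)


def extract_au_trajectories(stream: LandmarkStream) -> list[AUTrajectory]:
    """Compute the 11 AU centroid trajectories of a landmark stream."""
    arr = trajectory_array(stream.frames)
    return [
        AUTrajectory(au=d, positions=arr[k], fps=stream.fps)
        for k, d in enumerate(au_definitions())
    ]


def extract_analysis_window(stream: LandmarkStream, window_s: float = 30.0) -> LandmarkStream:
    """Trailing analysis window of a recording.

    The paradigm this pipeline serves records 210 s per condition of which
    only the final 30 s contain the cued expression; analysis is restricted
    to that trailing window.  Frame indices are re-based so that
    ``start_index`` records the original index of the first retained frame.
    """
    n_keep = int(round(window_s * stream.fps))
    if n_keep > stream.n_frames:
        raise ValidationError(
            f"stream too short for analysis window: need {window_s:g} s "
            f"({n_keep} frames), have {stream.duration:g} s ({stream.n_frames} frames)"
        )
    first = stream.n_frames - n_keep
    return LandmarkStream(
        frames=stream.frames[first:],
        fps=stream.fps,
        meta=dict(stream.meta),
        start_index=stream.start_index + first,
    )
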