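"""Synthetic landmark streams, RR series and full study cohorts.

The generator emulates the recording conditions the analysis pipeline is
built for: 210-s landmark streams at 30 fps in a 1280 x 980 frame of
which only the final 30 s contain a cued expression, and RR-interval
series with a controlled VLF/LF/HF power composition.  Every programmed
quantity (onset time, vibration frequency, amplitudes, band shares) is
recorded as ground truth so each pipeline stage can be validated against
what was injected.

Expression model
----------------
Landmarks belonging to an action unit follow a sigmoid onset ramp to the
profile's movement amplitude, superposed with a sinusoidal vibration and
per-landmark Gaussian jitter; a left/right asymmetry multiplier scales
left-side AUs.  ``vibration_hz`` is defined as the dominant frequency of
the frame-delta *magnitude* series — the quantity the feature extractor
measures.  Because the magnitude of a symmetric positional oscillation
is full-wave rectified (a position oscillation at f yields a speed
magnitude oscillating at 2f), the generator realises a programmed
vibration of f Hz as a positional oscillation at f/2 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .au import AU_NAMES, LandmarkStream, au_definitions
from .hrv import BANDS, RRSeries

__all__ = [
    "EMOTIONS",
    "ExpressionProfile",
    "CohortSpec",
    "CohortBundle",
    "neutral_face_template",
    "generate_stream",
    "generate_rr",
    "generate_cohort",
    "default_profiles",
    "default_hrv_shares",
]

EMOTIONS = ("happiness", "contentment", "anger", "sadness")
AUTHENTICITIES = ("real", "fake")

FRAME_WIDTH, FRAME_HEIGHT = 1280, 980


def neutral_face_template() -> np.ndarray:
    """Schematic frontal 68-point face, centred in a 1280 x 980 frame.

    Landmark semantics follow the standard 68-point scheme (jaw 0-16,
    brows 17-26, nose 27-35, eyes 36-47, lips 48-67).  The exact
    coordinates are a package constant chosen for geometric plausibility,
    not a measured face.
    """
    cx, cy = FRAME_WIDTH / 2.0, FRAME_HEIGHT / 2.0  # (640, 490)
    pts = np.zeros((68, 2))
    # jaw 0-16: half-ellipse from image-left temple to image-right temple
    ang = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17, 0] = cx + 260 * np.cos(ang)
    pts[0:17, 1] = cy - 120 + 320 * np.abs(np.sin(ang))
    # brows 17-21 (image-left) and 22-26 (image-right)
    pts[17:22, 0] = np.linspace(cx - 210, cx - 60, 5)
    pts[17:22, 1] = cy - 150 - np.array([0, 15, 22, 15, 5])
    pts[22:27, 0] = np.linspace(cx + 60, cx + 210, 5)
    pts[22:27, 1] = cy - 150 - np.array([5, 15, 22, 15, 0])
    # nose bridge 27-30 and nostril line 31-35
    pts[27:31, 0] = cx
    pts[27:31, 1] = np.linspace(cy - 120, cy + 10, 4)
    pts[31:36, 0] = np.linspace(cx - 55, cx + 55, 5)
    pts[31:36, 1] = cy + 45 - np.array([0, 6, 10, 6, 0])
    # eyes 36-41 (image-left) and 42-47 (image-right): hexagons
    for start, ex in ((36, cx - 140), (42, cx + 140)):
        hexa = np.array(
            [(-45, 0), (-20, -18), (20, -18), (45, 0), (20, 16), (-20, 16)], dtype=float
        )
        pts[start : start + 6] = hexa + (ex, cy - 80)
    # outer lip 48-59 (ellipse) and inner lip 60-67
    ang = np.linspace(np.pi, 3 * np.pi, 13)[:-1]
    pts[48:60, 0] = cx + 95 * np.cos(ang)
    pts[48:60, 1] = cy + 170 + 42 * np.sin(ang)
    ang = np.linspace(np.pi, 3 * np.pi, 9)[:-1]
    pts[60:68, 0] = cx + 55 * np.cos(ang)
    pts[60:68, 1] = cy + 170 + 18 * np.sin(ang)
    return pts


def _per_au(value: float | Mapping[str, float]) -> dict[str, float]:
    if isinstance(value, Mapping):
        unknown = set(value) - set(AU_NAMES)
        if unknown:
            raise ValueError(f"unknown AU name(s): {sorted(unknown)}")
        return {name: float(value.get(name, 0.0)) for name in AU_NAMES}
    return {name: float(value) for name in AU_NAMES}


@dataclass
class ExpressionProfile:
    """Movement parameters of one emotion x authenticity condition.

    Amplitudes are pixels; ``vibration_hz`` is the programmed dominant
    frequency of the delta-magnitude series (2-25 Hz micromovement
    band).  ``asymmetry`` multiplies the amplitudes of left-side AUs.
    ``onset_time_s`` is the absolute time of the sigmoid ramp midpoint
    (default: 15 s before the end of the recording, i.e. the middle of
    the 30-s expression window); ``ramp_s`` is the 10-90% rise time.
    """

    emotion: str
    onset_amplitude: float | Mapping[str, float] = 6.0
    vibration_amplitude: float | Mapping[str, float] = 1.0
    vibration_hz: float = 6.0
    asymmetry: float = 1.0
    ramp_s: float = 2.0
    onset_time_s: float | None = None
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        amps = _per_au(self.onset_amplitude)
        vibs = _per_au(self.vibration_amplitude)
        if any(v < 0 for v in list(amps.values()) + list(vibs.values())):
            raise ValueError("amplitudes must be non-negative")
        if not self.vibration_hz > 0:
            raise ValueError("vibration frequency must be positive")
        if not self.ramp_s > 0:
            raise ValueError("ramp duration must be positive")
        if self.noise_sd < 0 or self.asymmetry < 0:
            raise ValueError("noise SD and asymmetry must be non-negative")
        self.onset_amplitude = amps
        self.vibration_amplitude = vibs


def default_profiles() -> dict[str, dict[str, ExpressionProfile]]:
    """Default real/fake profiles per emotion.

    The defaults encode, as illustrative effect structure, the
    qualitative pattern the pipeline is meant to resolve: more movement
    in the real condition for every emotion; for the relaxation-based
    emotions (contentment, sadness) a higher-frequency vibration in the
    fake condition.  They are freely overridable and carry no empirical
    claim about real faces.
    """
    profiles: dict[str, dict[str, ExpressionProfile]] = {}
    for emotion in ("happiness", "anger"):
        profiles[emotion] = {
            "real": ExpressionProfile(emotion, onset_amplitude=8.0,
                                      vibration_amplitude=1.5, vibration_hz=7.0),
            "fake": ExpressionProfile(emotion, onset_amplitude=5.0,
                                      vibration_amplitude=1.0, vibration_hz=5.0),
        }
    for emotion in ("contentment", "sadness"):
        profiles[emotion] = {
            "real": ExpressionProfile(emotion, onset_amplitude=6.0,
                                      vibration_amplitude=2.0, vibration_hz=4.0),
            "fake": ExpressionProfile(emotion, onset_amplitude=4.0,
                                      vibration_amplitude=0.55, vibration_hz=10.0),
        }
    return profiles


def default_hrv_shares() -> dict[str, tuple[float, float, float]]:
    """Default VLF/LF/HF power shares per condition.

    Real: arousal-dominated (high VLF share); fake: relaxation-dominated
    (high HF share); LF share equal across conditions.
    """
    return {"real": (0.45, 0.30, 0.25), "fake": (0.25, 0.30, 0.45)}


@dataclass
class CohortSpec:
    """Design of a simulated cohort: 40 subjects x 4 emotions x 2 conditions."""

    n_subjects: int = 40
    fps: float = 30.0
    duration_s: float = 210.0
    window_s: float = 30.0
    hrv_duration_s: float = 210.0
    profiles: dict[str, dict[str, ExpressionProfile]] = field(default_factory=default_profiles)
    hrv_shares: dict[str, tuple[float, float, float]] = field(default_factory=default_hrv_shares)
    #: total RR modulation SD (s) per condition; the fake default is larger so
    #: absolute band powers rise in fake even where the share is unchanged
    hrv_mod_sd: dict[str, float] = field(default_factory=lambda: {"real": 0.030, "fake": 0.0375})
    subject_sd: float = 0.2  # lognormal sigma of the per-subject amplitude multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, shares in self.hrv_shares.items():
            if abs(sum(shares) - 1.0) > 1e-9:
                raise ValueError(f"HRV shares for {cond!r} must sum to 1")


def generate_stream(
    profile: ExpressionProfile,
    fps: float = 30.0,
    duration_s: float = 210.0,
    window_s: float = 30.0,
    seed: int | np.random.SeedSequence | list = 0,
    meta: dict | None = None,
    amplitude_multiplier: float = 1.0,
) -> LandmarkStream:
    """One synthetic recording: neutral face + jitter + cued expression.

    During the trailing ``window_s`` the landmarks of each AU ramp
    sigmoidally to the profile amplitude and vibrate; the vibration is
    gated by the same ramp so the pre-onset window stays neutral.
    Deterministic for a fixed seed.
    """
    if not 0 < profile.vibration_hz < fps / 2:
        raise ValueError("vibration frequency must lie below Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    template = neutral_face_template()
    frames = np.broadcast_to(template, (n, 68, 2)).copy()
    if profile.noise_sd > 0:
        frames += rng.normal(0.0, profile.noise_sd, size=(n, 68, 2))

    onset_time = profile.onset_time_s
    if onset_time is None:
        onset_time = duration_s - window_s / 2.0
    k = np.log(81.0) / profile.ramp_s  # 10-90% rise over ramp_s
    activation = 1.0 / (1.0 + np.exp(-k * (t - onset_time)))

    f_pos = profile.vibration_hz / 2.0  # positional oscillation; |delta| vibrates at vibration_hz
    direction = np.array([0.0, -1.0])  # upward in image coordinates
    for d in au_definitions():
        mult = amplitude_multiplier * (profile.asymmetry if d.side == "left" else 1.0)
        amp = profile.onset_amplitude[d.name] * mult
        vib = profile.vibration_amplitude[d.name] * mult
        phase = rng.uniform(0.0, 2.0 * np.pi)
        disp = activation * (amp + vib * np.sin(2.0 * np.pi * f_pos * t + phase))
        frames[:, list(d.landmarks), :] += disp[:, None, None] * direction

    return LandmarkStream(frames=frames, fps=fps, meta=dict(meta or {}))


_BAND_CENTERS = {name: float(np.sqrt(lo * hi)) for name, (lo, hi) in BANDS.items()}


def generate_rr(
    band_shares: tuple[float, float, float] | Mapping[str, float],
    duration_s: float = 210.0,
    seed: int | np.random.SeedSequence | list = 0,
    base_s: float = 0.8,
    mod_sd_s: float = 0.03,
    noise_sd_s: float = 0.002,
    meta: dict | None = None,
) -> RRSeries:
    """RR series with a programmed VLF/LF/HF power composition.

    A 0.8-s base interval is modulated by one sinusoid per band at the
    band's geometric-centre frequency (0.011, 0.077, 0.245 Hz); the
    amplitude of band b is ``mod_sd * sqrt(2 * share_b)`` so the
    modulation variance splits across bands in the requested ratio.
    White per-beat noise of SD ``noise_sd_s`` is added on top.
    """
    if isinstance(band_shares, Mapping):
        shares = (band_shares["vlf"], band_shares["lf"], band_shares["hf"])
    else:
        shares = tuple(float(s) for s in band_shares)
    if len(shares) != 3 or any(s < 0 for s in shares):
        raise ValueError("band shares must be three non-negative numbers")
    if abs(sum(shares) - 1.0) > 1e-9 and sum(shares) > 0:
        raise ValueError("band shares must sum to 1")
    rng = np.random.default_rng(seed)
    freqs = [_BAND_CENTERS["vlf"], _BAND_CENTERS["lf"], _BAND_CENTERS["hf"]]
    amps = [mod_sd_s * np.sqrt(2.0 * s) for s in shares]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)

    intervals = []
    t = 0.0
    while t < duration_s:
        rr = base_s + sum(
            a * np.sin(2.0 * np.pi * f * t + p) for a, f, p in zip(amps, freqs, phases)
        )
        if noise_sd_s > 0:
            rr += rng.normal(0.0, noise_sd_s)
        intervals.append(rr)
        t += rr
    return RRSeries(np.asarray(intervals), meta=dict(meta or {}))


@dataclass
class CohortBundle:
    """A simulated cohort: ground-truth manifest plus lazy data access.

    Streams are regenerated on demand from per-recording seeds rather
    than held in memory (a full default cohort is 320 recordings of
    6300 frames each).
    """

    spec: CohortSpec
    manifest: pd.DataFrame

    def stream(self, subject: int, emotion: str, authenticity: str) -> LandmarkStream:
        row = self._row(subject, emotion, authenticity)
        profile = self.spec.profiles[emotion][authenticity]
        return generate_stream(
            profile,
            fps=self.spec.fps,
            duration_s=self.spec.duration_s,
            window_s=self.spec.window_s,
            seed=[self.spec.seed, int(row.stream_seed)],
            meta={"subject": subject, "emotion": emotion, "authenticity": authenticity},
            amplitude_multiplier=float(row.amplitude_multiplier),
        )

    def rr(self, subject: int, authenticity: str) -> RRSeries:
        sub = self.manifest[
            (self.manifest.subject == subject) & (self.manifest.authenticity == authenticity)
        ].iloc[0]
        return generate_rr(
            self.spec.hrv_shares[authenticity],
            duration_s=self.spec.hrv_duration_s,
            seed=[self.spec.seed, int(sub.rr_seed)],
            mod_sd_s=self.spec.hrv_mod_sd.get(authenticity, 0.03),
            meta={"subject": subject, "authenticity": authenticity},
        )

    def iter_streams(self) -> Iterator[LandmarkStream]:
        for row in self.manifest.itertuples():
            yield self.stream(row.subject, row.emotion, row.authenticity)

    def _row(self, subject: int, emotion: str, authenticity: str):
        m = self.manifest
        sel = m[(m.subject == subject) & (m.emotion == emotion) & (m.authenticity == authenticity)]
        if not len(sel):
            raise KeyError((subject, emotion, authenticity))
        return sel.iloc[0]

    def __len__(self) -> int:
        return len(self.manifest)


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Build the ground-truth manifest of a cohort.

    Every subject receives a lognormal amplitude multiplier (median 1,
    sigma ``spec.subject_sd``) shared across their recordings, and each
    recording a derived seed, so the bundle is fully deterministic under
    ``spec.seed`` while data are generated lazily.
    """
    rng = np.random.default_rng([spec.seed, 777])
    rows = []
    counter = 1
    for subject in range(spec.n_subjects):
        mult = float(np.exp(rng.normal(0.0, spec.subject_sd)))
        for emotion in spec.profiles:
            for authenticity in AUTHENTICITIES:
                profile = spec.profiles[emotion][authenticity]
                onset_time = profile.onset_time_s
                if onset_time is None:
                    onset_time = spec.duration_s - spec.window_s / 2.0
                rows.append(
                    {
                        "subject": subject,
                        "emotion": emotion,
                        "authenticity": authenticity,
                        "amplitude_multiplier": mult,
                        "onset_time_s": onset_time,
                        "vibration_hz": profile.vibration_hz,
                        "stream_seed": counter,
                        "rr_seed": 100_000 + subject * 2 + (authenticity == "fake"),
                    }
                )
                counter += 1
    return CohortBundle(spec=spec, manifest=pd.DataFrame(rows))
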