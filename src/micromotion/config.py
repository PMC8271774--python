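"""Pipeline configuration.

Collects the tunable knobs of the landmark -> feature pipeline in one
place so that the high-level entry points (`feature_table`, cohort
analyses) stay simple.  Defaults reflect the analysis conditions the
package is designed around: 30 fps video, a 30-s trailing analysis
window, onset thresholding on a lightly smoothed displacement signal,
and spectral peak search restricted to the 2 Hz - Nyquist micromovement
band (vibration periods of 0.04-0.5 s correspond to 2-25 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class PipelineConfig:
    #: trailing analysis window length (s)
    window_s: float = 30.0
    #: seconds of the window start used for the neutral baseline position
    baseline_s: float = 1.0
    #: moving-average width (frames) applied before onset thresholding;
    #: 1 disables smoothing
    smooth_window: int = 5
    #: use a single global onset (median of per-AU onsets) for all AUs;
    #: False detects one onset per AU
    global_onset: bool = True
    #: lower edge of the dominant-peak search band (Hz); the upper edge
    #: is Nyquist
    band_low_hz: float = 2.0
    #: standard-deviation convention for delta summaries (0 = population)
    sd_ddof: int = 0
    #: compute features on per-axis deltas instead of Euclidean magnitude
    per_axis: bool = False
    #: apply a Hann taper before the dominant-peak FFT (off: sections are
    #: short and the statistic is a peak location)
    hann: bool = False
    #: optional reference face width (px); if set, coordinates are scaled
    #: so that the face width becomes this value before analysis, for
    #: cross-subject pooling of raw-pixel features
    normalize_width: float | None = None


DEFAULT_CONFIG = PipelineConfig()
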