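"""Cohort-level convenience entry points.

Glue between the synthetic cohort bundle (or any collection of landmark
streams / RR series) and the statistical comparison layer.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .au import LandmarkStream, extract_analysis_window, extract_au_trajectories
from .config import DEFAULT_CONFIG, PipelineConfig
from .features import feature_table
from .hrv import band_powers
from .segmentation import detect_onset, global_onset, movement_signal, segment
from .simulate import CohortBundle
from .stats import collapsed_comparison, comparison_grid, hrv_comparison

__all__ = [
    "segment_report",
    "cohort_feature_table",
    "cohort_hrv_table",
    "analyze_cohort",
]


def segment_report(
    stream: LandmarkStream, config: PipelineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-AU section table: one row per AU x section with frame ranges.

    Columns: subject, emotion, authenticity, au, onset_frame, section,
    start, end (half-open, window-relative), truncated.
    """
    window = extract_analysis_window(stream, config.window_s)
    trajectories = extract_au_trajectories(window)
    signals = [movement_signal(t, baseline_s=config.baseline_s) for t in trajectories]
    if config.global_onset:
        onsets = [global_onset(signals, config.smooth_window)] * len(trajectories)
    else:
        onsets = [detect_onset(s, config.smooth_window) for s in signals]
    meta = stream.meta
    rows = []
    for traj, onset in zip(trajectories, onsets):
        seg = segment(traj, onset)
        for name, sec in seg.sections.items():
            rows.append(
                {
                    "subject": meta.get("subject"),
                    "emotion": meta.get("emotion"),
                    "authenticity": meta.get("authenticity"),
                    "au": traj.au.name,
                    "onset_frame": onset,
                    "section": name,
                    "start": sec.start,
                    "end": sec.stop,
                    "truncated": sec.truncated,
                }
            )
    return pd.DataFrame(rows)


def cohort_feature_table(
    streams: Iterable[LandmarkStream],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Concatenated per-recording feature tables for a stream collection."""
    tables = [feature_table(s, config) for s in streams]
    if not tables:
        raise ValueError("no streams given")
    return pd.concat(tables, ignore_index=True)


def cohort_hrv_table(bundle: CohortBundle) -> pd.DataFrame:
    """Per subject x condition HRV band variables for a simulated cohort."""
    rows = []
    for subject in sorted(bundle.manifest.subject.unique()):
        for authenticity in ("real", "fake"):
            res = band_powers(bundle.rr(subject, authenticity))
            rows.append({"subject": subject, "authenticity": authenticity, **res.as_dict()})
    return pd.DataFrame(rows)


def analyze_cohort(
    bundle: CohortBundle,
    config: PipelineConfig = DEFAULT_CONFIG,
    hrv: bool = True,
) -> dict:
    """Run the full analysis on a simulated cohort.

    Returns a dict with the feature table, the per-cell comparison grid
    and face-grid layout, the collapsed per-emotion summaries, and (when
    ``hrv`` is set) the HRV table and its real-vs-fake comparison.
    """
    features = cohort_feature_table(bundle.iter_streams(), config)
    cells, grid = comparison_grid(features)
    out = {
        "features": features,
        "cells": cells,
        "face_grid": grid,
        "collapsed": collapsed_comparison(features),
    }
    if hrv:
        hrv_table = cohort_hrv_table(bundle)
        out["hrv"] = hrv_table
        out["hrv_cells"] = hrv_comparison(hrv_table)
    return out
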