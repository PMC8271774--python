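"""File formats for landmark streams, RR series and result tables.

Landmark streams travel as a wide CSV with header
``frame,x0,y0,...,x67,y67`` plus a JSON sidecar holding ``fps`` and the
condition metadata, or as a single JSON file bundling both.  RR input is
a one-column CSV of intervals in seconds (optionally two columns:
time, interval); ECG input is a one-column CSV at a stated sampling
rate.  Result writers emit tidy CSVs for features, segment reports and
comparison cells, and a JSON face grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .au import N_LANDMARKS, LandmarkStream
from .hrv import HRVResult, RRSeries

__all__ = [
    "write_landmark_csv",
    "read_landmark_csv",
    "write_landmark_json",
    "read_landmark_json",
    "read_rr_csv",
    "write_rr_csv",
    "read_ecg_csv",
    "write_hrv_csv",
    "write_face_grid_json",
]

_META_KEYS = ("subject", "emotion", "authenticity")

_COLUMNS = ["frame"] + [f"{axis}{i}" for i in range(N_LANDMARKS) for axis in ("x", "y")]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_landmark_csv(stream: LandmarkStream, path: str | Path) -> None:
    """Write a stream as wide CSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    flat = stream.frames.reshape(stream.n_frames, -1)
    df = pd.DataFrame(flat, columns=_COLUMNS[1:])
    df.insert(0, "frame", np.arange(stream.start_index, stream.start_index + stream.n_frames))
    df.to_csv(path, index=False)
    sidecar = {"fps": stream.fps, **{k: stream.meta.get(k) for k in _META_KEYS}}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_landmark_csv(path: str | Path, fps: float | None = None) -> LandmarkStream:
    """Read a wide landmark CSV; fps/meta come from the sidecar unless given."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns: {missing[:4]}...")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        fps = fps if fps is not None else data.get("fps")
        meta = {k: data.get(k) for k in _META_KEYS}
    if fps is None:
        raise ValueError("fps not given and no sidecar found")
    frames = df[_COLUMNS[1:]].to_numpy(dtype=float).reshape(len(df), N_LANDMARKS, 2)
    return LandmarkStream(frames=frames, fps=float(fps), meta=meta,
                          start_index=int(df["frame"].iloc[0]))


def write_landmark_json(stream: LandmarkStream, path: str | Path) -> None:
    """Single-file JSON dialect bundling frames and metadata."""
    payload = {
        "fps": stream.fps,
        "start_index": stream.start_index,
        "meta": {k: stream.meta.get(k) for k in _META_KEYS},
        "frames": stream.frames.reshape(stream.n_frames, -1).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_landmark_json(path: str | Path) -> LandmarkStream:
    data = json.loads(Path(path).read_text())
    frames = np.asarray(data["frames"], dtype=float).reshape(-1, N_LANDMARKS, 2)
    return LandmarkStream(
        frames=frames,
        fps=float(data["fps"]),
        meta=data.get("meta", {}),
        start_index=int(data.get("start_index", 0)),
    )


def read_rr_csv(path: str | Path, meta: dict | None = None) -> RRSeries:
    """RR intervals in seconds: one column, or two columns (time, interval)."""
    df = pd.read_csv(path)
    col = df.columns[-1]  # interval column is the last (only, or second of two)
    return RRSeries(df[col].to_numpy(dtype=float), meta=meta or {})


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    pd.DataFrame({"rr_s": rr.intervals}).to_csv(path, index=False)


def read_ecg_csv(path: str | Path) -> np.ndarray:
    """Single-channel ECG voltages, one column; sampling rate is external."""
    return pd.read_csv(path).iloc[:, 0].to_numpy(dtype=float)


_TABLE_NAMES = {  # output names mirror the reporting convention
    "vlf": "VLF", "lf": "LF", "hf": "HF",
    "vlf_pct": "VLF (%)", "lf_pct": "LF (%)", "hf_pct": "HF (%)",
}


def write_hrv_csv(result: HRVResult | pd.DataFrame, path: str | Path) -> None:
    """Write band powers (single result or sliding-window time course)."""
    if isinstance(result, HRVResult):
        df = pd.DataFrame([result.as_dict()])
    else:
        df = result.copy()
    df = df.rename(columns=_TABLE_NAMES)
    df.to_csv(path, index=False)


def write_face_grid_json(grid: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(grid, indent=1))


def write_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Tidy-table writer for feature tables, segment reports and cell grids."""
    df.to_csv(path, index=False)


def write_cohort_spec_yaml(spec, path: str | Path) -> None:
    """Serialise a CohortSpec (including nested profiles) to YAML."""
    import yaml

    from .simulate import CohortSpec, ExpressionProfile  # noqa: F401

    def profile_dict(p):
        return {
            "emotion": p.emotion,
            "onset_amplitude": dict(p.onset_amplitude),
            "vibration_amplitude": dict(p.vibration_amplitude),
            "vibration_hz": p.vibration_hz,
            "asymmetry": p.asymmetry,
            "ramp_s": p.ramp_s,
            "onset_time_s": p.onset_time_s,
            "noise_sd": p.noise_sd,
        }

    payload = {
        "n_subjects": spec.n_subjects,
        "fps": spec.fps,
        "duration_s": spec.duration_s,
        "window_s": spec.window_s,
        "hrv_duration_s": spec.hrv_duration_s,
        "subject_sd": spec.subject_sd,
        "seed": spec.seed,
        "hrv_shares": {k: list(v) for k, v in spec.hrv_shares.items()},
        "hrv_mod_sd": dict(spec.hrv_mod_sd),
        "profiles": {
            emo: {auth: profile_dict(p) for auth, p in pair.items()}
            for emo, pair in spec.profiles.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_cohort_spec_yaml(path: str | Path):
    """Load a CohortSpec from the YAML dialect of :func:`write_cohort_spec_yaml`."""
    import yaml

    from .simulate import CohortSpec, ExpressionProfile

    data = yaml.safe_load(Path(path).read_text())
    profiles = {
        emo: {auth: ExpressionProfile(**p) for auth, p in pair.items()}
        for emo, pair in data.pop("profiles").items()
    }
    hrv_shares = {k: tuple(v) for k, v in data.pop("hrv_shares").items()}
    return CohortSpec(profiles=profiles, hrv_shares=hrv_shares, **data)
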