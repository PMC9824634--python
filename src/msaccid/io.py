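"""Readers and writers for the package's plain-text artifacts.

Formats, declared once and used everywhere:

* traces        — CSV with header ``time_ms,x_deg,y_deg``;
* event points  — JSON, a list of events, each an array of [x, y] pairs;
* intervals     — BED-like 3-column text: trace_id, start, end
                  (0-based, half-open);
* features      — CSV, one row per event: person_id, fixation_id,
                  event_index, the 13 named feature columns;
* weights       — JSON with "singles" (13), "cross" (78) and the layout tag;
* config        — YAML.

Floats are serialized with 17 significant digits so write/read
round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GazeTrace, TraceError
from .features import FEATURE_NAMES, N_FEATURES, segment_features
from .metric import N_WEIGHTS, check_weights

_REQUIRED_COLS = ("time_ms", "x_deg", "y_deg")


def read_trace(path, expected_rate_hz: float | None = None) -> GazeTrace:
    """Load a trace CSV; the rate is inferred from the time column.

    Raises a structured error naming the offending line for missing
    columns, NaNs, or non-uniform sampling (step deviations > 1%).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise TraceError(f"{path}: missing required column {col!r}")
    if len(df) < 2:
        raise TraceError(f"{path}: need at least 2 samples")
    bad = df[list(_REQUIRED_COLS)].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.values)[0]) + 2  # header is line 1
        raise TraceError(f"{path}: NaN value at line {line}")
    t = df["time_ms"].to_numpy(dtype=float)
    steps = np.diff(t)
    step = np.median(steps)
    if step <= 0:
        raise TraceError(f"{path}: time column must be strictly increasing")
    dev = np.abs(steps - step) / step
    if np.any(dev > 0.01):
        line = int(np.flatnonzero(dev > 0.01)[0]) + 2
        raise TraceError(
            f"{path}: non-uniform sampling near line {line} "
            f"(step deviates more than 1%)"
        )
    rate = 1000.0 / step
    if expected_rate_hz is not None and abs(rate - expected_rate_hz) > 0.01 * expected_rate_hz:
        raise TraceError(
            f"{path}: inferred rate {rate:.1f} Hz does not match "
            f"configured {expected_rate_hz} Hz"
        )
    return GazeTrace(
        x=df["x_deg"].to_numpy(dtype=float),
        y=df["y_deg"].to_numpy(dtype=float),
        rate_hz=rate,
    )


def write_trace(trace: GazeTrace, path) -> None:
    t = np.arange(len(trace)) * trace.dt_ms
    df = pd.DataFrame({"time_ms": t, "x_deg": trace.x, "y_deg": trace.y})
    df.to_csv(path, index=False, float_format="%.17g")


def write_intervals(intervals, path, trace_id: str = "trace") -> None:
    """BED-like: trace_id, start, end (0-based half-open), tab-separated."""
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{trace_id}\t{s}\t{e}\n")


def read_intervals(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                _, s, e = line.split("\t")
                out.append((int(s), int(e)))
    return out


def write_truth(intervals, path) -> None:
    with open(path, "w") as fh:
        json.dump({"intervals": [[int(s), int(e)] for s, e in intervals]}, fh)


def read_truth(path) -> list:
    with open(path) as fh:
        return [tuple(iv) for iv in json.load(fh)["intervals"]]


def write_segment_json(segment, path) -> None:
    """Events as a JSON list; each event is an array of [x, y] points."""
    events = [m.points.tolist() for m in segment.microsaccades]
    with open(path, "w") as fh:
        json.dump(events, fh)


def write_features_csv(records, path) -> None:
    """Feature table: one row per microsaccade across a set of PersonRecords."""
    rows = []
    for rec in records:
        for seg in rec.segments:
            F = segment_features(seg)
            for i, row in enumerate(F):
                rows.append(
                    {"person_id": rec.person_id, "fixation_id": seg.fixation_id,
                     "event_index": i,
                     **{name: val for name, val in zip(FEATURE_NAMES, row)}}
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_scales(scales: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        json.dump({"scales": list(map(float, scales)),
                   "features": list(FEATURE_NAMES)}, fh)


def write_weights(w: np.ndarray, path, err_star: float | None = None) -> None:
    w = check_weights(w)
    payload = {
        "singles": [float(v) for v in w[:N_FEATURES]],
        "cross": [float(v) for v in w[N_FEATURES:]],
        "layout": "i<j lexicographic",
    }
    if err_star is not None:
        payload["err"] = float(err_star)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_weights(path) -> np.ndarray:
    with open(path) as fh:
        payload = json.load(fh)
    w = np.array(payload["singles"] + payload["cross"], dtype=float)
    if w.shape != (N_WEIGHTS,):
        raise TraceError(f"{path}: weight file does not contain {N_WEIGHTS} entries")
    return w


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
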