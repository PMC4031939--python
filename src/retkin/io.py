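"""File formats: model definition files, tracer-curve CSV, report writers.

One canonical CSV dialect throughout: comma-separated, UTF-8, '.' decimal,
header required, units embedded in column names.  Model definitions
round-trip losslessly through YAML (time-varying hooks are runtime objects
and are not serialized).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CompartmentalModel, TracerCurve

__all__ = [
    "save_model",
    "load_model",
    "save_curve",
    "load_curve",
    "config_hash",
    "write_json",
]

CURVE_COLUMNS = ("group", "time_days", "fraction_of_dose")


def save_model(model: CompartmentalModel, path) -> None:
    path = Path(path)
    path.write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def load_model(path) -> CompartmentalModel:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: not a model definition file")
    return CompartmentalModel.from_dict(data)


def save_curve(curve: TracerCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


def load_curve(path, group: str | None = None) -> TracerCurve:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(("time_days", "fraction_of_dose")) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if group is not None and "group" in df.columns:
        sub = df[df["group"] == group]
        if sub.empty:
            raise ValueError(f"{path}: no rows for group {group!r}")
        df = sub
    times = df["time_days"].to_numpy(dtype=float)
    dup = pd.Series(times).duplicated()
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate time_days values at lines {lines}")
    order = np.argsort(times, kind="stable")
    if not np.array_equal(order, np.arange(len(times))):
        bad = (df.index[np.flatnonzero(np.diff(times) <= 0) + 1] + 2).tolist()
        raise ValueError(
            f"{path}: time_days not strictly increasing (first offending "
            f"lines {bad[:5]})"
        )
    return TracerCurve.from_frame(df, group=group)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for provenance stamps."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
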