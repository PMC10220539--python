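"""Trajectory CSV interchange, gap filling and sweep configuration.

The on-disk layout is one long-format CSV with columns ``trajectory_id``,
``sensor_id``, ``time_s``, ``position``, ``class_label`` — one row per
sample per sensor.  Missing positions (sensor drop-outs) may be encoded as
empty cells or NaN and are repaired with piecewise cubic spline
interpolation before analysis.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline

from .simulate import RIGID_SENSOR, Trajectory, TrajectoryDataset

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "dataset_from_frame",
    "fill_gaps",
    "load_sweep_config",
    "write_run_config",
]

REQUIRED_COLUMNS = ("trajectory_id", "sensor_id", "time_s", "position", "class_label")

_DT_TOLERANCE = 0.01  # relative spread of sampling intervals allowed


def write_trajectories(dataset: TrajectoryDataset, path) -> None:
    """Write a dataset to the long-format CSV layout."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.12g")


def _validate_columns(frame: pd.DataFrame, source: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {', '.join(missing)}")


def _coerce_numeric(frame: pd.DataFrame, column: str, source: str,
                    allow_nan: bool = False) -> pd.Series:
    coerced = pd.to_numeric(frame[column], errors="coerce")
    bad = coerced.isna() & frame[column].notna() & (frame[column].astype(str).str.strip() != "")
    if bad.any():
        row = int(frame.index[bad][0]) + 2  # header line + 1-based
        raise ValueError(f"{source}: non-numeric value in column {column!r} at row {row}")
    if not allow_nan and coerced.isna().any():
        row = int(frame.index[coerced.isna()][0]) + 2
        raise ValueError(f"{source}: missing value in column {column!r} at row {row}")
    return coerced


def dataset_from_frame(frame: pd.DataFrame, source: str = "<frame>",
                       fill_missing: bool = True) -> TrajectoryDataset:
    """Build a :class:`TrajectoryDataset` from a long-format table.

    Rows are grouped by (trajectory_id, sensor_id) and time-sorted, so row
    order on disk is irrelevant.  The sampling interval must be constant to
    within 1% within every channel.  Missing positions are spline-filled
    (see :func:`fill_gaps`) when ``fill_missing`` is true.
    """
    _validate_columns(frame, source)
    frame = frame.copy()
    frame["time_s"] = _coerce_numeric(frame, "time_s", source)
    frame["position"] = _coerce_numeric(frame, "position", source, allow_nan=True)
    frame["class_label"] = _coerce_numeric(frame, "class_label", source).astype(int)

    trajectories = []
    for tid, group in frame.groupby("trajectory_id", sort=True):
        labels = group["class_label"].unique()
        if len(labels) != 1:
            raise ValueError(f"{source}: trajectory {tid} has conflicting class labels {labels}")
        channels: dict[str, np.ndarray] = {}
        times_ref = None
        for sid, chan in group.groupby("sensor_id"):
            chan = chan.sort_values("time_s")
            t = chan["time_s"].to_numpy()
            pos = chan["position"].to_numpy()
            if len(t) < 2:
                raise ValueError(f"{source}: trajectory {tid} sensor {sid} has <2 samples")
            dt = np.diff(t)
            if dt.min() <= 0:
                raise ValueError(f"{source}: trajectory {tid} sensor {sid} has duplicate times")
            if (dt.max() - dt.min()) > _DT_TOLERANCE * np.median(dt):
                raise ValueError(
                    f"{source}: trajectory {tid} sensor {sid} sampling interval varies "
                    f"by more than {_DT_TOLERANCE:.0%} (min {dt.min():.6g}, max {dt.max():.6g})"
                )
            if fill_missing and np.isnan(pos).any():
                t, pos = fill_gaps(t, pos)
            channels[str(sid)] = pos
            times_ref = t
        rigid = channels.pop(RIGID_SENSOR, None)
        trajectories.append(Trajectory(
            times=times_ref,
            rigid=rigid,
            fabric=channels,
            label=int(labels[0]),
            omega=float("nan"),
            phase=float("nan"),
            trajectory_id=int(tid) if str(tid).isdigit() else tid,
        ))
    return TrajectoryDataset(trajectories)


def read_trajectories(path) -> TrajectoryDataset:
    """Read a trajectory CSV (see module docstring for the layout)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    return dataset_from_frame(frame, source=str(path))


def fill_gaps(times: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Repair missing samples with piecewise cubic spline interpolation.

    Interior NaNs are replaced by a cubic spline through the retained
    samples (which are left untouched); leading/trailing NaNs cannot be
    interpolated and are trimmed with a warning.  Needs at least 4 retained
    samples.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    ok = ~np.isnan(positions)
    if not ok.any():
        raise ValueError("channel contains no valid samples")
    first, last = np.argmax(ok), len(ok) - 1 - np.argmax(ok[::-1])
    if first > 0 or last < len(ok) - 1:
        warnings.warn(
            f"trimming {first + (len(ok) - 1 - last)} leading/trailing missing samples",
            stacklevel=2,
        )
        times, positions, ok = times[first:last + 1], positions[first:last + 1], ok[first:last + 1]
    if ok.sum() < 4:
        raise ValueError(f"need >=4 valid samples for cubic interpolation, got {int(ok.sum())}")
    if ok.all():
        return times, positions
    spline = CubicSpline(times[ok], positions[ok])
    filled = positions.copy()
    filled[~ok] = spline(times[~ok])
    return times, filled


def load_sweep_config(path) -> dict:
    """Load a YAML sweep configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: sweep configuration must be a mapping")
    return cfg


def write_run_config(out_dir, config: dict) -> Path:
    """Persist the fully resolved run configuration (audit trail)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.json"
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
    return path
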