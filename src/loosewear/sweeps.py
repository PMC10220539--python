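"""Scripted experiment sweeps: window-size and frequency-difference studies.

Each sweep repeats the full protocol — simulate a fresh dataset, split it at
the trajectory level, window, standardise, train the SVM, score — for every
condition (sensor x window size, or sensor x frequency pair) and returns a
long-format table with one row per trial.  Aggregation helpers reduce the
table to mean +/- sd per condition, and the frequency sweep additionally
relates the empirical/analytic KS distance ``D`` to accuracy via Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import ks_distance_fabric, ks_distance_rigid
from .recognition import ActivityRecognition, ClassifierConfig
from .simulate import RIGID_SENSOR, DatasetSpec, generate_dataset

__all__ = [
    "SweepSpec",
    "run_window_sweep",
    "run_frequency_sweep",
    "aggregate",
    "d_accuracy_correlation",
]

_DEFAULT_WINDOWS_S = (0.1, 0.2, 0.5, 1.0, 2.5)


@dataclass(frozen=True)
class SweepSpec:
    """Configuration of a repeated-protocol sweep.

    ``resimulate=True`` (default) regenerates the dataset every trial (fresh
    phases and fabric noise); ``False`` simulates once and only re-splits.
    """

    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    window_sizes_s: tuple[float, ...] = _DEFAULT_WINDOWS_S
    omega_high_values: tuple[float, ...] = (1.2, 1.5, 2.0, 3.0, 4.0)
    repeats: int = 100
    seed: int = 0
    resimulate: bool = True
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    sensors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        K = self.dataset.n_samples
        for w in self.window_sizes_s:
            i = max(1, int(round(w * self.dataset.fs)))
            if i > K:
                raise ValueError(
                    f"window {w} s is {i} samples but trajectories have only {K}"
                )

    def sensor_ids(self) -> tuple[str, ...]:
        return self.sensors if self.sensors is not None else tuple(self.dataset.sensor_ids)


def _condition_columns(spec: DatasetSpec, sensor: str) -> dict:
    return {
        "sensor_id": sensor,
        "L": np.nan if sensor == RIGID_SENSOR else spec.fabric_length_of(sensor),
        "omega_low": spec.omega_low,
        "omega_high": spec.omega_high,
    }


def run_window_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Accuracy of every sensor at every window size, per trial.

    Returns a long table with columns sensor_id, L, omega_low, omega_high,
    window_s, window_samples, trial, accuracy, ks_stat, seed.  Fully
    reproducible from ``spec.seed``.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.repeats)
    base = spec.dataset
    rows = []
    dataset = generate_dataset(base) if not spec.resimulate else None
    for trial, stream in enumerate(streams):
        child = stream.spawn(2)
        if spec.resimulate:
            trial_seed = int(child[0].generate_state(1)[0] % (2**31))
            dataset = generate_dataset(replace(base, seed=trial_seed))
        split_seed = int(child[1].generate_state(1)[0] % (2**31))
        for sensor in spec.sensor_ids():
            for w_s in spec.window_sizes_s:
                model = ActivityRecognition(dataset, sensor, w_s, spec.classifier)
                res = model.fit(n_trials=1, seed=split_seed)
                rows.append({
                    **_condition_columns(base, sensor),
                    "window_s": w_s,
                    "window_samples": model.window_len,
                    "trial": trial,
                    "accuracy": res.accuracies[0],
                    "ks_stat": res.ks_stats[0],
                    "seed": spec.seed,
                })
    return pd.DataFrame(rows)


def run_frequency_sweep(spec: SweepSpec, window_s: float | None = None) -> pd.DataFrame:
    """Accuracy and KS distance across frequency gaps at one small window.

    For each ``omega_high`` in ``spec.omega_high_values`` the dataset is
    re-specified with that class-1 frequency (class 0 stays at
    ``dataset.omega_low``) and evaluated at ``window_s`` (default: the
    smallest window in ``spec.window_sizes_s``).  Output columns add
    ``ks_analytic``, the model-predicted KS distance for the condition.
    """
    w_s = min(spec.window_sizes_s) if window_s is None else window_s
    streams = np.random.SeedSequence(spec.seed).spawn(spec.repeats)
    rows = []
    for trial, stream in enumerate(streams):
        children = stream.spawn(len(spec.omega_high_values))
        for omega_high, child in zip(spec.omega_high_values, children):
            if omega_high < spec.dataset.omega_low:
                raise ValueError(
                    f"omega_high {omega_high} below omega_low {spec.dataset.omega_low}"
                )
            sub = child.spawn(2)
            if omega_high > spec.dataset.omega_low:
                base = replace(spec.dataset, omega_high=omega_high)
            else:
                # degenerate condition: both classes effectively at omega_low
                base = replace(spec.dataset,
                               omega_high=np.nextafter(spec.dataset.omega_low, np.inf))
            trial_seed = int(sub[0].generate_state(1)[0] % (2**31))
            dataset = generate_dataset(replace(base, seed=trial_seed)) \
                if spec.resimulate else generate_dataset(base)
            split_seed = int(sub[1].generate_state(1)[0] % (2**31))
            for sensor in spec.sensor_ids():
                model = ActivityRecognition(dataset, sensor, w_s, spec.classifier)
                res = model.fit(n_trials=1, seed=split_seed)
                if sensor == RIGID_SENSOR:
                    d_true = ks_distance_rigid(spec.dataset.omega_low, omega_high)
                else:
                    L = spec.dataset.fabric_length_of(sensor)
                    d_true = ks_distance_fabric(spec.dataset.omega_low,
                                                max(omega_high, spec.dataset.omega_low),
                                                L)
                rows.append({
                    **_condition_columns(base, sensor),
                    "omega_high": omega_high,
                    "window_s": w_s,
                    "window_samples": model.window_len,
                    "trial": trial,
                    "accuracy": res.accuracies[0],
                    "ks_stat": res.ks_stats[0],
                    "ks_analytic": d_true,
                    "seed": spec.seed,
                })
    return pd.DataFrame(rows)


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of accuracy (and KS) per condition over trials."""
    keys = [c for c in ("sensor_id", "L", "omega_low", "omega_high",
                        "window_s", "window_samples") if c in results.columns]
    agg = {"accuracy": ["mean", "std"], "ks_stat": ["mean", "std"]}
    if "ks_analytic" in results.columns:
        agg["ks_analytic"] = ["first"]
    out = results.groupby(keys, dropna=False).agg(agg)
    out.columns = ["_".join(c).rstrip("_").replace("_first", "") for c in out.columns]
    return out.reset_index()


def d_accuracy_correlation(results: pd.DataFrame, sensor_ids=None,
                           use_analytic: bool = False) -> float:
    """Pearson correlation between KS distance D and mean accuracy.

    Computed across frequency-sweep conditions (mean over trials per
    condition), for fabric sensors by default.
    """
    df = results
    if sensor_ids is None:
        df = df[df["sensor_id"] != RIGID_SENSOR]
    else:
        df = df[df["sensor_id"].isin(sensor_ids)]
    col = "ks_analytic" if use_analytic else "ks_stat"
    per_cond = df.groupby(["sensor_id", "omega_high"], dropna=False).agg(
        accuracy=("accuracy", "mean"), d=(col, "mean")).reset_index()
    if len(per_cond) < 3:
        raise ValueError("need at least 3 conditions for a correlation")
    return float(stats.pearsonr(per_cond["d"], per_cond["accuracy"]).statistic)
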