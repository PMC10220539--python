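"""Stochastic scotch-yoke simulator: labelled rigid and fabric trajectories.

Generates the synthetic two-class datasets used throughout the evaluation
protocol: each trajectory is a sinusoid sampled on a regular grid with a
fresh uniformly random starting phase, and, per fabric length, a noisy copy
obtained by adding an independent uniform offset ``delta_k ~ U(-zL, zL)`` at
every sample (``z`` the frequency-dependent excitation factor).  Class 0
moves at the low frequency, class 1 at the high frequency.

The per-sample offsets are white by default — the model only constrains the
marginal of the offset, not its temporal correlation.  An optional
moving-average smoothing length is exposed for qualitative realism and is
off everywhere in the shipped protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distributions import FabricSpec, HarmonicMotionSpec, excitation_factor

__all__ = [
    "DatasetSpec",
    "Trajectory",
    "TrajectoryDataset",
    "sample_phase",
    "simulate_trajectory",
    "generate_dataset",
]

RIGID_SENSOR = "R1"


def fabric_sensor_ids(n: int) -> list[str]:
    return [f"F{k + 1}" for k in range(n)]


@dataclass(frozen=True)
class DatasetSpec:
    """Configuration of one simulated two-class dataset.

    Defaults reproduce the simulated scotch-yoke study: 200 trajectories per
    class at 1 vs 2 rad/s, duration ``2*pi`` s sampled at 10 Hz (63 samples),
    amplitude 1, fabric lengths 1/3, 2/3 and 1 (sensors F1-F3) alongside the
    rigid sensor R1.
    """

    n_per_class: int = 200
    omega_low: float = 1.0
    omega_high: float = 2.0
    fabric_lengths: tuple[float, ...] = (1.0 / 3.0, 2.0 / 3.0, 1.0)
    fs: float = 10.0
    duration: float = 2.0 * np.pi
    amplitude: float = 1.0
    seed: int = 0
    smooth_len: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0 < self.omega_low < self.omega_high:
            raise ValueError(
                f"need 0 < omega_low < omega_high, got {self.omega_low}, {self.omega_high}"
            )
        if not (self.fs > 0 and self.duration > 0):
            raise ValueError("fs and duration must be positive")
        if self.n_samples < 2:
            raise ValueError("duration * fs must give at least 2 samples")
        for L in self.fabric_lengths:
            FabricSpec(L)  # validates range

    @property
    def n_samples(self) -> int:
        """Samples per trajectory, ``K = round(duration * fs)``."""
        return int(round(self.duration * self.fs))

    @property
    def sensor_ids(self) -> list[str]:
        return [RIGID_SENSOR] + fabric_sensor_ids(len(self.fabric_lengths))

    def fabric_length_of(self, sensor_id: str) -> float | None:
        """Fabric length behind a sensor id; None for the rigid sensor."""
        if sensor_id == RIGID_SENSOR:
            return None
        idx = fabric_sensor_ids(len(self.fabric_lengths)).index(sensor_id)
        return self.fabric_lengths[idx]


@dataclass(frozen=True)
class Trajectory:
    """One labelled recording: a rigid channel plus fabric channels.

    ``rigid`` may be None for ingested recordings without a rigid sensor.
    """

    times: np.ndarray
    rigid: np.ndarray | None
    fabric: dict[str, np.ndarray]
    label: int
    omega: float
    phase: float
    trajectory_id: int = 0

    @property
    def sensor_ids(self) -> list[str]:
        ids = [RIGID_SENSOR] if self.rigid is not None else []
        return ids + sorted(self.fabric)

    def channel(self, sensor_id: str) -> np.ndarray:
        if sensor_id == RIGID_SENSOR and self.rigid is not None:
            return self.rigid
        try:
            return self.fabric[sensor_id]
        except KeyError:
            raise KeyError(f"trajectory {self.trajectory_id} has no sensor {sensor_id!r}") from None

    @property
    def n_samples(self) -> int:
        return len(self.times)


def sample_phase(rng: np.random.Generator) -> float:
    """Starting wheel angle, uniform on ``[-pi, pi)``."""
    return float(rng.uniform(-np.pi, np.pi))


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    # reflect-pad so the smoothed offset keeps the trajectory length
    pad = width // 2
    xp = np.pad(x, (pad, width - 1 - pad), mode="reflect")
    return np.convolve(xp, kernel, mode="valid")


def simulate_trajectory(
    motion: HarmonicMotionSpec,
    fabrics: Sequence[FabricSpec],
    fs: float,
    duration: float,
    rng: np.random.Generator,
    label: int = 0,
    trajectory_id: int = 0,
    smooth_len: int | None = None,
) -> Trajectory:
    """Simulate one trajectory of the rigid body and its fabric sensors.

    The rigid channel is the exact sinusoid; each fabric channel adds a
    fresh uniform offset per sample with half-width
    ``zL = excitation_factor(omega) * L``.  An empty ``fabrics`` sequence
    yields a rigid-only trajectory.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError(f"duration*fs = {duration * fs:.3g} gives fewer than 2 samples")
    times = np.arange(n) / fs
    u = motion.positions(times)
    z = float(excitation_factor(motion.omega))
    fabric: dict[str, np.ndarray] = {}
    for sid, spec in zip(fabric_sensor_ids(len(fabrics)), fabrics):
        # fabric length is a fraction of the amplitude; offsets scale with it
        zl = z * spec.length * motion.amplitude
        delta = rng.uniform(-zl, zl, n)
        if smooth_len and smooth_len > 1:
            delta = _moving_average(delta, smooth_len)
            # renormalise so the marginal width is preserved after averaging
            delta = np.clip(delta * np.sqrt(smooth_len), -zl, zl)
        fabric[sid] = u + delta
    return Trajectory(times=times, rigid=u, fabric=fabric, label=label,
                      omega=motion.omega, phase=motion.phase,
                      trajectory_id=trajectory_id)


class TrajectoryDataset:
    """A labelled collection of simulated (or ingested) trajectories."""

    def __init__(self, trajectories: Sequence[Trajectory], spec: DatasetSpec | None = None):
        if not trajectories:
            raise ValueError("dataset must contain at least one trajectory")
        self.trajectories = list(trajectories)
        self.spec = spec

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trajectories])

    @property
    def sensor_ids(self) -> list[str]:
        return self.trajectories[0].sensor_ids

    def positions(self, sensor_id: str) -> np.ndarray:
        """Stacked channel matrix of shape (n_trajectories, n_samples)."""
        return np.stack([t.channel(sensor_id) for t in self.trajectories])

    def subset(self, indices: Iterable[int]) -> "TrajectoryDataset":
        return TrajectoryDataset([self.trajectories[i] for i in indices], self.spec)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: trajectory_id, sensor_id, time_s, position, class_label."""
        rows = []
        for t in self.trajectories:
            for sid in t.sensor_ids:
                pos = t.channel(sid)
                rows.append(pd.DataFrame({
                    "trajectory_id": t.trajectory_id,
                    "sensor_id": sid,
                    "time_s": t.times,
                    "position": pos,
                    "class_label": t.label,
                }))
        return pd.concat(rows, ignore_index=True)


def generate_dataset(spec: DatasetSpec) -> TrajectoryDataset:
    """Generate the full two-class dataset described by ``spec``.

    ``n_per_class`` trajectories at ``omega_low`` (label 0) then
    ``n_per_class`` at ``omega_high`` (label 1), each with its own phase and
    fabric-noise substream (spawned from one seed sequence, so the result is
    bitwise reproducible and trajectories are mutually independent).
    """
    fabrics = [FabricSpec(L) for L in spec.fabric_lengths]
    streams = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_class)
    trajectories = []
    tid = 0
    for omega, label in ((spec.omega_low, 0), (spec.omega_high, 1)):
        for _ in range(spec.n_per_class):
            rng = np.random.default_rng(streams[tid])
            motion = HarmonicMotionSpec(omega=omega, amplitude=spec.amplitude,
                                        phase=sample_phase(rng))
            trajectories.append(
                simulate_trajectory(motion, fabrics, spec.fs, spec.duration, rng,
                                    label=label, trajectory_id=tid,
                                    smooth_len=spec.smooth_len)
            )
            tid += 1
    return TrajectoryDataset(trajectories, spec)
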