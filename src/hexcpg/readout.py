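"""Rate coding of spike trains and export of motor trajectories.

A population's spike train is converted to an analog signal by counting
spikes inside a sliding 5 ms window — the same low-pass filtering a muscle
applies to its motor-neuron input.  The resulting rate signal is mapped
affinely onto joint angles in radians, clamped to the joint's range of
motion, and exported as one comma-delimited file per joint, optionally
resampled to the 60 Hz rate a position-controlled servo expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cpg_network import SpikeRaster

__all__ = [
    "RateSignal",
    "JointTrajectory",
    "LinearCalibration",
    "rate_code",
    "to_joint_trajectory",
    "export_joint_files",
    "DEFAULT_WINDOW",
]

#: Sliding-window width for rate coding (ms).
DEFAULT_WINDOW = 5.0


@dataclass
class RateSignal:
    """Windowed spike counts of one population on the simulation time grid."""

    times: np.ndarray  # ms, dt-spaced
    counts: np.ndarray  # spikes per window, same length
    window: float  # ms
    population: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def after(self, t_min: float) -> "RateSignal":
        """Restrict the signal to times >= ``t_min`` (transient removal)."""
        mask = self.times >= t_min
        return RateSignal(self.times[mask], self.counts[mask], self.window, self.population)


def rate_code(
    raster: SpikeRaster,
    population: str,
    window: float = DEFAULT_WINDOW,
    mode: str = "centered",
) -> RateSignal:
    """Sliding-window spike count of one population.

    For each grid time ``t`` (the simulation dt grid over [0, duration]) the
    count is the number of population spikes in ``[t - w/2, t + w/2)``
    (``mode="centered"``, the default: recorded data permits looking forward
    in time) or ``(t - w, t]`` (``mode="causal"``, for live-like use).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if mode not in ("centered", "causal"):
        raise ValueError(f"unknown window mode {mode!r}")
    spikes = raster.population_spikes(population)  # raises on unknown label
    n = int(round(raster.duration / raster.dt)) + 1
    times = np.arange(n) * raster.dt
    if mode == "centered":
        lo, hi = times - window / 2.0, times + window / 2.0
        counts = np.searchsorted(spikes, hi, side="left") - np.searchsorted(
            spikes, lo, side="left"
        )
    else:
        lo, hi = times - window, times
        counts = np.searchsorted(spikes, hi, side="right") - np.searchsorted(
            spikes, lo, side="right"
        )
    return RateSignal(times, counts.astype(float), window, population)


@dataclass(frozen=True)
class LinearCalibration:
    """Affine map from window counts to joint angle, with clamping bounds.

    ``position = offset + scale * count`` (radians), clipped to
    ``[lower, upper]``.
    """

    scale: float
    offset: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("bounds must satisfy lower < upper")

    @classmethod
    def from_count_range(
        cls, count_max: float, lower: float, upper: float
    ) -> "LinearCalibration":
        """Map counts [0, count_max] linearly onto the joint range."""
        if count_max <= 0:
            raise ValueError("count_max must be positive")
        return cls((upper - lower) / count_max, lower, lower, upper)

    def apply(self, counts: np.ndarray) -> np.ndarray:
        return np.clip(self.offset + self.scale * np.asarray(counts, float),
                       self.lower, self.upper)

    def invert(self, positions: np.ndarray) -> np.ndarray:
        """Inverse of the unclamped affine map."""
        return (np.asarray(positions, float) - self.offset) / self.scale


@dataclass
class JointTrajectory:
    """Joint angle time series in radians, bounded to the range of motion."""

    times: np.ndarray  # ms
    positions: np.ndarray  # rad
    lower_bound: float
    upper_bound: float
    joint: str


def to_joint_trajectory(
    signal: RateSignal, calibration: LinearCalibration, joint: str | None = None
) -> JointTrajectory:
    """Translate a rate signal into a bounded joint trajectory."""
    return JointTrajectory(
        times=signal.times.copy(),
        positions=calibration.apply(signal.counts),
        lower_bound=calibration.lower,
        upper_bound=calibration.upper,
        joint=joint or signal.population,
    )


def export_joint_files(
    trajectories: list[JointTrajectory],
    out_dir: str | Path,
    resample_hz: float | None = None,
) -> list[Path]:
    """Write one CSV per joint (header ``time_ms,position_rad``).

    With ``resample_hz`` the trajectory is linearly interpolated onto a
    uniform grid at that rate (60 Hz for the servo controller), giving
    ``floor(duration_s * rate) + 1`` rows.
    """
    if not trajectories:
        raise ValueError("no trajectories to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for traj in trajectories:
        times, positions = traj.times, traj.positions
        if resample_hz is not None:
            if resample_hz <= 0:
                raise ValueError("resample rate must be positive")
            step_ms = 1000.0 / resample_hz
            n = int(np.floor(times[-1] * resample_hz / 1000.0 + 1e-9)) + 1
            grid = np.arange(n) * step_ms
            positions = np.interp(grid, times, positions)
            times = grid
        path = out_dir / f"{traj.joint.replace('.', '_')}.csv"
        with open(path, "w", newline="\n") as fh:
            fh.write("time_ms,position_rad\n")
            for t, p in zip(times, positions):
                fh.write(f"{t:.4f},{p:.6f}\n")
        paths.append(path)
    return paths
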