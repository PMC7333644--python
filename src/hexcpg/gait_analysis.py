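"""Quantitative gait analysis of spiking CPG output.

Turns spike rasters or rate-coded signals into the quantities the network
design is judged by: burst frequency, pairwise phase relations, tripod
classification, and per-leg stance/swing gait diagrams.  A seeded fixture
generator produces periodic burst trains with known frequency and phase so
every analysis routine can be tested in closed loop without the simulator.

Conventions: phases are degrees in [0, 360); ``estimate_phase(a, b)``
measures how far ``b`` lags ``a`` around the cycle, so it is antisymmetric
(``phase(a,b) + phase(b,a) = 0 mod 360``).  :func:`phase_separation` folds a
phase onto [0, 180] for statements like "the joints are 90 degrees apart".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cpg_network import SpikeRaster
from .readout import RateSignal

__all__ = [
    "BurstSequence",
    "PhaseEstimate",
    "GaitDiagram",
    "detect_bursts",
    "estimate_frequency",
    "estimate_phase",
    "phase_separation",
    "classify_gait",
    "gait_diagram",
    "make_fixture",
    "DEFAULT_ISI_THRESHOLD",
    "DEFAULT_TRANSIENT_MS",
    "GAIT_TOLERANCE_DEG",
]

#: Inter-spike-interval threshold (ms) separating bursts: intra-burst ISIs
#: are a few ms, inter-burst intervals at least 125 ms even at 8 Hz.
DEFAULT_ISI_THRESHOLD = 50.0

#: Initial transient (ms) excluded before phase or gait statistics.
DEFAULT_TRANSIENT_MS = 2000.0

#: Half-width (degrees) of the in-phase / anti-phase acceptance bands used by
#: gait classification; the midpoint between 0 and 180.
GAIT_TOLERANCE_DEG = 45.0


@dataclass
class BurstSequence:
    """Detected bursts: onset/offset times (ms) and events per burst."""

    onsets: np.ndarray
    offsets: np.ndarray
    spikes_per_burst: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.spikes_per_burst = np.asarray(self.spikes_per_burst, dtype=int)

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class PhaseEstimate:
    """Phase of one signal relative to another.

    ``phase`` in degrees [0, 360), the ``period`` (ms) it was measured
    against, and a [0, 1] ``confidence`` (normalised correlation at the best
    lag — low for aperiodic or poorly locked signals).
    """

    phase: float
    period: float
    confidence: float


@dataclass
class GaitDiagram:
    """Per-leg stance intervals (ms) over a record of given duration."""

    stance: dict[str, list[tuple[float, float]]]
    duration: float

    @property
    def legs(self) -> list[str]:
        return list(self.stance)


def _event_times(source, isi_threshold: float) -> np.ndarray:
    if isinstance(source, RateSignal):
        return source.times[source.counts > 0]
    return np.sort(np.asarray(source, dtype=float))


def detect_bursts(source, isi_threshold: float = DEFAULT_ISI_THRESHOLD) -> BurstSequence:
    """Group spikes into bursts by inter-spike interval.

    ``source`` is either an array of spike times (ms) or a
    :class:`~hexcpg.readout.RateSignal` (whose active — nonzero-count — grid
    times serve as events; onsets are then biased early by half a window).
    Events closer than ``isi_threshold`` belong to one burst.  An empty
    record yields an empty sequence.
    """
    if isi_threshold <= 0:
        raise ValueError("isi_threshold must be positive")
    t = _event_times(source, isi_threshold)
    if t.size == 0:
        return BurstSequence(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    breaks = np.nonzero(np.diff(t) >= isi_threshold)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))
    return BurstSequence(t[starts], t[ends], ends - starts + 1)


def estimate_frequency(bursts: BurstSequence) -> float:
    """Burst (inter-burst-interval) frequency in Hz: the reciprocal of the
    median inter-onset interval.  Requires at least three bursts."""
    if len(bursts) < 3:
        raise ValueError("need at least 3 bursts to estimate a frequency")
    return 1000.0 / float(np.median(np.diff(bursts.onsets)))


def estimate_phase(
    sig_a: RateSignal,
    sig_b: RateSignal,
    period: float | None = None,
) -> PhaseEstimate:
    """Phase lag of ``sig_b`` behind ``sig_a`` by circular cross-correlation.

    The circular cross-correlation of the mean-subtracted signals is
    maximised over lags within one period (taken from the burst frequency of
    ``sig_a`` unless given) and the best lag converted to degrees.
    Restricting the search to one period keeps the estimate locked to the
    *relative* lag even when the common phase of two coupled oscillators
    drifts over the record.  Signals must share the same time grid; callers
    should drop the initial transient first.
    """
    if sig_a.times.size != sig_b.times.size or sig_a.times.size < 2:
        raise ValueError("signals must share one time grid with >= 2 samples")
    dt = sig_a.dt
    if period is None:
        period = 1000.0 / estimate_frequency(detect_bursts(sig_a))
    x = sig_a.counts - sig_a.counts.mean()
    y = sig_b.counts - sig_b.counts.mean()
    L = x.size
    corr = np.fft.irfft(np.conj(np.fft.rfft(x)) * np.fft.rfft(y), n=L)
    p = int(round(period / dt))
    if p < 2 or p > L:
        raise ValueError("period must resolve to at least 2 samples within the record")
    lag = int(np.argmax(corr[:p]))
    phase = (360.0 * lag * dt / period) % 360.0
    denom = np.std(x) * np.std(y)
    conf = 0.0
    if denom > 0:
        r = float(np.dot(x, np.roll(y, -lag)) / (L * denom))
        conf = float(np.clip(r, 0.0, 1.0))
    return PhaseEstimate(phase=phase, period=float(period), confidence=conf)


def phase_separation(phase_deg: float) -> float:
    """Fold a phase onto [0, 180]: the unsigned angular separation."""
    p = phase_deg % 360.0
    return min(p, 360.0 - p)


def _circular_distance(a: float, b: float) -> float:
    return phase_separation(a - b)


def classify_gait(
    phases: Mapping[str, float],
    tolerance: float = GAIT_TOLERANCE_DEG,
) -> str:
    """Classify six per-leg phases (degrees, relative to any reference) as
    ``"tripod"`` or ``"non_tripod"``.

    Tripod requires the {FL, MR, BL} and {FR, ML, BR} triplets to be mutually
    in phase (pairwise within ``tolerance``) and the two triplets anti-phasic
    (pairwise separation within ``tolerance`` of 180).  The criterion uses
    only pairwise circular distances, so it is invariant to a global phase
    rotation.
    """
    required = ("FL", "ML", "BL", "FR", "MR", "BR")
    missing = [leg for leg in required if leg not in phases]
    if missing:
        raise ValueError(f"missing legs: {missing}")
    group_a = ("FL", "MR", "BL")
    group_b = ("FR", "ML", "BR")
    for group in (group_a, group_b):
        for i, leg_i in enumerate(group):
            for leg_j in group[i + 1:]:
                if _circular_distance(phases[leg_i], phases[leg_j]) > tolerance:
                    return "non_tripod"
    for leg_i in group_a:
        for leg_j in group_b:
            if abs(_circular_distance(phases[leg_i], phases[leg_j]) - 180.0) > tolerance:
                return "non_tripod"
    return "tripod"


def gait_diagram(
    rectified_signals: Mapping[str, RateSignal],
    threshold: float | Mapping[str, float] | None = None,
) -> GaitDiagram:
    """Stance/swing intervals from rectified per-leg activity signals.

    Stance is a maximal run where the signal exceeds the threshold; by
    default each leg uses the median of its own signal (a data-derived
    threshold), mirroring foot-contact detection from rectified force traces.
    """
    stance: dict[str, list[tuple[float, float]]] = {}
    duration = 0.0
    for leg, sig in rectified_signals.items():
        if isinstance(threshold, Mapping):
            thr = threshold[leg]
        elif threshold is None:
            thr = float(np.median(sig.counts))
        else:
            thr = float(threshold)
        if threshold is not None and thr <= 0:
            raise ValueError("stance threshold must be positive")
        above = sig.counts > thr
        edges = np.diff(above.astype(int))
        starts = np.nonzero(edges == 1)[0] + 1
        ends = np.nonzero(edges == -1)[0] + 1
        if above.size and above[0]:
            starts = np.concatenate(([0], starts))
        if above.size and above[-1]:
            ends = np.concatenate((ends, [above.size - 1]))
        stance[leg] = [
            (float(sig.times[s]), float(sig.times[e])) for s, e in zip(starts, ends)
        ]
        if sig.times.size:
            duration = max(duration, float(sig.times[-1]))
    return GaitDiagram(stance=stance, duration=duration)


def make_fixture(
    frequency: float,
    phase_offsets: Mapping[str, float] | Sequence[float],
    spikes_per_burst: int = 5,
    jitter: float = 0.0,
    seed: int | None = None,
    duration: float = 5000.0,
    size: int = 1,
    intra_burst_isi: float = 3.0,
    dt: float = 0.1,
) -> SpikeRaster:
    """Deterministic periodic burst trains with known frequency and phase.

    Each channel fires ``spikes_per_burst`` spikes (``intra_burst_isi`` ms
    apart) per neuron at every cycle of the given ``frequency``, shifted by
    its phase offset (degrees).  ``jitter`` adds seeded Gaussian noise (ms)
    to each neuron's burst onset, leaving intra-burst spacing — and hence the
    refractory invariant — intact.  Used to exercise every analysis routine
    in closed loop.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if isinstance(phase_offsets, Mapping):
        channels = dict(phase_offsets)
    else:
        channels = {f"ch{i}": off for i, off in enumerate(phase_offsets)}
    rng = np.random.default_rng(seed)
    period = 1000.0 / frequency
    times_all, ids_all = [], []
    populations: dict[str, tuple[int, int]] = {}
    next_id = 0
    for label, offset_deg in channels.items():
        populations[label] = (next_id, next_id + size)
        base_onsets = np.arange((offset_deg % 360.0) / 360.0 * period, duration, period)
        for neuron in range(size):
            onsets = base_onsets
            if jitter > 0:
                onsets = onsets + rng.normal(0.0, jitter, size=base_onsets.size)
            for onset in onsets:
                spikes = onset + intra_burst_isi * np.arange(spikes_per_burst)
                spikes = spikes[(spikes >= 0) & (spikes <= duration)]
                times_all.append(spikes)
                ids_all.append(np.full(spikes.size, next_id + neuron))
        next_id += size
    if times_all:
        times = np.concatenate(times_all)
        ids = np.concatenate(ids_all)
        order = np.argsort(times, kind="stable")
        times, ids = times[order], ids[order]
    else:
        times, ids = np.empty(0), np.empty(0, dtype=np.int64)
    return SpikeRaster(times, ids.astype(np.int64), duration, dt, populations)
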