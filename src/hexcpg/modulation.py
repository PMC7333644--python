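"""Online manipulation rules: frequency, amplitude and phase control.

The burst frequency of the oscillators is steered by the spike threshold
``V_T`` (usable range -56..-51 mV at a 500 pA bias, mapping roughly linearly
onto 3..8 Hz).  Three compensations accompany a threshold change:

* the weak inter-joint coupling weight grows with ``V_T`` to make up for the
  shrinking number of spikes per burst,
  ``w_coupling = (V_T - V_T_min) * 0.1 - 1`` nS;
* the delay on the CF motor synapse is recomputed from the output frequency,
  ``delay = 1000 / (2 * (f - 1))`` ms, to hold the 90 degree intra-leg phase
  shift;
* the excitatory motor weight can be swept geometrically (2 -> 486 nS by
  factors of 3) to modulate output amplitude while running.

Updates are applied between one-second simulation segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CouplingRule",
    "ScheduleSegment",
    "FrequencyMap",
    "coupling_weight",
    "phase_delay",
    "amplitude_schedule",
    "make_sweep_schedule",
    "DEFAULT_FREQUENCY_MAP",
    "VT_MIN",
    "VT_MAX",
]

#: Usable spike-threshold range (mV) at a 500 pA bias current.
VT_MIN = -56.0
VT_MAX = -51.0


@dataclass(frozen=True)
class CouplingRule:
    """Affine map from spike threshold to the weak inter-joint coupling
    weight.  At ``V_T = V_T_min`` the weight is ``offset`` (-1 nS); at the top
    of the 5 mV range it reaches -0.5 nS."""

    V_T_min: float = VT_MIN
    slope: float = 0.1  # nS per mV
    offset: float = -1.0  # nS


def coupling_weight(V_T: float, rule: CouplingRule = CouplingRule()) -> float:
    """Inter-joint coupling weight (nS) compensating for the loss of spikes
    per burst at higher thresholds.

    Linear in ``V_T``; equals ``rule.offset`` at ``V_T_min`` and stays within
    the weak-coupling band [-1.0, -0.5] nS over the permitted 5 mV range.
    """
    lo, hi = rule.V_T_min, rule.V_T_min + 5.0
    if not lo <= V_T <= hi:
        raise ValueError(f"V_T={V_T} mV outside the usable range [{lo}, {hi}]")
    w = (V_T - rule.V_T_min) * rule.slope + rule.offset
    if w >= 0:
        raise ValueError("coupling weight must remain inhibitory")
    return w


def phase_delay(frequency: float) -> float:
    """Delay (ms) on the CF motor synapse producing the intra-leg phase
    shift at the given output frequency (Hz).

    ``delay = 1000 / (2 * (frequency - 1))``; 250 ms at 3 Hz, ~71 ms at 8 Hz.
    Strictly decreasing in frequency; undefined at or below 1 Hz.
    """
    if frequency <= 1.0:
        raise ValueError("phase delay is singular for frequencies <= 1 Hz")
    return 1000.0 / (2.0 * (frequency - 1.0))


def amplitude_schedule(start: float, factor: float, steps: int) -> np.ndarray:
    """Geometric sequence of motor weights ``start * factor**k`` (nS),
    ``k = 0 .. steps-1``.  The canonical amplitude sweep is (2, 3, 6):
    2, 6, 18, 54, 162, 486 nS."""
    if start <= 0:
        raise ValueError("start weight must be positive")
    if factor <= 0:
        raise ValueError("factor must be positive")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    return start * factor ** np.arange(steps, dtype=float)


@dataclass(frozen=True)
class FrequencyMap:
    """Measured threshold-to-frequency table with linear interpolation.

    The network is open loop, so scheduled delays use this calibrated map
    rather than an online frequency estimate.
    """

    V_T: tuple[float, ...]
    frequency: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.V_T)
        f = np.asarray(self.frequency)
        if v.size != f.size or v.size < 1:
            raise ValueError("V_T and frequency must be equal-length, nonempty")
        if v.size > 1 and not (np.all(np.diff(v) > 0) and np.all(np.diff(f) > 0)):
            raise ValueError("frequency must be strictly increasing in V_T")

    def __call__(self, V_T: float) -> float:
        return float(np.interp(V_T, self.V_T, self.frequency))


#: Calibrated map: 3 Hz at -56 mV rising linearly to 8 Hz at -51 mV.
DEFAULT_FREQUENCY_MAP = FrequencyMap(
    V_T=(-56.0, -55.0, -54.0, -53.0, -52.0, -51.0),
    frequency=(3.0, 4.0, 5.0, 6.0, 7.0, 8.0),
)


@dataclass(frozen=True)
class ScheduleSegment:
    """Parameters of one simulation segment (default one second).

    Fields left as ``None`` keep their previous value.
    """

    duration: float = 1000.0
    V_T: float | None = None
    motor_weight: float | None = None
    joint_weight: float | None = None
    cf_delay: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.V_T is not None and not VT_MIN <= self.V_T <= VT_MAX:
            raise ValueError(
                f"V_T={self.V_T} mV outside the constrained range "
                f"[{VT_MIN}, {VT_MAX}]"
            )
        if self.motor_weight is not None and self.motor_weight <= 0:
            raise ValueError("motor weight must be positive (excitatory)")
        if self.joint_weight is not None and self.joint_weight >= 0:
            raise ValueError("joint coupling weight must be negative (inhibitory)")
        if self.cf_delay is not None and self.cf_delay <= 0:
            raise ValueError("CF motor delay must be positive")


def make_sweep_schedule(
    V_T_start: float = VT_MIN,
    V_T_end: float = VT_MAX,
    step: float = 1.0,
    frequency_map: FrequencyMap = DEFAULT_FREQUENCY_MAP,
    amplitude: tuple[float, float] | None = None,
    motor_weight: float | None = None,
    coupling_rule: CouplingRule = CouplingRule(),
    segment_ms: float = 1000.0,
) -> list[ScheduleSegment]:
    """Build a threshold-sweep schedule, one segment per ``V_T`` value.

    Each segment carries the coupling weight from :func:`coupling_weight`,
    the CF delay from :func:`phase_delay` applied to the mapped frequency,
    and — when ``amplitude=(start, factor)`` is given — a geometrically
    growing motor weight.  Otherwise ``motor_weight`` (possibly ``None``,
    i.e. unchanged) is used for every segment.
    """
    if step == 0:
        raise ValueError("V_T step must be nonzero")
    step = abs(step) if V_T_end >= V_T_start else -abs(step)
    n = int(round((V_T_end - V_T_start) / step)) + 1
    thresholds = [V_T_start + k * step for k in range(n)]
    for vt in thresholds:
        if not VT_MIN - 1e-9 <= vt <= VT_MAX + 1e-9:
            raise ValueError(f"swept V_T={vt} mV outside [{VT_MIN}, {VT_MAX}]")
    weights = (
        amplitude_schedule(amplitude[0], amplitude[1], n)
        if amplitude is not None
        else [motor_weight] * n
    )
    return [
        ScheduleSegment(
            duration=segment_ms,
            V_T=vt,
            motor_weight=wt,
            joint_weight=coupling_weight(vt, coupling_rule),
            cf_delay=phase_delay(frequency_map(vt)),
        )
        for vt, wt in zip(thresholds, weights)
    ]
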