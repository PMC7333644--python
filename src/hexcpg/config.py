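"""Structured YAML configuration for simulations.

A config file has up to four blocks::

    neuron:              # AdEx parameters, flat key: value (units as in docs)
      I_e: 500.0
      V_T: -56.0
      noise_std: 800.0   # Gaussian current noise (pA)
      noise_mean: 0.0
    topology:
      kind: hexapod      # scpg | leg | hexapod
      coupling_mode: full
      size: 5
      strong_weight: -10.0
      joint_weight: -1.0
      motor_weight: 54.0
      cf_delay: 250.0
    schedule:            # optional: list of segments (overrides run.duration)
      - {duration: 1000, V_T: -56.0, motor_weight: 2.0}
      - {duration: 1000, V_T: -55.0, motor_weight: 6.0}
    run:
      duration: 10000.0  # ms, used when no schedule is given
      dt: 0.1
      seed: 1

Unknown keys raise immediately so typos do not silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .adex_core import AdExParameters, NoiseSpec, cpg_parameters
from .cpg_network import (
    DEFAULT_DT,
    DEFAULT_MOTOR_WEIGHT,
    DEFAULT_NOISE_STD,
    STRONG_WEIGHT,
    HexapodSpec,
    Network,
    build_hexapod,
    build_leg,
    build_scpg,
)
from .modulation import ScheduleSegment

__all__ = ["SimulationConfig", "load_config"]

_ADEX_FIELDS = {f.name for f in dataclasses.fields(AdExParameters)}


@dataclasses.dataclass
class SimulationConfig:
    """Parsed configuration: a network, an optional schedule, and run options."""

    network: Network
    schedule: list[ScheduleSegment] | None
    duration: float
    dt: float
    seed: int | None


def _parse_neuron(block: dict) -> tuple[AdExParameters, NoiseSpec]:
    block = dict(block or {})
    noise = NoiseSpec(
        mean=float(block.pop("noise_mean", 0.0)),
        std=float(block.pop("noise_std", DEFAULT_NOISE_STD)),
        seed=block.pop("noise_seed", None),
    )
    unknown = set(block) - _ADEX_FIELDS
    if unknown:
        raise ValueError(f"unknown neuron parameters: {sorted(unknown)}")
    params = cpg_parameters()
    if block:
        params = params.with_(**{k: float(v) for k, v in block.items()})
    return params, noise


def _parse_topology(block: dict, params: AdExParameters, noise: NoiseSpec) -> Network:
    block = dict(block or {})
    kind = block.pop("kind", "hexapod")
    size = int(block.pop("size", 5))
    if kind == "scpg":
        weight = float(block.pop("strong_weight", STRONG_WEIGHT))
        net = build_scpg(params, size, weight, noise=noise)
    elif kind == "leg":
        net = build_leg(
            block.pop("prefix", "FL"),
            params,
            size,
            float(block.pop("joint_weight", -1.0)),
            float(block.pop("motor_weight", DEFAULT_MOTOR_WEIGHT)),
            float(block.pop("cf_delay", 250.0)),
            noise,
        )
    elif kind == "hexapod":
        net = build_hexapod(
            HexapodSpec(
                params=params,
                noise=noise,
                size=size,
                coupling_mode=block.pop("coupling_mode", "full"),
                strong_weight=float(block.pop("strong_weight", STRONG_WEIGHT)),
                joint_weight=float(block.pop("joint_weight", -1.0)),
                motor_weight=float(block.pop("motor_weight", DEFAULT_MOTOR_WEIGHT)),
                cf_motor_delay=float(block.pop("cf_delay", 250.0)),
            )
        )
    else:
        raise ValueError(f"unknown topology kind {kind!r}")
    if block:
        raise ValueError(f"unknown topology options: {sorted(block)}")
    return net


def load_config(path: str | Path) -> SimulationConfig:
    """Parse a YAML config file into a ready-to-run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"neuron", "topology", "schedule", "run"}
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    params, noise = _parse_neuron(raw.get("neuron", {}))
    network = _parse_topology(raw.get("topology", {}), params, noise)
    schedule = None
    if raw.get("schedule"):
        schedule = [ScheduleSegment(**seg) for seg in raw["schedule"]]
    run = dict(raw.get("run", {}))
    cfg = SimulationConfig(
        network=network,
        schedule=schedule,
        duration=float(run.pop("duration", 10000.0)),
        dt=float(run.pop("dt", DEFAULT_DT)),
        seed=run.pop("seed", None),
    )
    if run:
        raise ValueError(f"unknown run options: {sorted(run)}")
    return cfg
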