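"""Adaptive exponential integrate-and-fire (AdEx) neuron dynamics.

The AdEx model is a two-dimensional hybrid system: a membrane voltage ``V``
with exponential spike initiation and an adaptation current ``w`` that
accumulates with every spike.  In the regular-bursting regime used here the
reset voltage ``V_r`` sits *above* the spike threshold ``V_T``, so after each
reset the exponential term immediately drives the neuron toward another spike;
the burst terminates only once ``w`` has grown large enough to pull the
voltage down.  This intrinsic bursting is what makes the neuron a pacemaker
suitable for driving a central pattern generator.

Continuous dynamics between spikes::

    C dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T)
              - g_exc (V - E_ex) - g_inh (V - E_in) - w + I_e + I_noise
    tau_w dw/dt = a (V - E_L) - w

Discrete events: when ``V`` crosses the numerical cutoff ``V_peak`` a spike is
emitted, ``V -> V_r``, ``w -> w + b``, and the neuron is refractory (voltage
clamped at ``V_r``, ``w`` still integrating) for ``t_ref`` milliseconds.

Synapses are conductance based with an alpha-function kernel,
``g(t) = g_peak * alpha**2 * t * exp(-alpha t)`` after each presynaptic spike.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AdExParameters",
    "NoiseSpec",
    "NeuronState",
    "SynapseSpec",
    "alpha_conductance",
    "adex_derivatives",
    "step_neuron",
    "regular_bursting_parameters",
    "cpg_parameters",
    "motor_parameters",
    "EXP_ARG_MAX",
    "E_EX_DEFAULT",
    "E_IN_DEFAULT",
    "ALPHA_EXC_DEFAULT",
    "ALPHA_INH_DEFAULT",
]

#: Clamp on the exponential argument (V - V_T)/Delta_T so the spike-initiation
#: term stays finite for any voltage the Euler step may briefly produce.
EXP_ARG_MAX = 20.0

#: Default synaptic reversal potentials (mV).
E_EX_DEFAULT = 0.0
E_IN_DEFAULT = -85.0

#: Default alpha-kernel rise rates (1/ms): rise time 1/alpha of 0.2 ms for the
#: excitatory channel and 2.0 ms for the inhibitory channel.
ALPHA_EXC_DEFAULT = 5.0
ALPHA_INH_DEFAULT = 0.5


@dataclass(frozen=True)
class AdExParameters:
    """Parameter set of one AdEx neuron.

    Units follow common simulator convention: pF, nS, mV, ms, pA.  With these
    units pA / pF = mV / ms, so the equations integrate consistently in
    milliseconds.

    Attributes
    ----------
    C : membrane capacitance (pF)
    g_L : leak conductance (nS)
    E_L : resting potential (mV)
    V_T : spike threshold of the exponential term (mV)
    Delta_T : slope factor (mV)
    tau_w : adaptation time constant (ms)
    a : subthreshold adaptation conductance (nS)
    b : spike-triggered adaptation increment (pA)
    V_r : reset voltage (mV)
    I_e : constant bias current (pA)
    t_ref : absolute refractory period (ms)
    V_peak : numerical spike-detection cutoff (mV); must exceed ``V_T``
    """

    C: float = 200.0
    g_L: float = 10.0
    E_L: float = -58.0
    V_T: float = -50.0
    Delta_T: float = 2.0
    tau_w: float = 120.0
    a: float = 2.0
    b: float = 100.0
    V_r: float = -46.0
    I_e: float = 210.0
    t_ref: float = 0.0
    V_peak: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance C must be positive")
        if self.g_L <= 0:
            raise ValueError("leak conductance g_L must be positive")
        if self.Delta_T <= 0:
            raise ValueError("slope factor Delta_T must be positive")
        if self.tau_w <= 0:
            raise ValueError("adaptation time constant tau_w must be positive")
        if self.t_ref < 0:
            raise ValueError("refractory period t_ref must be non-negative")
        if self.V_peak <= self.V_T:
            raise ValueError("spike cutoff V_peak must exceed threshold V_T")
        for name in ("V_r", "V_T"):
            v = getattr(self, name)
            if not -100.0 <= v <= 50.0:
                raise ValueError(f"{name}={v} mV outside sanity bound [-100, 50]")

    def with_(self, **kwargs) -> "AdExParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def regular_bursting_parameters() -> AdExParameters:
    """Regular-bursting AdEx parameter set (Naud-style regime).

    Bias current 210 pA and no refractory period; the threshold sits at the
    canonical -50 mV.
    """
    return AdExParameters()


def cpg_parameters(V_T: float = -56.0) -> AdExParameters:
    """Parameter set used for the pattern-generating populations.

    Same regular-bursting regime but with the bias current raised to 500 pA to
    promote repetitive bursting, a 2 ms refractory period, and an adjustable
    threshold (the frequency control knob, usable between -56 and -51 mV).
    """
    return AdExParameters(I_e=500.0, t_ref=2.0, V_T=V_T)


def motor_parameters(V_T: float = -56.0) -> AdExParameters:
    """Motor-neuron parameter set: no intrinsic drive (``I_e = 0``).

    Motor populations must fire only when excited by their pattern generator;
    an intrinsically bursting motor neuron would decouple the output from the
    drive.
    """
    return cpg_parameters(V_T).with_(I_e=0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian current noise injected independently into each neuron at
    every time step, mimicking noise in the nervous system.

    ``seed`` is optional extra entropy folded into the run seed so distinct
    populations can decorrelate their noise streams explicitly.
    """

    mean: float = 0.0
    std: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("noise std must be non-negative")


@dataclass
class NeuronState:
    """Dynamic state of one neuron: voltage (mV), adaptation current (pA)
    and remaining refractory time (ms)."""

    V: float
    w: float = 0.0
    refractory_remaining: float = 0.0

    @classmethod
    def at_rest(cls, params: AdExParameters) -> "NeuronState":
        return cls(V=params.E_L, w=0.0, refractory_remaining=0.0)


@dataclass(frozen=True)
class SynapseSpec:
    """Conductance-based alpha synapse.

    The sign of ``weight`` selects the channel: positive weights act through
    the excitatory reversal ``E_ex``, negative weights through the inhibitory
    reversal ``E_in``.  ``alpha`` is the kernel rise rate in 1/ms (peak
    conductance is reached at t = 1/alpha after spike delivery), ``delay`` the
    spike-delivery latency in ms.
    """

    weight: float
    alpha: float | None = None
    delay: float = 0.1
    E_ex: float = E_EX_DEFAULT
    E_in: float = E_IN_DEFAULT

    def __post_init__(self) -> None:
        if self.alpha is None:
            # channel-appropriate default rise rate
            object.__setattr__(
                self,
                "alpha",
                ALPHA_EXC_DEFAULT if self.weight >= 0 else ALPHA_INH_DEFAULT,
            )
        if self.alpha <= 0:
            raise ValueError("alpha rise rate must be positive")
        if self.delay <= 0:
            raise ValueError("synaptic delay must be positive")

    @property
    def is_excitatory(self) -> bool:
        return self.weight >= 0

    @property
    def reversal(self) -> float:
        return self.E_ex if self.is_excitatory else self.E_in


def alpha_conductance(t_since_spike, weight: float, alpha: float):
    """Alpha-kernel conductance ``|weight| * alpha**2 * t * exp(-alpha t)``.

    Parameters
    ----------
    t_since_spike : float or array
        Time since the delivered spike, ms.  Must be non-negative.
    weight : float
        Peak-conductance scale in nS; only its magnitude enters (channel
        selection is the caller's job).
    alpha : float
        Rise rate in 1/ms.

    Returns
    -------
    Conductance in nS, same shape as ``t_since_spike``.  Zero at t = 0,
    maximal (``|weight| * alpha / e``) at t = 1/alpha, decaying to zero.
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be non-negative")
    out = abs(weight) * alpha**2 * t * np.exp(-alpha * t)
    return out if out.ndim else float(out)


def adex_derivatives(
    state: NeuronState,
    params: AdExParameters,
    g_exc: float = 0.0,
    g_inh: float = 0.0,
    I_noise: float = 0.0,
    E_ex: float = E_EX_DEFAULT,
    E_in: float = E_IN_DEFAULT,
) -> tuple[float, float]:
    """Right-hand side of the AdEx continuous dynamics.

    Returns ``(dV/dt, dw/dt)`` in (mV/ms, pA/ms).  The exponential argument is
    clamped at :data:`EXP_ARG_MAX` so the result is finite for any voltage.
    """
    V, w = state.V, state.w
    exp_arg = min((V - params.V_T) / params.Delta_T, EXP_ARG_MAX)
    I_ion = (
        -params.g_L * (V - params.E_L)
        + params.g_L * params.Delta_T * np.exp(exp_arg)
        - g_exc * (V - E_ex)
        - g_inh * (V - E_in)
        - w
        + params.I_e
        + I_noise
    )
    dV = I_ion / params.C
    dw = (params.a * (V - params.E_L) - w) / params.tau_w
    return float(dV), float(dw)


def step_neuron(
    state: NeuronState,
    params: AdExParameters,
    g_exc: float = 0.0,
    g_inh: float = 0.0,
    I_noise: float = 0.0,
    dt: float = 0.1,
    E_ex: float = E_EX_DEFAULT,
    E_in: float = E_IN_DEFAULT,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one forward-Euler step of length ``dt`` (ms).

    During the refractory period the voltage is clamped at ``V_r`` while the
    adaptation current keeps integrating.  A spike is reported when the
    updated voltage crosses ``V_peak``; the neuron is then reset
    (``V -> V_r``, ``w -> w + b``) and becomes refractory for ``t_ref``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    if state.refractory_remaining > 0:
        clamped = NeuronState(params.V_r, state.w, state.refractory_remaining)
        _, dw = adex_derivatives(clamped, params, g_exc, g_inh, I_noise, E_ex, E_in)
        return (
            NeuronState(
                V=params.V_r,
                w=state.w + dt * dw,
                refractory_remaining=max(0.0, state.refractory_remaining - dt),
            ),
            False,
        )

    dV, dw = adex_derivatives(state, params, g_exc, g_inh, I_noise, E_ex, E_in)
    V_new = state.V + dt * dV
    w_new = state.w + dt * dw
    if V_new >= params.V_peak:
        return NeuronState(params.V_r, w_new + params.b, params.t_ref), True
    return NeuronState(V_new, w_new, 0.0), False
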