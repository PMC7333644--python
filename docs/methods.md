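# Methods

## The model

`hexcpg` simulates decentralised spiking central pattern generators (CPGs)
for six-legged locomotion. Each controlled joint is driven by a half-center
oscillator: two populations of adaptive exponential integrate-and-fire
(AdEx) neurons coupled by strong all-to-all mutual inhibition. The neurons
are intrinsically bursting ("pacemaker" CPGs), so the rhythm originates in
the cells and the inhibition organises it into anti-phase.

The AdEx membrane equations are

    C dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_T)/Δ_T)
              - Σ_r g_r(t) (V - E_r) - w + I_e + ξ(t)
    τ_w dw/dt = a (V - E_L) - w

with a reset V → V_r, w → w + b and a t_ref = 2 ms refractory clamp when V
crosses the numerical cutoff V_peak. Synapses are conductance based with an
alpha kernel g(t) = ḡ α² t e^(-αt) per delivered spike. ξ(t) is independent
per-neuron Gaussian current noise drawn each time step.

Default neuron parameters are the regular-bursting set (C = 200 pF,
g_L = 10 nS, E_L = -58 mV, Δ_T = 2 mV, τ_w = 120 ms, a = 2 nS, b = 100 pA,
V_r = -46 mV) with the bias current raised to I_e = 500 pA. Because
V_r > V_T, every reset relaunches the spike upstroke and bursts terminate
only once the adaptation current w has accumulated; this is the regime the
whole design rests on. Motor populations use the same parameters with
I_e = 0 so they fire (almost) only when driven by their half-center.

## Topology

A leg couples its thorax-coxa (TC) and coxa-femur (CF) half-centers with
weak mutual inhibition (the femur-tibia joint is held fixed: incorporating
it properly requires load feedback, which is out of scope). Population "1"
of each half-center excites a five-neuron motor population; the CF motor
synapse carries an adjustable delay. The hexapod couples contralateral
same-segment legs and ipsilateral neighbouring segments (front↔middle,
middle↔back) with strong (-10 nS) mutual inhibition, per joint, either
between the "1" populations only (`first_only`) or between both populations
(`full`). All projections between populations are all-to-all; populations
have five neurons by default.

## Online modulation

Long runs are split into one-second segments; between segments the
following may be replaced (all neuron and synapse state, including
in-flight spikes, carries over):

* **Frequency** — the spike threshold V_T, usable over -56..-51 mV at the
  500 pA bias. Raising V_T shortens bursts (fewer spikes before w
  terminates them) and raises the burst rate roughly linearly from ~3 to
  ~8 Hz.
* **Joint coupling** — w_coupling = (V_T - V_T_min)·0.1 - 1 nS, spanning
  the weak band -1.0..-0.5 nS; it compensates the loss of spikes per burst
  at higher frequencies. Note the sign of the linear term: the rule must
  produce -1.0 nS at V_T = -56 and -0.5 nS at -51.
* **Intra-leg phase** — the CF motor delay, delay = 1000/(2(f-1)) ms,
  evaluated on a configured threshold→frequency table (the network is open
  loop; nothing estimates f online). 250 ms at 3 Hz down to ~71 ms at 8 Hz.
* **Amplitude** — the excitatory motor weight, optionally swept
  geometrically (canonically 2→486 nS by factors of 3 over six segments).

## Numerics

The simulator integrates all neurons synchronously at dt = 0.1 ms (10,000
steps per simulated second). Plain forward Euler is *not* accurate enough
here: the exponential upstroke makes single-neuron spike counts converge
only as ~O(dt) (191 spikes/s at dt = 0.1 versus 157 converged). Each step
therefore uses an exponential integrator: freezing the slow currents (leak,
synaptic, adaptation, bias, noise) over the step, the substitution
y = exp(-(V - V_T)/Δ_T) turns the voltage equation into a linear ODE in y
that is advanced exactly; threshold crossings are located by interpolation
in y (y is nearly linear in time during the upstroke) so the refractory
clock starts at the crossing rather than at the step boundary, and partial
refractory steps integrate the exact remaining fraction. With this scheme
the single-neuron spike count at dt = 0.1 ms is within one spike per second
of a 100× finer reference, which the test suite checks against an
independently written fine-step integrator. The adaptation current relaxes
exponentially with the voltage frozen; synaptic conductances use the exact
two-state propagator of the alpha kernel, so recorded conductances equal
the analytic sum of per-spike kernels to rounding error. Spike delivery
uses a ring buffer; delays are quantised to whole steps (minimum one step).
Spike times are reported on the step grid. The exponential argument is
clamped at 20 before V_peak detection to avoid overflow.

V_peak defaults to 0 mV. The printed reset condition "when V > V_T" cannot
be meant literally in this regime (V_r = -46 mV lies *above* the -56..-51
mV thresholds, so a literal reading retriggers instantly); the exponential
term carries the voltage to the cutoff within a fraction of a millisecond,
so any cutoff well above V_r yields the same bursts.

## Noise calibration

The noise amplitude is the one deliberately calibrated constant. It was
chosen by scanning the std of the per-step Gaussian current and measuring
the rate-coded burst frequency of a 5+5 half-center at the two ends of the
threshold range, keeping the value whose map best matches 3 Hz at -56 mV
and 8 Hz at -51 mV; the calibrated default is mean 0, std 800 pA. Without
noise the map is too steep (≈2.7 Hz at -56 mV rising past 10 Hz before
-51 mV, with oscillation collapse at the top); the noise both desynchronises
neurons within a population and linearises the map. The std is large enough
that motor neurons — whose rheobase at V_T = -56 mV is almost exactly zero
— also fire spontaneously at a few tens of hertz; consequences are noted
under Limitations.

## Measurement conventions

* **Rate coding** — spikes per population counted in a sliding 5 ms window
  on the simulation grid, centred by default (recorded data may look
  ahead); a causal mode exists for live-like use.
* **Bursts** — maximal groups of events with inter-spike intervals below
  50 ms, a threshold sitting well between intra-burst intervals (a few ms)
  and inter-burst intervals (≥125 ms at 8 Hz). Burst frequency is the
  reciprocal median inter-onset interval.
* **Phase** — circular cross-correlation of two mean-subtracted rate
  signals, maximised over lags within one period; the best lag maps to
  degrees in [0, 360). Restricting the search to one period keeps the
  estimate locked to the relative lag of two coupled oscillators even when
  their common phase drifts over tens of seconds (folding the correlation
  across periods, the obvious alternative, smears the peak under drift).
  `phase_separation` folds to [0, 180°] for "how far apart" statements.
  The first two seconds of every simulated record are discarded before
  phase or gait statistics; the full hexapod occasionally needs longer, so
  the behavioural tests analyse late windows of 12-20 s runs.
* **Gait** — tripod iff {FL, MR, BL} and {FR, ML, BR} are each mutually
  within ±45° and the two triplets are 180° ± 45° apart; ±45° is the
  midpoint between in-phase and anti-phase. The criterion is pairwise, so
  it is invariant to global rotation. Stance intervals threshold each
  leg's rectified summed motor rate at its own median (a data-derived
  threshold), mirroring foot-contact detection from rectified force traces.

## Synthetic fixtures

`make_fixture` generates seeded periodic burst trains with specified
frequency, per-channel phase offsets, spikes per burst and Gaussian onset
jitter (applied per neuron per burst, preserving intra-burst spacing and
hence the refractory invariant). It emulates the *timing* structure of CPG
output — periodicity, phase relations, burst grouping — but none of the
dynamics: no amplitude variation, duty-cycle asymmetry, phase drift or
frequency wander. Fixture-based tests therefore validate the estimators'
correctness, not their robustness to real network output; the latter is
exercised by the simulation-backed behavioural tests.

## Problem sizes

Behavioural statistics use 12-30 s simulations: 12 s per threshold for the
frequency map, 12-20 s for tripod classification, and four 30 s single-leg
runs averaged for the intra-leg phase (the TC-CF lock wanders slowly, so
single short runs scatter by ±25°). These lengths give seed-robust
estimates while keeping a full verification run to a few minutes.

## Known limitations

* The threshold→frequency map runs slightly above nominal at the bottom of
  the range (≈3.1 Hz at -56 mV). The fixed 250 ms CF delay then produces an
  intra-leg separation of ≈95-105° rather than exactly 90°: the delay rule
  assumes 3.00 Hz, and each 0.1 Hz of mismatch shifts the phase by ~8°.
* Because motor neurons sit at rheobase at low thresholds, the calibrated
  noise makes them fire spontaneously; motor output is drive-dominated, but
  "motor population emits a spike" is not evidence of transmission from the
  CPG. A minimum-population-size study based on motor silence (the original
  motivation for five neurons per population) therefore does not
  discriminate sizes under this calibration — every size 1..6 keeps all
  motor populations active, and the corresponding acceptance test records
  this as a failed expectation rather than hiding it.
* The first_only/full coupling comparison shows only a weak stability
  difference here: both modes hold front-back in-phase at fixed thresholds,
  and intermittent violations appear mainly during threshold sweeps.
* Re-settling after a mid-run threshold step usually restores the tripod,
  but occasionally the pattern shears so that one leg pair sits a few
  degrees outside the ±45° classification band; the behavioural test
  therefore asserts tripod persistence as a majority over independent runs.
* No sensory feedback, no femur-tibia joint, no learning, and no robot or
  physics-simulator I/O: the package characterises the open-loop network.
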