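# Methods

## Models

### Single-compartment soma

The soma of a layer-2/3 pyramidal neuron is modeled as an equipotential
sphere carrying Hodgkin–Huxley Na⁺ and K⁺ channels plus a leak:

    C_m dV/dt = −[g_L(V−E_L) + g_K n⁴(V−E_K) + g_Na m³h(V−E_Na) + Σ I_syn] + I_e/A

with g_Na = 120, g_K = 36, g_L = 0.3 mS/cm², E_Na = +50, E_K = −77,
E_L = −54.3 mV, C_m = 1 µF/cm².  Gates obey first-order kinetics
τ_x(V) dx/dt = x_∞(V) − x with the classical rate functions (rest shifted
to −65 mV); the two removable singularities (α_n at −55 mV, α_m at −40 mV)
are evaluated by their analytic limits whenever the denominator argument is
below 1e−7.

Units are mV, ms, mS/cm², µA/cm², µF/cm².  Injected currents are specified
in nA and divided by the compartment area; with areas in mm² the conversion
is `density = 0.1 · I[nA] / A[mm²]` µA/cm².

### Two-compartment model

A dendritic compartment (apical dendrite) couples resistively to the soma:

    C_m dV_s/dt = −I_m,s + I_e,s/A_s + g_ds (V_d − V_s)
    C_m dV_d/dt = −I_m,d + I_e,d/A_d + g_sd (V_s − V_d)

The coupling terms use the physical diffusive sign (current flows from the
more depolarized compartment into the other).  The dendrite carries the
same leak as the soma plus the dendritic calcium action potential (dCaAP)
current

    I_dCaAP = −ω · K(v) · (A − B),
    K(v)   = exp(−F (v − V_thresh)/τ_K),  F = 1/(V_thresh − V_rest),
    A      = 1/(1 + exp(−(t−t′)/τ_A)),
    B      = 1/(1 + exp(−(t − (t′+Δt′))/τ_A)),

with V_thresh = −36 mV, ω = 3 (dimensionless), τ_K = 0.3, τ_A = 3 ms,
Δt′ = 21 ms and a 200 ms refractory period.  A dCaAP initiates at the first
time step where the dendritic voltage is at or above threshold and the
mechanism is eligible; K is evaluated with that step's voltage and frozen
for the waveform.  Because the voltage at initiation grows with the
sustained input level (under constant drive re-initiations occur at the
steady-state voltage), the event amplitude *decreases* with input strength
— the non-monotonic transfer that underlies the XOR capability.  The decay
sigmoid B uses τ_A, the printed form of the model; a sharp-decay variant
using the separately quoted τ_B = 0.4 ms is selectable
(`DCaAPParameters(decay_tau="B")`).  V_rest in F is the dendrite's passive
resting potential, which equals E_L = −54.3 mV since the dendrite at rest
carries only leak, giving F = 1/18.3 per mV.

Synapses are excitatory (E_syn = 0 mV) with conductance
g_syn = g_max · P_s, P_s = P_max e^(−t/τ_s), τ_s = 10 ms, P_max = 1, reset
to 1 at each presynaptic event.  g_max = 0.05 is read directly in mS/cm²
per synapse on the target compartment (reading it through the S/cm²
convention used for channel densities would give 50 mS/cm² per synapse,
which clamps the dendrite to E_syn and admits no working synapse count).

### Geometry and drive calibration

The published model constants above leave four quantities open: the compartment
areas, the two coupling conductances, and the normalization that turns the
dimensionless dCaAP waveform into a current density.  They ship as a single
documented calibration, chosen once against the qualitative behavior
battery and then frozen:

| parameter    | value | role |
|--------------|-------|------|
| `a_soma`     | 0.01 mm² | maps 0.3 nA → ≈3 µA/cm² (one spike) and 3 nA → ≈30 µA/cm² (repetitive firing) |
| `a_dend`     | 0.02 mm² | puts the dCaAP threshold current at ≈1.7 nA, below the 3 nA reference drive |
| `g_sd`       | 0.15 mS/cm² | dendrite-side coupling; small enough that somatic spikes (+40 mV, ~1 ms) never lift the dendrite to −36 mV |
| `g_ds`       | 0.04 mS/cm² | soma-side coupling; dCaAP events (not the passive dendritic baseline) decide somatic firing |
| `dcaap_gain` | 37 µA/cm² per unit | scales −ω·K·(A−B) into the dendritic membrane equation |

The couplings are deliberately asymmetric, the standard reduction for
compartments of unequal area (cf. Pinsky–Rinzel); a single shared scalar
cannot simultaneously let dCaAPs drive the soma and keep somatic action
potentials from triggering the dendrite.

## Numerics

Backward Euler at dt = 0.1 ms.  Gates are advanced first, from the pre-step
voltage, with the exponential update x′ = x_∞ + (x − x_∞)e^(−dt/τ) (exact
for frozen voltage); the membrane equation is then linear in V and the
implicit step is solved in closed form — a scalar division for one
compartment, Gaussian elimination of the 2×2 system for the coupled pair
(with both couplings zero the elimination reduces bitwise to two
independent solves, which is tested).  The scheme is unconditionally
stable; at dt = 1 ms and 0–10 nA the voltage stays within [−120, +80] mV.
Being first order, it carries an O(dt) period bias: halving dt shifts the
3 nA spike train by ≈0.15 ms per spike, so spike times are
grid-converged only up to a linearly growing phase (tested on the first
spikes).  The dCaAP trigger is evaluated on the pre-step dendritic voltage;
threshold semantics are at-or-above.  Somatic spikes are upward crossings
of −20 mV with re-arming below threshold.  Initialization: both
compartments at −65 mV, gates at equilibrium, dCaAP eligible; stimulus
protocols begin with 100 ms of rest.

### Lookup tables

The gating path can replace all runtime exponentials/divisions by tables
holding x_∞ and exp(−dt/τ_x) at 1 mV nodes on [−100, +100] mV (201 nodes),
queried with linear interpolation and clamped outside; the decay factor is
stored with the stable negative exponent.  The A−B waveform is tabulated at
the simulation resolution, truncated below 1e−6 (625 nodes at 0.1 ms;
2.5 kB at 4 bytes/entry) and queried by flooring — the offset t−t′ is
always an exact grid multiple.

Linear interpolation of curved functions carries an O(h²) bias, which
accumulates as a phase drift of the free-running spike train: double+LUT
differs from double+direct by up to ~2.5 ms over a 2 s run.  Accuracy
comparisons between arithmetic modes therefore run both modes with the same
tables, which cancels the shared interpolation bias and isolates the
arithmetic representation; the direct double path remains the reference for
the resolution study, where the table bias is the quantity of interest.

### Fixed-point emulation

The fixed arithmetic mode quantizes every intermediate of the state update
to the 32-bit formats of FPU-less neuromorphic cores: s16.15 (signed
"accum"; voltages, currents, conductances) and u0.32 ("unsigned long
fract"; gates, release probabilities, waveform values, decay factors, K),
with round-to-nearest (ties away from zero) and saturation.  `FixedValue`
implements the exact-wide-intermediate-then-round contract with integer
payloads; the solver uses float-domain quantizers proven bit-identical on
representable values (power-of-two scaling of a double is exact).
Exponentials and divisions use a double-precision core followed by
quantization rather than bit-faithful software routines — consequently the
no-LUT fixed path is *more* accurate here (0.78 mV max error on the 3 nA
run) than the table paths (65.6 / 89.0 mV for 1 / 2 mV tables, whose maxima
are dominated by single-step spike-edge misalignment), whereas on hardware
with ~100-cycle software exp/div the no-LUT path is the least accurate.
The resolution ordering that matters — finer tables strictly more accurate
— holds in both regimes.

The gate update is evaluated as x′ = x_∞(1 − e) + x·e (algebraically the
published form): every operand lies in [0,1), so the whole update stays in
u0.32 with 2⁻³² resolution.  Holding the signed intermediate (x − x_∞) in
s16.15 instead truncates gates to 15 fractional bits and the accumulated
phase error reaches ~2 ms over a 2 s spike train; in the fract-only form
every matched spike over the 0–10 nA sweep lands within one timestep
(0.1 ms) of the double-precision run.  Saturation events are counted and
equal zero in all shipped protocols.

## Behavior battery

Ten firing features run with the single default parameter set; predicates
are machine-checkable, stimuli calibrated once (scan scripts under
scratch/, not shipped):

1. tonic spiking — 1.0 nA somatic: ≥5 spikes, ISI CV < 0.1;
2. phasic spiking — 0.3 nA somatic: exactly one spike;
3. subthreshold oscillations — ≥2 local maxima below −40 mV (prominence
   ≥ 1e−3 mV) after the phasic spike;
4. accommodation — 1 s ramp to 0.35 nA: no spike; step to 0.35 nA: spike;
5. Class II excitability — onset frequency of the 0.4–1.2 nA scan
   (0.05 nA steps, rate over the last 1.5 s) exceeds 40 Hz;
6. rebound spike — −0.5 nA for 300 ms: no spike during, ≥1 within 100 ms
   of release;
7. integrator — paired 0.4 nA × 2 ms pulses: spike at 1 ms gap, none at
   40 ms;
8. variable threshold — the same subthreshold probe spikes only when
   preceded by a −0.3 nA × 20 ms pre-pulse (ending 3 ms before it);
9. adaptation — 2.3 nA constant dendritic drive: ≥3 successive strictly
   increasing somatic ISIs (measured 16.6 → 186.5 → 200.0 ms: a
   two-spike burst under the first, full-amplitude dCaAP, then
   refractory-paced single spikes);
10. XOR — below.

The dCaAP amplitude scan reports, per dendritic current, the steady-state
event amplitude ω·K·max(A−B) (window from 350 ms, i.e. after the first
event, whose amplitude does not yet reflect the sustained drive level) and
the somatic spike count in the same window: amplitude is maximal at the
smallest suprathreshold current, non-increasing beyond, and the soma falls
silent at strong drive while the dendrite keeps firing every 200 ms.

### XOR

Each logical input is one group of 24 identical dendritic synapses firing
synchronously at 20 Hz for 1 s.  One active group depolarizes the dendrite
to just above −36 mV, so dCaAPs initiate with K ≈ 0.9 and their waveform
(≈ +90 mV dendritic events) drives a somatic spike per event.  With both
groups active the dendrite overshoots ~10 mV past threshold at
re-initiation, K collapses (≈ 0.1–0.3), and the doubled synaptic
conductance additionally shunts the waveform; the soma stays ≈ 40 mV below
spike threshold.  Output = "any somatic spike in the window", the window
starting 250 ms into the stimulus: the first dCaAP of a run always
initiates during the initial voltage rise at near-threshold (K ≈ 1 in every
combination) and is therefore uninformative about the input level.  The
truth table is reproduced exactly in both arithmetic modes.

## What the protocols do and do not show

All inputs are synthetic stimulus protocols (constant/ramped/pulsed
currents, periodic synapse trains); there is no noise, no channel
stochasticity, no temperature dependence, and the synaptic trains are
perfectly regular.  Passing the battery shows that the deterministic
dynamics express the ten qualitative regimes under the shipped calibration;
it does not show robustness to input jitter, to biological parameter
spread, or that the calibrated constants are unique.  The fixed-point
fidelity results quantify arithmetic error against the double path of this
same code base, not against an external simulator; absolute error
magnitudes reported for particular hardware/reference pairings are
implementation-specific and are not reproduced here, only their orderings.

## Problem sizes

Validation sweeps run 21 currents × 2 s at dt = 0.1 ms per mode
(≈ 420 k steps per mode pair plus the fixed-mode overhead); the battery is
~30 runs of 1–2 s.  The full test suite completes in well under a minute on
one core, the acceptance script in ~15 s.

## Known limitations

- Frozen-K initiation makes the first dCaAP of any sustained stimulus a
  full-amplitude event regardless of drive; analyses therefore separate the
  onset transient from the steady state.
- Strong constant dendritic injections push the passive dendritic voltage
  tens of mV above threshold (the model has no dendritic repolarizing
  conductance), so dCaAP *events* persist while their amplitude → 0.
- The soma shows classical depolarization block above ≈ 90 µA/cm²
  (≈ 9 nA); firing-rate monotonicity holds below that.
- Backward Euler's O(dt) period bias means absolute spike times carry a
  dt-dependent phase; all cross-mode comparisons use identical dt.
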