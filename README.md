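# pyramidal

Biophysical neuron models of a layer-2/3 pyramidal cell for
neuromorphic-style simulation: a single-compartment Hodgkin–Huxley (HH)
soma and a two-compartment soma+dendrite model whose dendrite fires
calcium action potentials (dCaAPs), together with the engineering needed to
run them on hardware without floating point — lookup-table evaluation of
the channel kinetics and an emulated 32-bit fixed-point arithmetic mode —
plus a validation harness and a demonstration battery (ten firing features
and single-neuron XOR).

It is written for computational neuroscientists and neuromorphic engineers
who want a desk-scale, fully deterministic reference for how much model
behavior survives reduced-precision arithmetic and table-based kinetics.

## The models

**Soma** (equipotential sphere, area A):

    C_m dV/dt = −[g_L(V−E_L) + g_K n⁴(V−E_K) + g_Na m³h(V−E_Na)] + I_e/A

with the classical gate kinetics τ_x(V) dx/dt = x_∞(V) − x for x ∈ {m, h, n}.

**Dendrite** (coupled resistively to the soma) adds a threshold-triggered
calcium current

    I_dCaAP = −ω · K(v) · (A − B),    K(v) = exp(−F (v − V_thresh)/τ_K)

where A − B is a rise/decay sigmoid pair and K is frozen at initiation
using the dendritic voltage of that time step.  Stronger input ⇒ larger
overshoot at initiation ⇒ *smaller* event — a non-monotonic input–output
map that lets one neuron compute XOR, classically impossible for a single
linear threshold unit.

Integration is backward Euler (dt = 0.1 ms) exploiting the conditional
linearity of the membrane equation; gates use the exact exponential update.
Everything can run in IEEE double or in emulated s16.15 / u0.32 fixed-point
with round-to-nearest, with gating evaluated directly or from 1 mV lookup
tables.  See `docs/methods.md` for the full model description, the
calibration, and the numerical analysis.

## Worked example

Inject 3 nA into the dendrite for 2 s (after 100 ms of rest):

```python
import numpy as np
from pyramidal import run_protocol
from pyramidal.validation import constant_current_protocol

r = run_protocol("two", None, constant_current_protocol(3.0, "dend"))
print(r.dcaap_onsets[:4])              # [102.4 302.4 502.4 702.4]
print(np.diff(r.dcaap_onsets).min())   # 200.0
print(r.soma_spikes[0])                # 106.4
```

The dendrite fires a dCaAP every 200 ms — the refractory period, not the
drive, paces it — and the first somatic spike (106.4 ms) follows the first
dendritic event (102.4 ms), not the other way around.

The demonstration battery and the XOR truth table from the shell:

```
$ pyramidal battery
PASS tonic_spiking (soma 1.0 nA constant)
PASS phasic_spiking (soma 0.3 nA constant)
...
PASS xor (24 dendritic synapses per input at 20 Hz)
10/10 features passed

$ pyramidal xor
A B | spikes | out | expected
0 0 |      0 | 0   | 0
0 1 |      3 | 1   | 1
1 0 |      3 | 1   | 1
1 1 |      0 | 0   | 0
truth table matches
```

With one active input group the soma fires three times in the evaluation
window (one spike per dCaAP); with both groups active the dendritic events
collapse in amplitude and the soma is silent — output 1 only for exactly
one active input.

`pyramidal run -c config.yml -o out/` runs an arbitrary YAML-configured
protocol and writes traces, spike times and metadata as delimited text;
`pyramidal sweep` and `pyramidal validate` drive the fixed-vs-double
current sweep and the accuracy predicates.

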