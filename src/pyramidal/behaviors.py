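"""Demonstration battery: ten neurocomputational firing features with one
fixed parameter set, the dCaAP amplitude scan, and the single-neuron XOR.

Every feature is expressed as a machine-checkable predicate evaluated on the
simulated somatic trace.  All protocols run the two-compartment model with
the default parameters; only the stimulus differs between features.  The
stimulus magnitudes shipped here are calibrated (the behavior, not the
stimulus value, is the contract) and documented in the methods note.

The XOR experiment encodes each logical input as a group of identical
synapses on the dendritic compartment firing synchronously at 20 Hz.  One
active group depolarizes the dendrite just past the dCaAP threshold, so
dCaAPs initiate with near-maximal amplitude and drive somatic spikes; with
both groups active the dendrite overshoots into the decaying limb of the
amplitude function K and the synaptic conductance shunts the waveform, so
the soma stays silent.  The binary output of a combination is "the soma
fired at least once" inside the evaluation window, which starts 250 ms into
the stimulus so that the common onset transient (the very first dCaAP,
whose amplitude does not yet reflect the sustained input level) is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solver import (
    NeuronParameters,
    StimulusProtocol,
    SynapseGroup,
    Waveform,
    run_protocol,
)
from .validation import SETTLE, constant_current_protocol

__all__ = [
    "FeatureResult",
    "XORResult",
    "feature_battery",
    "amplitude_scan",
    "xor_experiment",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "tonic_spiking",
    "phasic_spiking",
    "subthreshold_oscillations",
    "accommodation",
    "class_2_excitability",
    "rebound_spike",
    "integrator",
    "variable_threshold",
    "adaptation",
    "xor",
)

# calibrated stimulus constants (nA unless noted); see docs/methods.md
TONIC_I = 1.0
PHASIC_I = 0.3
ACCOM_CEILING = 0.35
ACCOM_RAMP_MS = 1000.0
CLASS2_SCAN = tuple(np.round(np.arange(0.4, 1.21, 0.05), 3))
CLASS2_FLOOR_HZ = 40.0
REBOUND_I = -0.5
REBOUND_MS = 300.0
INTEGRATOR_I = 0.4
INTEGRATOR_W = 2.0
INTEGRATOR_SHORT = 1.0
INTEGRATOR_LONG = 40.0
VT_PROBE_I = 0.4
VT_PROBE_W = 2.0
VT_PRE_I = -0.3
VT_PRE_MS = 20.0
VT_GAP = 3.0
ADAPT_DEND_I = 2.3
XOR_N_SYN = 24
XOR_RATE_HZ = 20.0
XOR_DURATION = 1000.0
XOR_WINDOW_OFFSET = 250.0


@dataclass
class FeatureResult:
    name: str
    stimulus: str
    passed: bool
    detail: dict = field(default_factory=dict)


@dataclass
class XORResult:
    """Somatic spike counts per input combination inside the evaluation
    window, and the derived binary outputs."""

    counts: dict[tuple[int, int], int]
    outputs: dict[tuple[int, int], int]
    window: tuple[float, float]
    arithmetic: str

    @property
    def matches_truth_table(self) -> bool:
        return all(self.outputs[k] == (k[0] ^ k[1]) for k in self.outputs)


def _spikes_after(result, t0: float) -> np.ndarray:
    sp = result.soma_spikes
    return sp[sp >= t0]


def _run(params, proto, arithmetic="double", gating="direct"):
    return run_protocol("two", params, proto, arithmetic=arithmetic, gating=gating)


def _increasing_run(isi: np.ndarray) -> int:
    """Length (in intervals) of the longest run of strictly increasing
    consecutive inter-spike intervals."""
    best = 1 if len(isi) else 0
    run = 1
    for k in range(1, len(isi)):
        run = run + 1 if isi[k] > isi[k - 1] + 1e-9 else 1
        best = max(best, run)
    return best


def _local_maxima_below(v: np.ndarray, threshold: float, min_prominence: float = 1e-3):
    """Count strict local maxima of a trace below a voltage ceiling, ignoring
    ripples smaller than ``min_prominence`` (mV)."""
    cnt = 0
    last_min = v[0]
    rising = False
    prev = v[0]
    for x in v[1:]:
        if x > prev:
            if not rising:
                last_min = prev
                rising = True
        elif x < prev:
            if rising and prev < threshold and prev - last_min >= min_prominence:
                cnt += 1
            rising = False
        prev = x
    return cnt


def feature_battery(
    params: NeuronParameters | None = None, arithmetic: str = "double"
) -> list[FeatureResult]:
    """Run the ten firing-feature protocols with the single fixed parameter
    set and evaluate each predicate."""
    params = params or NeuronParameters()
    out: list[FeatureResult] = []
    onset = SETTLE

    # tonic spiking: sustained regular firing under constant somatic drive
    r = _run(params, constant_current_protocol(TONIC_I), arithmetic)
    sp = _spikes_after(r, onset)
    isi = np.diff(sp)
    cv = float(isi.std() / isi.mean()) if len(isi) > 1 else np.inf
    out.append(
        FeatureResult(
            "tonic_spiking",
            f"soma {TONIC_I} nA constant",
            len(sp) >= 5 and cv < 0.1,
            {"n_spikes": len(sp), "isi_cv": cv},
        )
    )

    # phasic spiking: a just-suprathreshold step fires exactly once
    r = _run(params, constant_current_protocol(PHASIC_I), arithmetic)
    sp = _spikes_after(r, onset)
    out.append(
        FeatureResult(
            "phasic_spiking",
            f"soma {PHASIC_I} nA constant",
            len(sp) == 1,
            {"n_spikes": len(sp)},
        )
    )

    # subthreshold oscillations after the phasic spike
    if len(sp) == 1:
        sel = r.time >= sp[0] + 15.0
        n_max = _local_maxima_below(r.v_soma[sel], -40.0)
    else:
        n_max = 0
    out.append(
        FeatureResult(
            "subthreshold_oscillations",
            "post-spike trace of the phasic protocol",
            n_max >= 2,
            {"n_local_maxima": n_max},
        )
    )

    # accommodation: slow ramp to a ceiling silent, step to the same ceiling fires
    ramp = Waveform.ramp(onset, onset + ACCOM_RAMP_MS, 0.0, ACCOM_CEILING)
    ramp.segments.append((onset + ACCOM_RAMP_MS, onset + 2000.0, ACCOM_CEILING, ACCOM_CEILING))
    r_ramp = _run(params, StimulusProtocol(duration=onset + 2000.0, soma_current=ramp), arithmetic)
    r_step = _run(params, constant_current_protocol(ACCOM_CEILING), arithmetic)
    n_ramp = len(_spikes_after(r_ramp, onset))
    n_step = len(_spikes_after(r_step, onset))
    out.append(
        FeatureResult(
            "accommodation",
            f"ramp over {ACCOM_RAMP_MS:g} ms vs step to {ACCOM_CEILING} nA",
            n_ramp == 0 and n_step >= 1,
            {"ramp_spikes": n_ramp, "step_spikes": n_step},
        )
    )

    # Class II excitability: firing-rate onset at a high nonzero frequency
    first_nz = None
    freqs = []
    for i_nA in CLASS2_SCAN:
        r = _run(params, constant_current_protocol(float(i_nA)), arithmetic)
        f = len(_spikes_after(r, onset + 500.0)) / 1.5  # Hz over [600, 2100] ms
        freqs.append(f)
        if f > 0 and first_nz is None:
            first_nz = f
    out.append(
        FeatureResult(
            "class_2_excitability",
            f"somatic scan {CLASS2_SCAN[0]}..{CLASS2_SCAN[-1]} nA",
            first_nz is not None and first_nz > CLASS2_FLOOR_HZ,
            {"onset_frequency_hz": first_nz, "frequencies": freqs},
        )
    )

    # rebound spike after release from hyperpolarization
    w = Waveform.constant(REBOUND_I, onset, onset + REBOUND_MS)
    r = _run(params, StimulusProtocol(duration=onset + 900.0, soma_current=w), arithmetic)
    sp = r.soma_spikes
    during = sp[(sp >= onset) & (sp < onset + REBOUND_MS)]
    after = sp[(sp >= onset + REBOUND_MS) & (sp <= onset + REBOUND_MS + 100.0)]
    out.append(
        FeatureResult(
            "rebound_spike",
            f"{REBOUND_I} nA for {REBOUND_MS:g} ms, then release",
            len(during) == 0 and len(after) >= 1,
            {"during": len(during), "within_100ms_after": len(after)},
        )
    )

    # integrator: paired brief pulses fire only at a short gap
    def pulse_pair(gap):
        w = Waveform()
        w.plus_pulse(200.0, INTEGRATOR_W, INTEGRATOR_I)
        w.plus_pulse(200.0 + INTEGRATOR_W + gap, INTEGRATOR_W, INTEGRATOR_I)
        return StimulusProtocol(duration=1000.0, soma_current=w)

    n_short = len(_spikes_after(_run(params, pulse_pair(INTEGRATOR_SHORT), arithmetic), 100.0))
    n_long = len(_spikes_after(_run(params, pulse_pair(INTEGRATOR_LONG), arithmetic), 100.0))
    out.append(
        FeatureResult(
            "integrator",
            f"two {INTEGRATOR_I} nA x {INTEGRATOR_W:g} ms pulses, "
            f"gap {INTEGRATOR_SHORT:g} vs {INTEGRATOR_LONG:g} ms",
            n_short >= 1 and n_long == 0,
            {"short_gap_spikes": n_short, "long_gap_spikes": n_long},
        )
    )

    # variable threshold: a subthreshold probe fires only after a brief
    # inhibitory pre-pulse
    def probe(with_pre):
        w = Waveform()
        if with_pre:
            w.segments.append((200.0, 200.0 + VT_PRE_MS, VT_PRE_I, VT_PRE_I))
        t0 = 200.0 + VT_PRE_MS + VT_GAP
        w.plus_pulse(t0, VT_PROBE_W, VT_PROBE_I)
        return StimulusProtocol(duration=1000.0, soma_current=w)

    n_alone = len(_spikes_after(_run(params, probe(False), arithmetic), 100.0))
    n_pre = len(_spikes_after(_run(params, probe(True), arithmetic), 100.0))
    out.append(
        FeatureResult(
            "variable_threshold",
            f"{VT_PROBE_I} nA x {VT_PROBE_W:g} ms probe, with/without "
            f"{VT_PRE_I} nA pre-pulse",
            n_alone == 0 and n_pre >= 1,
            {"alone": n_alone, "with_prepulse": n_pre},
        )
    )

    # spike-rate adaptation via the dendrite: constant dendritic drive,
    # somatic inter-spike intervals strictly increasing
    r = _run(
        params,
        constant_current_protocol(ADAPT_DEND_I, compartment="dend", stim_duration=1000.0),
        arithmetic,
    )
    sp = _spikes_after(r, onset)
    isi = np.diff(sp)
    inc = _increasing_run(isi)
    out.append(
        FeatureResult(
            "adaptation",
            f"dendrite {ADAPT_DEND_I} nA constant",
            inc >= 3,
            {"n_spikes": len(sp), "isi_ms": [float(x) for x in isi[:6]]},
        )
    )

    # XOR via the dendrite
    xr = xor_experiment(arithmetic=arithmetic)
    out.append(
        FeatureResult(
            "xor",
            f"{XOR_N_SYN} dendritic synapses per input at {XOR_RATE_HZ:g} Hz",
            xr.matches_truth_table,
            {"counts": {str(k): v for k, v in xr.counts.items()}},
        )
    )
    return out


def amplitude_scan(
    currents,
    params: NeuronParameters | None = None,
    arithmetic: str = "double",
    stim_duration: float = 2000.0,
    window_start: float = 350.0,
) -> list[dict]:
    """Steady-state dCaAP amplitude (peak |I_dCaAP| in the model's
    dimensionless current units) and somatic spike count per dendritic
    injection current.

    The analysis window starts after the first dCaAP so that the reported
    amplitude reflects the sustained input level (the very first event always
    initiates near threshold while the voltage is still rising).
    """
    params = params or NeuronParameters()
    out = []
    dc = params.dcaap
    for i_nA in currents:
        proto = constant_current_protocol(
            float(i_nA), compartment="dend", stim_duration=stim_duration
        )
        r = run_protocol("two", params, proto, arithmetic=arithmetic)
        # reconstruct |I_dCaAP| from the recorded onsets and the dendritic
        # voltage at each onset step (K frozen at activation)
        amp = 0.0
        for t_on in r.dcaap_onsets:
            if t_on < window_start:
                continue
            k_idx = int(round(t_on / proto.dt))
            v_at = r.v_dend[k_idx]
            K = np.exp(-dc.normalization * max(0.0, v_at - dc.v_thresh) / dc.tau_k)
            # peak of A-B over the waveform support
            ts = np.arange(0.0, dc.delta_t_prime + 10 * dc.tau_decay, proto.dt)
            a = 1.0 / (1.0 + np.exp(-ts / dc.tau_a))
            b = 1.0 / (1.0 + np.exp(-(ts - dc.delta_t_prime) / dc.tau_decay))
            amp = max(amp, dc.omega * K * float(np.max(a - b)))
        spikes = r.soma_spikes
        out.append(
            {
                "current_nA": float(i_nA),
                "dcaap_amplitude": float(amp),
                "soma_spikes": int(np.sum(spikes >= window_start)),
                "n_onsets": int(len(r.dcaap_onsets)),
            }
        )
    return out


def xor_experiment(
    n_syn_per_input: int = XOR_N_SYN,
    rate: float = XOR_RATE_HZ,
    duration: float = XOR_DURATION,
    params: NeuronParameters | None = None,
    arithmetic: str = "double",
    gating: str = "direct",
) -> XORResult:
    """Present the four XOR input combinations as synchronous 20 Hz synapse
    groups on the dendrite and read the somatic firing as binary output."""
    params = params or NeuronParameters()
    period = 1000.0 / rate
    events = tuple(np.arange(SETTLE, SETTLE + duration - period / 2, period))
    total = SETTLE + duration
    win = (SETTLE + XOR_WINDOW_OFFSET, total)
    counts: dict[tuple[int, int], int] = {}
    for combo in ((0, 0), (0, 1), (1, 0), (1, 1)):
        groups = tuple(
            SynapseGroup(events=events, n=n_syn_per_input)
            for bit in combo
            if bit
        )
        proto = StimulusProtocol(duration=total, dend_synapses=groups)
        r = run_protocol("two", params, proto, arithmetic=arithmetic, gating=gating)
        sp = r.soma_spikes
        counts[combo] = int(np.sum((sp >= win[0]) & (sp <= win[1])))
    outputs = {k: int(v > 0) for k, v in counts.items()}
    return XORResult(counts=counts, outputs=outputs, window=win, arithmetic=arithmetic)
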