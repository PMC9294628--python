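"""Time stepping of the single-compartment soma and the coupled
soma+dendrite model.

Voltages advance by one backward-Euler step per timestep.  With the gating
variables updated first (from the pre-step voltage, using the exact
exponential gate update), the membrane equation is linear in voltage, so the
implicit step is solved in closed form -- a scalar division for the single
compartment, a 2x2 linear solve (Gaussian elimination) for the coupled
pair.  The scheme is unconditionally stable, which matters for these stiff
equations at dt = 0.1 ms.

Per step, in order: presynaptic events are applied; synaptic conductances
and the dCaAP trigger (evaluated on the pre-step dendritic voltage) are
computed; gates advance; the voltage system is assembled and solved.  Somatic
spikes are threshold crossings of the stored trace (-20 mV, upward, with
re-arming below threshold); dendritic events are recorded as dCaAP
activation times.

Every arithmetic result in the state update passes through the active
arithmetic mode's quantizer (identity for double precision, s16.15/u0.32
round-to-nearest for the emulated fixed-point mode), so the identical code
path serves both numeric regimes.  Gating can be evaluated directly or
through lookup tables.

Compartment coupling uses the physical diffusive form: the current into a
compartment is g * (V_other - V_self).  Injected currents are given in nA
and divided by the compartment area (mm^2); the conversion factor to
uA/cm^2 is 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import dcaap as _dcaap
from .dcaap import DCaAPParameters, DCaAPState
from .errors import ConfigurationError, InvalidInputError
from .fixedpoint import DoubleArithmetic, FixedArithmetic, get_mode
from .lut import LookupTable, build_ab_table, build_gating_tables
from .model_core import (
    GatingState,
    HHChannelParameters,
    SynapseParameters,
    gating_equilibrium,
    rate_constants,
)

__all__ = [
    "GeometryParameters",
    "NeuronParameters",
    "Waveform",
    "SynapseGroup",
    "StimulusProtocol",
    "CompartmentState",
    "SimulationResult",
    "step_single",
    "step_two",
    "run_protocol",
    "detect_spikes",
    "SPIKE_THRESHOLD",
    "NA_PER_MM2_TO_UA_PER_CM2",
]

SPIKE_THRESHOLD = -20.0  # mV, somatic spike detection
NA_PER_MM2_TO_UA_PER_CM2 = 0.1
V_INIT = -65.0  # resting initialization of both compartments


@dataclass(frozen=True)
class GeometryParameters:
    """Compartment areas (mm^2), resistive couplings (mS/cm^2, per-area on
    the receiving compartment) and the dCaAP drive calibration.

    The defaults are the package's documented calibration: the somatic area
    maps nA-scale injections onto the classical current-density regime (a
    0.3 nA step elicits one spike, 3 nA repetitive firing); the dendritic
    area puts the dCaAP threshold current below 3 nA; the asymmetric
    couplings let dCaAPs drive somatic spikes while somatic action
    potentials never trigger the dendrite; ``dcaap_gain`` converts the
    dimensionless dCaAP waveform (omega * K * (A-B)) into a dendritic
    current density (uA/cm^2 per unit).
    """

    a_soma: float = 0.01
    a_dend: float = 0.02
    g_ds: float = 0.04  # coupling conductance into the soma
    g_sd: float = 0.15  # coupling conductance into the dendrite
    dcaap_gain: float = 37.0

    def __post_init__(self) -> None:
        if self.a_soma <= 0 or self.a_dend <= 0:
            raise InvalidInputError("compartment areas must be positive")
        if self.g_ds < 0 or self.g_sd < 0:
            raise InvalidInputError("couplings must be non-negative")


@dataclass(frozen=True)
class NeuronParameters:
    """Bundle of all model parameters with the published/calibrated defaults."""

    hh: HHChannelParameters = field(default_factory=HHChannelParameters)
    dcaap: DCaAPParameters = field(default_factory=DCaAPParameters)
    synapse: SynapseParameters = field(default_factory=SynapseParameters)
    geometry: GeometryParameters = field(default_factory=GeometryParameters)


class Waveform:
    """Piecewise-linear injected-current waveform (nA against ms).

    Built from segments (t0, t1, v0, v1); the current ramps linearly from v0
    at t0 to v1 at t1 and is zero outside all segments.  Constructors cover
    the stock protocols (constant steps, ramps, pulse pairs).
    """

    def __init__(self, segments: list[tuple[float, float, float, float]] | None = None):
        self.segments = list(segments or [])

    @classmethod
    def constant(cls, amplitude: float, t0: float, t1: float) -> "Waveform":
        return cls([(t0, t1, amplitude, amplitude)])

    @classmethod
    def ramp(cls, t0: float, t1: float, v0: float, v1: float) -> "Waveform":
        return cls([(t0, t1, v0, v1)])

    def plus_pulse(self, t0: float, width: float, amplitude: float) -> "Waveform":
        self.segments.append((t0, t0 + width, amplitude, amplitude))
        return self

    def sample(self, n_steps: int, dt: float) -> np.ndarray:
        """Current (nA) applied during each of the ``n_steps`` update steps;
        step k uses the waveform value at t = k*dt."""
        t = np.arange(n_steps) * dt
        out = np.zeros(n_steps)
        for (t0, t1, v0, v1) in self.segments:
            sel = (t >= t0) & (t < t1)
            if t1 > t0:
                out[sel] += v0 + (v1 - v0) * (t[sel] - t0) / (t1 - t0)
            else:
                out[sel] += v0
        return out


@dataclass(frozen=True)
class SynapseGroup:
    """A set of ``n`` identical synapses on one compartment activated
    synchronously at the listed event times (ms)."""

    events: tuple[float, ...]
    n: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("a synapse group needs n >= 1")
        if list(self.events) != sorted(self.events):
            raise InvalidInputError("event times must be sorted")


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulation plan: injected current per compartment, synaptic event
    trains per compartment, total duration and timestep (ms)."""

    duration: float
    dt: float = 0.1
    soma_current: Waveform | None = None
    dend_current: Waveform | None = None
    soma_synapses: tuple[SynapseGroup, ...] = ()
    dend_synapses: tuple[SynapseGroup, ...] = ()

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration must be a multiple of dt")
        for grp in self.soma_synapses + self.dend_synapses:
            for t in grp.events:
                if not 0.0 <= t <= self.duration:
                    raise ConfigurationError(
                        f"synaptic event at {t} ms outside [0, {self.duration}]"
                    )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class CompartmentState:
    """Voltage plus the mechanism state of one compartment (HH gates for the
    soma, dCaAP state for the dendrite)."""

    v: float
    gates: GatingState | None = None
    dcaap: DCaAPState | None = None


@dataclass
class SimulationResult:
    """Time grid, voltage traces, event times and run metadata."""

    time: np.ndarray
    v_soma: np.ndarray
    v_dend: np.ndarray | None
    soma_spikes: np.ndarray
    dcaap_onsets: np.ndarray
    gates: dict[str, np.ndarray] | None
    metadata: dict

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


# ---------------------------------------------------------------------------
# mode-aware building blocks
# ---------------------------------------------------------------------------


class _Consts:
    """All model constants pre-quantized for the active arithmetic mode."""

    def __init__(self, params: NeuronParameters, dt: float, mode):
        qa = mode.acc
        hh = params.hh
        geo = params.geometry
        dc = params.dcaap
        self.g_l = qa(hh.g_leak_ms)
        self.g_k = qa(hh.g_k_ms)
        self.g_na = qa(hh.g_na_ms)
        self.e_l = qa(hh.e_leak)
        self.e_k = qa(hh.e_k)
        self.e_na = qa(hh.e_na)
        self.cm_dt = qa(hh.c_m / dt)
        self.g_ds = qa(geo.g_ds)
        self.g_sd = qa(geo.g_sd)
        self.v_thresh = qa(dc.v_thresh)
        # F/tau_K, the exponent slope of the amplitude function (per mV)
        self.k_slope = qa(dc.normalization / dc.tau_k)
        # omega * gain: dimensionless waveform -> current density
        self.dcaap_drive = qa(dc.omega * geo.dcaap_gain)
        self.dt_q = qa(dt)
        self.e_syn = qa(params.synapse.e_syn)
        self.tau_s = params.synapse.tau_s
        self.g_syn_unit = qa(params.synapse.g_max)
        self.p_max = mode.frac(params.synapse.p_max)


def _advance_gates_direct(gates: GatingState, v: float, dt: float, mode) -> GatingState:
    """One exponential gate step evaluated from the rate functions (software
    exp/div in fixed mode), in the [0,1)-preserving product form."""
    qa, qf = mode.acc, mode.frac
    r = rate_constants(v)
    out = {}
    for gate, a, b in (
        ("n", r.alpha_n, r.beta_n),
        ("m", r.alpha_m, r.beta_m),
        ("h", r.alpha_h, r.beta_h),
    ):
        aq = qa(a)
        bq = qa(b)
        s = qa(aq + bq)
        xi = qf(qa(aq / s))
        ef = qf(math.exp(qa(-qa(dt * s))))
        x = getattr(gates, gate)
        out[gate] = qf(qf(xi * qf(1.0 - ef)) + qf(x * ef))
    return GatingState(m=out["m"], h=out["h"], n=out["n"])


def _advance_gates_lut(
    gates: GatingState, v: float, table: LookupTable, mode
) -> GatingState:
    qa, qf = mode.acc, mode.frac
    cols = table.columns
    n_nodes = table.n_nodes
    u = qa(qa(v - table.domain_min) * qa(1.0 / table.step))
    i0 = int(u)
    if i0 < 0:
        i0, frp = 0, 0.0
    elif i0 >= n_nodes - 1:
        i0, frp = n_nodes - 2, 1.0
    else:
        frp = qa(u - i0)
    out = {}
    for gate in ("n", "m", "h"):
        ci = cols[f"{gate}_inf"]
        ce = cols[f"expfac_{gate}"]
        xi = qf(ci[i0] + qa(frp * qa(ci[i0 + 1] - ci[i0])))
        ef = qf(ce[i0] + qa(frp * qa(ce[i0 + 1] - ce[i0])))
        x = getattr(gates, gate)
        out[gate] = qf(qf(xi * qf(1.0 - ef)) + qf(x * ef))
    return GatingState(m=out["m"], h=out["h"], n=out["n"])


def _assemble_soma(
    gates: GatingState, c: _Consts, dens: float, syn_g: float, syn_src: float, mode
):
    """Active conductance G and reversal-weighted source S of the somatic
    membrane equation (backward-Euler right-hand side pieces)."""
    qa, qf = mode.acc, mode.frac
    n = gates.n
    m = gates.m
    n2 = qf(n * n)
    n4 = qf(n2 * n2)
    m2 = qf(m * m)
    m3 = qf(m2 * m)
    m3h = qf(m3 * gates.h)
    gk = qa(c.g_k * n4)
    gna = qa(c.g_na * m3h)
    g = qa(qa(qa(c.g_l + gk) + gna) + syn_g)
    s = qa(
        qa(qa(c.g_l * c.e_l) + qa(gk * c.e_k))
        + qa(qa(gna * c.e_na) + qa(dens + syn_src))
    )
    return g, s


def _assemble_dend(
    c: _Consts, dens: float, syn_g: float, syn_src: float, dcaap_src: float, mode
):
    """Passive conductance and source of the dendritic membrane equation;
    the dCaAP current enters as an explicit (voltage-independent) source."""
    qa = mode.acc
    g = qa(c.g_l + syn_g)
    s = qa(qa(qa(c.g_l * c.e_l) + qa(dens + syn_src)) + dcaap_src)
    return g, s


def _solve_one(v: float, g: float, s: float, c: _Consts, mode) -> float:
    qa = mode.acc
    a11 = qa(c.cm_dt + g)
    b1 = qa(qa(c.cm_dt * v) + s)
    return qa(b1 / a11)


def _solve_pair(
    vs: float, gs: float, ss: float, vd: float, gd: float, sd: float, c: _Consts, mode
) -> tuple[float, float]:
    """Joint backward-Euler step of the coupled pair by Gaussian elimination.
    With both couplings exactly zero this reduces bitwise to two independent
    single-compartment solves."""
    qa = mode.acc
    a11 = qa(qa(c.cm_dt + gs) + c.g_ds)
    a12 = -c.g_ds
    a21 = -c.g_sd
    a22 = qa(qa(c.cm_dt + gd) + c.g_sd)
    b1 = qa(qa(c.cm_dt * vs) + ss)
    b2 = qa(qa(c.cm_dt * vd) + sd)
    mf = qa(a21 / a11)
    a22p = qa(a22 - qa(mf * a12))
    b2p = qa(b2 - qa(mf * b1))
    vd_new = qa(b2p / a22p)
    vs_new = qa(qa(b1 - qa(a12 * vd_new)) / a11)
    return vs_new, vd_new


# ---------------------------------------------------------------------------
# public stepping API
# ---------------------------------------------------------------------------


def initial_state(kind: str = "soma", v: float = V_INIT) -> CompartmentState:
    """Compartment at the standard initialization: v = -65 mV, gates at
    their steady state for that voltage, dCaAP inactive and eligible."""
    if kind == "soma":
        eq = gating_equilibrium(v)
        return CompartmentState(
            v=v, gates=GatingState(m=eq.m_inf, h=eq.h_inf, n=eq.n_inf)
        )
    if kind == "dend":
        return CompartmentState(v=v, dcaap=DCaAPState())
    raise InvalidInputError(f"unknown compartment kind {kind!r}")


def step_single(
    state: CompartmentState,
    ie: float,
    dt: float,
    p: HHChannelParameters | None = None,
    geom: GeometryParameters | None = None,
    mode=None,
    params: NeuronParameters | None = None,
) -> CompartmentState:
    """One backward-Euler step of the single-compartment HH soma with
    injected current ``ie`` (nA)."""
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    params = params or NeuronParameters(
        hh=p or HHChannelParameters(), geometry=geom or GeometryParameters()
    )
    mode = mode or DoubleArithmetic()
    c = _Consts(params, dt, mode)
    dens = mode.acc(
        NA_PER_MM2_TO_UA_PER_CM2 * ie / params.geometry.a_soma
    )
    gates = _advance_gates_direct(state.gates, state.v, dt, mode)
    g, s = _assemble_soma(gates, c, dens, 0.0, 0.0, mode)
    v_new = _solve_one(state.v, g, s, c, mode)
    return CompartmentState(v=v_new, gates=gates)


def step_two(
    soma: CompartmentState,
    dend: CompartmentState,
    ie_s: float,
    ie_d: float,
    t_now: float,
    dt: float,
    params: NeuronParameters | None = None,
    mode=None,
) -> tuple[CompartmentState, CompartmentState]:
    """One joint backward-Euler step of the coupled soma+dendrite pair.

    The dCaAP trigger is evaluated on the pre-step dendritic voltage; both
    voltages then advance simultaneously through the 2x2 solve.
    """
    params = params or NeuronParameters()
    mode = mode or DoubleArithmetic()
    c = _Consts(params, dt, mode)
    geo = params.geometry
    dens_s = mode.acc(NA_PER_MM2_TO_UA_PER_CM2 * ie_s / geo.a_soma)
    dens_d = mode.acc(NA_PER_MM2_TO_UA_PER_CM2 * ie_d / geo.a_dend)

    dc_state = _dcaap.dcaap_trigger(dend.v, t_now, dend.dcaap, params.dcaap)
    dcaap_src = 0.0
    if dc_state.active:
        w = _dcaap.ab_waveform(t_now - dc_state.t_prime, params.dcaap)
        if w >= _dcaap.WAVEFORM_FLOOR:
            wq = mode.frac(w)
            kq = mode.frac(dc_state.k_at_activation)
            dcaap_src = mode.acc(mode.acc(c.dcaap_drive * kq) * wq)
        elif t_now - dc_state.t_prime > params.dcaap.delta_t_prime:
            dc_state = _dcaap.deactivate(dc_state)

    gates = _advance_gates_direct(soma.gates, soma.v, dt, mode)
    gs, ss = _assemble_soma(gates, c, dens_s, 0.0, 0.0, mode)
    gd, sd = _assemble_dend(c, dens_d, 0.0, 0.0, dcaap_src, mode)
    vs_new, vd_new = _solve_pair(soma.v, gs, ss, dend.v, gd, sd, c, mode)
    return (
        CompartmentState(v=vs_new, gates=gates),
        CompartmentState(v=vd_new, dcaap=dc_state),
    )


def detect_spikes(
    trace: np.ndarray, dt: float, threshold: float = SPIKE_THRESHOLD
) -> np.ndarray:
    """Times of upward threshold crossings.  After a detection no new spike
    is registered until the trace has fallen back below the threshold, so a
    plateau above threshold counts once."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise InvalidInputError("empty trace")
    above = trace >= threshold
    rising = above[1:] & ~above[:-1]
    return (np.flatnonzero(rising) + 1) * dt


def _group_tse(grp: SynapseGroup, n_steps: int, dt: float) -> np.ndarray:
    """Per-step time since the most recent event of a group (inf before the
    first event)."""
    tse = np.full(n_steps, np.inf)
    ev = np.asarray(grp.events, dtype=float)
    t = np.arange(n_steps) * dt
    idx = np.searchsorted(ev, t + 1e-9) - 1
    has = idx >= 0
    tse[has] = t[has] - ev[idx[has]]
    return tse


def run_protocol(
    model: str,
    params: NeuronParameters | None,
    protocol: StimulusProtocol,
    arithmetic: str = "double",
    gating: str = "direct",
    lut_step: float = 1.0,
    record_gates: bool = False,
) -> SimulationResult:
    """Run a full stimulation protocol and return traces, spike times and
    dCaAP onsets.  Fully deterministic for identical inputs.

    model: "single" (HH soma only) or "two" (coupled soma+dendrite).
    arithmetic: "double" or "fixed"; gating: "direct" or "lut".
    """
    if model not in ("single", "two"):
        raise ConfigurationError(f"unknown model {model!r}")
    if gating not in ("direct", "lut"):
        raise ConfigurationError(f"unknown gating path {gating!r}")
    params = params or NeuronParameters()
    mode = get_mode(arithmetic)
    qa, qf = mode.acc, mode.frac
    dt = protocol.dt
    n_steps = protocol.n_steps
    c = _Consts(params, dt, mode)
    geo = params.geometry
    dc_par = params.dcaap
    two = model == "two"

    gtable = None
    ab_vals = None
    if gating == "lut":
        gtable = build_gating_tables(step=lut_step, dt=dt)
        abt = build_ab_table(dt_res=dt, p=dc_par)
        if arithmetic == "fixed":
            gtable = gtable.quantized(qf)
            abt = abt.quantized(qf)
        ab_vals = abt.columns["ab"]

    # pre-step injected current densities (uA/cm^2), mode-quantized
    ie_s = (protocol.soma_current or Waveform()).sample(n_steps, dt)
    dens_s = np.array(
        [qa(NA_PER_MM2_TO_UA_PER_CM2 * v / geo.a_soma) for v in ie_s]
    )
    if two:
        ie_d = (protocol.dend_current or Waveform()).sample(n_steps, dt)
        dens_d = np.array(
            [qa(NA_PER_MM2_TO_UA_PER_CM2 * v / geo.a_dend) for v in ie_d]
        )

    # synaptic bookkeeping: per-group time-since-event arrays
    syn_s = [
        (qa(grp.n * params.synapse.g_max), _group_tse(grp, n_steps, dt))
        for grp in protocol.soma_synapses
    ]
    syn_d = [
        (qa(grp.n * params.synapse.g_max), _group_tse(grp, n_steps, dt))
        for grp in protocol.dend_synapses
    ]
    tau_s = params.synapse.tau_s
    p_max = c.p_max
    e_syn = c.e_syn

    soma = initial_state("soma")
    soma = CompartmentState(
        v=qa(soma.v),
        gates=GatingState(
            m=qf(soma.gates.m), h=qf(soma.gates.h), n=qf(soma.gates.n)
        ),
    )
    vs = soma.v
    gates = soma.gates
    vd = qa(V_INIT) if two else None
    dc_active = False
    dc_tprime = None
    dc_k = 0.0
    onsets: list[float] = []

    trace_s = np.empty(n_steps + 1)
    trace_s[0] = vs
    trace_d = np.empty(n_steps + 1) if two else None
    if two:
        trace_d[0] = vd
    gate_tr = (
        {k: np.empty(n_steps + 1) for k in ("m", "h", "n")} if record_gates else None
    )
    if record_gates:
        for k in ("m", "h", "n"):
            gate_tr[k][0] = getattr(gates, k)

    refractory = dc_par.refractory
    delta_t = dc_par.delta_t_prime
    v_thresh = c.v_thresh
    floor = _dcaap.WAVEFORM_FLOOR

    for k in range(n_steps):
        t = k * dt

        # synaptic conductance and reversal-weighted source per compartment
        sg_s = 0.0
        src_s = 0.0
        for g_unit, tse in syn_s:
            tk = tse[k]
            if tk != np.inf:
                ps = qf(p_max * math.exp(-tk / tau_s))
                gsy = qa(g_unit * ps)
                sg_s = qa(sg_s + gsy)
                src_s = qa(src_s + qa(gsy * e_syn))
        if two:
            sg_d = 0.0
            src_d = 0.0
            for g_unit, tse in syn_d:
                tk = tse[k]
                if tk != np.inf:
                    ps = qf(p_max * math.exp(-tk / tau_s))
                    gsy = qa(g_unit * ps)
                    sg_d = qa(sg_d + gsy)
                    src_d = qa(src_d + qa(gsy * e_syn))

            # dCaAP trigger on the pre-step dendritic voltage
            eligible = dc_tprime is None or (t - dc_tprime) >= refractory
            if vd >= v_thresh and eligible:
                dc_active = True
                dc_tprime = t
                dc_k = qf(math.exp(qa(-qa(c.k_slope * qa(vd - v_thresh)))))
                onsets.append(t)
            dcaap_src = 0.0
            if dc_active:
                off = t - dc_tprime
                if ab_vals is not None:
                    i_ab = int(round(off / dt))
                    w = ab_vals[i_ab] if i_ab < len(ab_vals) else 0.0
                else:
                    w = _dcaap.ab_waveform(off, dc_par)
                if w >= floor:
                    dcaap_src = qa(qa(c.dcaap_drive * dc_k) * qf(w))
                elif off > delta_t:
                    dc_active = False

        # gates from the pre-step somatic voltage
        if gtable is not None:
            gates = _advance_gates_lut(gates, vs, gtable, mode)
        else:
            gates = _advance_gates_direct(gates, vs, dt, mode)

        gs, ss = _assemble_soma(gates, c, dens_s[k], sg_s, src_s, mode)
        if two:
            gd, sd = _assemble_dend(c, dens_d[k], sg_d, src_d, dcaap_src, mode)
            vs, vd = _solve_pair(vs, gs, ss, vd, gd, sd, c, mode)
            trace_d[k + 1] = vd
        else:
            vs = _solve_one(vs, gs, ss, c, mode)
        trace_s[k + 1] = vs
        if record_gates:
            for nm in ("m", "h", "n"):
                gate_tr[nm][k + 1] = getattr(gates, nm)

    time = np.arange(n_steps + 1) * dt
    return SimulationResult(
        time=time,
        v_soma=trace_s,
        v_dend=trace_d,
        soma_spikes=detect_spikes(trace_s, dt),
        dcaap_onsets=np.array(onsets),
        gates=gate_tr,
        metadata={
            "model": model,
            "arithmetic": arithmetic,
            "gating": gating,
            "lut_step": lut_step if gating == "lut" else None,
            "dt": dt,
            "duration": protocol.duration,
            "saturation_count": mode.saturation_count,
        },
    )
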