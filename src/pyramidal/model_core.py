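"""Hodgkin-Huxley ion-channel kinetics, somatic membrane current and the
exponential-release synapse, as pure functions over state.

The model describes the soma of a layer-2/3 pyramidal neuron as an
equipotential sphere carrying voltage-gated Na+ and K+ channels plus a leak.
Gating variables m (Na+ activation), h (Na+ inactivation) and n (K+
activation) follow first-order kinetics

    tau_x(V) dx/dt = x_inf(V) - x

with the classical voltage-dependent opening/closing rates alpha_x, beta_x.
Because the rates depend only on voltage, the gate equation is linear in x at
fixed V and admits the closed-form update

    x(t + dt) = x_inf + (x(t) - x_inf) * exp(-dt / tau_x)

which this module uses ("conditional linearity"); it is exact for constant V
over the step.

Unit system: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2. Channel conductances are
specified in S/cm^2 (the conventional literature values) and converted to
mS/cm^2 internally so that (mS/cm^2) * mV = uA/cm^2 is consistent with
(uF/cm^2) * (mV/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError, InvalidStateError

__all__ = [
    "HHChannelParameters",
    "GatingState",
    "RateSet",
    "GatingEquilibrium",
    "SynapseParameters",
    "SynapseState",
    "rate_constants",
    "gating_equilibrium",
    "advance_gate",
    "somatic_membrane_current",
    "synaptic_release_probability",
    "synaptic_current",
]

# Tolerance below which the removable singularities of alpha_n / alpha_m are
# evaluated by their analytic limits instead of the 0/0 expression.
_SINGULARITY_EPS = 1e-7


@dataclass(frozen=True)
class HHChannelParameters:
    """Maximal conductances (S/cm^2), reversal potentials (mV) and membrane
    capacitance (uF/cm^2) of the somatic Na+/K+/leak membrane."""

    g_na: float = 0.12
    g_k: float = 0.036
    g_leak: float = 0.0003
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.3
    c_m: float = 1.0

    def __post_init__(self) -> None:
        if min(self.g_na, self.g_k, self.g_leak) < 0:
            raise InvalidInputError("conductances must be non-negative")
        if self.c_m <= 0:
            raise InvalidInputError("membrane capacitance must be positive")
        if not self.e_na > self.e_k:
            raise InvalidInputError("E_Na must exceed E_K")

    # conductances in mS/cm^2, the unit actually used in the membrane equation
    @property
    def g_na_ms(self) -> float:
        return self.g_na * 1000.0

    @property
    def g_k_ms(self) -> float:
        return self.g_k * 1000.0

    @property
    def g_leak_ms(self) -> float:
        return self.g_leak * 1000.0


@dataclass
class GatingState:
    """Dimensionless channel-gate open fractions, each confined to [0, 1]."""

    m: float
    h: float
    n: float

    def validate(self) -> None:
        for name in ("m", "h", "n"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidStateError(f"gate {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class RateSet:
    """Gate transition rates (1/ms) at a fixed voltage."""

    alpha_n: float
    beta_n: float
    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float


@dataclass(frozen=True)
class GatingEquilibrium:
    """Steady-state values and time constants of the three gates."""

    n_inf: float
    tau_n: float
    m_inf: float
    tau_m: float
    h_inf: float
    tau_h: float


@dataclass(frozen=True)
class SynapseParameters:
    """Excitatory (NMDA-like, E_syn = 0 mV) synapse with exponentially
    decaying release probability.

    ``g_max`` is the maximal conductance density contributed by one synapse,
    expressed directly in mS/cm^2 on the target compartment (the printed
    value 0.05 is read in this normalized unit system; see the methods note).
    """

    g_max: float = 0.05
    e_syn: float = 0.0
    p_max: float = 1.0
    tau_s: float = 10.0

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise InvalidInputError("g_max must be non-negative")
        if not 0.0 <= self.p_max <= 1.0:
            raise InvalidInputError("P_max must lie in [0, 1]")
        if self.tau_s <= 0:
            raise InvalidInputError("tau_s must be positive")


@dataclass
class SynapseState:
    """Time of the most recent presynaptic activation; None means the
    synapse has never been activated."""

    last_event_time: float | None = None


def rate_constants(v: float) -> RateSet:
    """Opening/closing rates of the n, m and h gates at voltage ``v`` (mV).

    The two removable singularities (alpha_n at v = -55, alpha_m at v = -40)
    return their analytic limits 0.1 and 1.0.
    """
    if not math.isfinite(v):
        raise InvalidInputError(f"voltage must be finite, got {v!r}")

    x = v + 55.0
    if abs(x) < _SINGULARITY_EPS:
        alpha_n = 0.1
    else:
        alpha_n = 0.01 * x / (1.0 - math.exp(-0.1 * x))
    beta_n = 0.125 * math.exp(-0.0125 * (v + 65.0))

    y = v + 40.0
    if abs(y) < _SINGULARITY_EPS:
        alpha_m = 1.0
    else:
        alpha_m = 0.1 * y / (1.0 - math.exp(-0.1 * y))
    beta_m = 4.0 * math.exp(-0.0556 * (v + 65.0))

    alpha_h = 0.07 * math.exp(-0.05 * (v + 65.0))
    beta_h = 1.0 / (1.0 + math.exp(-0.1 * (v + 35.0)))

    return RateSet(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)


def gating_equilibrium(v: float) -> GatingEquilibrium:
    """Steady state x_inf = alpha/(alpha+beta) and time constant
    tau_x = 1/(alpha+beta) (ms) for each gate at voltage ``v``."""
    r = rate_constants(v)
    sn = r.alpha_n + r.beta_n
    sm = r.alpha_m + r.beta_m
    sh = r.alpha_h + r.beta_h
    return GatingEquilibrium(
        n_inf=r.alpha_n / sn,
        tau_n=1.0 / sn,
        m_inf=r.alpha_m / sm,
        tau_m=1.0 / sm,
        h_inf=r.alpha_h / sh,
        tau_h=1.0 / sh,
    )


def advance_gate(x: float, v: float, dt: float, gate: str = "n") -> float:
    """Advance one gate by ``dt`` (ms) at fixed voltage using the exact
    exponential update x' = x_inf + (x - x_inf) exp(-dt/tau_x).

    The result is a convex combination of ``x`` and x_inf(v), hence always
    in [0, 1] and between the two.
    """
    if not 0.0 <= x <= 1.0:
        raise InvalidStateError(f"gate value {x} outside [0, 1]")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    eq = gating_equilibrium(v)
    x_inf = getattr(eq, f"{gate}_inf")
    tau = getattr(eq, f"tau_{gate}")
    return x_inf + (x - x_inf) * math.exp(-dt / tau)


def somatic_membrane_current(
    v: float, gates: GatingState, p: HHChannelParameters
) -> float:
    """Total somatic membrane current density (uA/cm^2):
    leak + K+ (n^4) + Na+ (m^3 h), each driven by its reversal potential."""
    gates.validate()
    n4 = gates.n**4
    m3h = gates.m**3 * gates.h
    return (
        p.g_leak_ms * (v - p.e_leak)
        + p.g_k_ms * n4 * (v - p.e_k)
        + p.g_na_ms * m3h * (v - p.e_na)
    )


def synaptic_release_probability(
    t_since_event: float | None, p: SynapseParameters
) -> float:
    """P_s = P_max exp(-t/tau_s); zero if the synapse was never activated."""
    if t_since_event is None:
        return 0.0
    if t_since_event < 0:
        raise InvalidInputError("time since event must be non-negative")
    return p.p_max * math.exp(-t_since_event / p.tau_s)


def synaptic_current(
    v: float, t_since_event: float | None, p: SynapseParameters
) -> float:
    """Synaptic current density (uA/cm^2) of one synapse,
    I_syn = g_max P_s (V - E_syn). Outward-positive like the channel terms."""
    ps = synaptic_release_probability(t_since_event, p)
    return p.g_max * ps * (v - p.e_syn)
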