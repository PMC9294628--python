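"""Dendritic calcium action potential (dCaAP) current.

The dendritic compartment carries, besides the leak, a threshold-triggered
calcium current

    I_dCaAP = -omega * K(v) * (A - B)

A dCaAP is initiated when the dendritic potential reaches the threshold
V_thresh = -36 mV while the mechanism is not refractory.  At initiation the
amplitude factor

    K(v) = exp(-F * (v - V_thresh) / tau_K),    F = 1 / (V_thresh - V_rest)

is evaluated with the dendritic voltage of that very time step and then held
fixed for the whole waveform, so the farther the voltage has overshot the
threshold at initiation, the smaller the event: the signature non-monotonic
input-output property of these dendrites.  A - B is a difference of two
sigmoids describing the rise (time constant tau_A) and, offset by
delta_t_prime, the decay of the current.  After initiation the mechanism is
refractory for 200 ms.

The decay sigmoid uses the same time constant as the rise (tau_A), following
the printed form of the model; the separately quoted tau_B = 0.4 ms is kept
as a parameter and can be selected via ``decay_tau`` for a sharp-cutoff
variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import InvalidInputError, InvalidStateError
from .model_core import HHChannelParameters

__all__ = [
    "DCaAPParameters",
    "DCaAPState",
    "dcaap_trigger",
    "ab_waveform",
    "dcaap_current",
    "dendritic_membrane_current",
    "WAVEFORM_FLOOR",
]

# below this value the A - B waveform is treated as ended
WAVEFORM_FLOOR = 1e-9


@dataclass(frozen=True)
class DCaAPParameters:
    """Threshold, amplitude and waveform constants of the dCaAP current.

    v_rest is the passive resting potential used in the normalization factor
    F = 1/(v_thresh - v_rest); the dendrite at rest carries only leak, so it
    defaults to the leak reversal (-54.3 mV), giving F = 1/18.3 per mV.
    tau_k is dimensionless, all times in ms.
    """

    v_thresh: float = -36.0
    v_rest: float = -54.3
    omega: float = 3.0
    tau_k: float = 0.3
    tau_a: float = 3.0
    tau_b: float = 0.4
    delta_t_prime: float = 21.0
    refractory: float = 200.0
    decay_tau: str = "A"  # which constant the decay sigmoid uses: "A" or "B"

    def __post_init__(self) -> None:
        if min(self.tau_a, self.tau_b, self.delta_t_prime, self.refractory) <= 0:
            raise InvalidInputError("dCaAP time constants must be positive")
        if not self.v_thresh > self.v_rest:
            raise InvalidInputError("V_thresh must exceed V_rest")
        if self.decay_tau not in ("A", "B"):
            raise InvalidInputError("decay_tau must be 'A' or 'B'")

    @property
    def normalization(self) -> float:
        """F = 1/(V_thresh - V_rest), per mV."""
        return 1.0 / (self.v_thresh - self.v_rest)

    @property
    def tau_decay(self) -> float:
        return self.tau_a if self.decay_tau == "A" else self.tau_b


@dataclass(frozen=True)
class DCaAPState:
    """Whether a waveform is in progress, when the most recent dCaAP was
    initiated, and the amplitude factor frozen at initiation."""

    active: bool = False
    t_prime: float | None = None
    k_at_activation: float = 0.0

    def validate(self, t_now: float | None = None) -> None:
        if self.active and self.t_prime is None:
            raise InvalidStateError("active dCaAP without an activation time")
        if self.active and not 0.0 < self.k_at_activation <= 1.0:
            raise InvalidStateError(
                f"K_at_activation={self.k_at_activation} outside (0, 1]"
            )
        if t_now is not None and self.t_prime is not None and self.t_prime > t_now:
            raise InvalidStateError("activation time lies in the future")


def dcaap_trigger(
    v_dend: float, t_now: float, state: DCaAPState, p: DCaAPParameters
) -> DCaAPState:
    """Evaluate the activation rule at one time step.

    Fires when v_dend >= V_thresh and the refractory period since the last
    activation has elapsed (or none has ever occurred).  On activation the
    amplitude factor K is computed from this step's overshoot and frozen;
    otherwise the state is returned unchanged.
    """
    state.validate(t_now)
    eligible = state.t_prime is None or (t_now - state.t_prime) >= p.refractory
    if v_dend >= p.v_thresh and eligible:
        k = math.exp(-p.normalization * (v_dend - p.v_thresh) / p.tau_k)
        return DCaAPState(active=True, t_prime=t_now, k_at_activation=k)
    return state


def ab_waveform(t_minus_tprime: float, p: DCaAPParameters) -> float:
    """Rise-minus-decay waveform A - B at time ``t_minus_tprime`` (ms) after
    activation; dimensionless, non-negative, < 1."""
    if t_minus_tprime < 0:
        raise InvalidInputError("waveform argument must be non-negative")
    a = 1.0 / (1.0 + math.exp(-t_minus_tprime / p.tau_a))
    b = 1.0 / (1.0 + math.exp(-(t_minus_tprime - p.delta_t_prime) / p.tau_decay))
    return a - b


def dcaap_current(state: DCaAPState, t_now: float, p: DCaAPParameters) -> float:
    """I_dCaAP = -omega * K * (A - B) in the model's dimensionless current
    units (negative = inward/depolarizing); exactly 0 when no waveform is in
    progress or the waveform has decayed below the floor."""
    state.validate(t_now)
    if not state.active or state.t_prime is None:
        return 0.0
    w = ab_waveform(t_now - state.t_prime, p)
    if w < WAVEFORM_FLOOR:
        return 0.0
    return -p.omega * state.k_at_activation * w


def waveform_finished(state: DCaAPState, t_now: float, p: DCaAPParameters) -> bool:
    """True once the waveform of an active dCaAP has decayed below the floor
    (used by the solver to deactivate the state)."""
    if not state.active or state.t_prime is None:
        return False
    dt = t_now - state.t_prime
    return dt > p.delta_t_prime and ab_waveform(dt, p) < WAVEFORM_FLOOR


def deactivate(state: DCaAPState) -> DCaAPState:
    return replace(state, active=False)


def dendritic_membrane_current(
    v_dend: float,
    state: DCaAPState,
    t_now: float,
    hh: HHChannelParameters,
    p: DCaAPParameters,
    current_scale: float = 1.0,
) -> float:
    """Total dendritic membrane current density (uA/cm^2): the leak plus the
    dCaAP current scaled into current-density units by ``current_scale``
    (the dendrite-to-soma drive calibration; see GeometryParameters)."""
    return hh.g_leak_ms * (v_dend - hh.e_leak) + current_scale * dcaap_current(
        state, t_now, p
    )
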