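"""Accuracy methodology: trace and spike-time comparison between arithmetic
and gating modes, constant-current sweeps, and the lookup-table resolution
study.

The in-package reference trajectory is the double-precision direct-evaluation
path.  Spike-time fidelity between the emulated fixed-point mode and double
precision is assessed with both simulations using the same lookup tables, so
that the comparison isolates the arithmetic representation (table
discretization shifts the trajectory of *both* modes identically; measured
against the table-free reference that shared bias would dominate -- see the
methods note).

Max-voltage errors are reported over the whole run; spike-time deltas pair
the k-th spike with the k-th spike, flagging count mismatches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import ComparisonError
from .solver import (
    NeuronParameters,
    SimulationResult,
    StimulusProtocol,
    Waveform,
    run_protocol,
)

__all__ = [
    "ComparisonReport",
    "compare_traces",
    "current_sweep",
    "lut_resolution_study",
    "serialize_reports",
    "constant_current_protocol",
    "SETTLE",
    "DEFAULT_SWEEP_CURRENTS",
]

SETTLE = 100.0  # ms of rest preceding stimulus onset in validation runs
DEFAULT_SWEEP_CURRENTS = tuple(np.arange(0.0, 10.01, 0.5))


def constant_current_protocol(
    amplitude: float,
    compartment: str = "soma",
    stim_duration: float = 2000.0,
    dt: float = 0.1,
    settle: float = SETTLE,
) -> StimulusProtocol:
    """Constant injection of ``amplitude`` nA into one compartment for
    ``stim_duration`` ms after a settling period at rest."""
    wave = Waveform.constant(amplitude, settle, settle + stim_duration)
    kw = {"soma_current": wave} if compartment == "soma" else {"dend_current": wave}
    return StimulusProtocol(duration=settle + stim_duration, dt=dt, **kw)


@dataclass
class ComparisonReport:
    """Pointwise and spike-time comparison of two runs of one protocol."""

    max_abs_voltage_error: dict[str, float]
    spike_deltas: dict[str, np.ndarray]
    spike_count_mismatch: bool
    meta: dict = field(default_factory=dict)

    @property
    def max_spike_delta(self) -> float:
        vals = [float(np.max(d)) for d in self.spike_deltas.values() if len(d)]
        return max(vals) if vals else 0.0


def _paired_deltas(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, bool]:
    n = min(len(a), len(b))
    return np.abs(a[:n] - b[:n]), len(a) != len(b)


def compare_traces(a: SimulationResult, b: SimulationResult) -> ComparisonReport:
    """Max |V_a - V_b| per compartment and in-order spike-time deltas."""
    if len(a.time) != len(b.time) or abs(a.dt - b.dt) > 1e-12:
        raise ComparisonError("simulation results are on different time grids")
    err = {"soma": float(np.max(np.abs(a.v_soma - b.v_soma)))}
    deltas, mism = _paired_deltas(a.soma_spikes, b.soma_spikes)
    spike_deltas = {"soma": deltas}
    if a.v_dend is not None and b.v_dend is not None:
        err["dend"] = float(np.max(np.abs(a.v_dend - b.v_dend)))
        d2, m2 = _paired_deltas(a.dcaap_onsets, b.dcaap_onsets)
        spike_deltas["dend"] = d2
        mism = mism or m2
    return ComparisonReport(
        max_abs_voltage_error=err,
        spike_deltas=spike_deltas,
        spike_count_mismatch=mism,
        meta={"modes": (a.metadata, b.metadata)},
    )


def current_sweep(
    model: str = "single",
    params: NeuronParameters | None = None,
    currents=DEFAULT_SWEEP_CURRENTS,
    stim_duration: float = 2000.0,
    compartment: str = "soma",
    mode_a: tuple[str, str] = ("fixed", "lut"),
    mode_b: tuple[str, str] = ("double", "lut"),
    lut_step: float = 1.0,
) -> list[ComparisonReport]:
    """Run each constant-current protocol under two (arithmetic, gating)
    mode pairs and compare; one report per current."""
    params = params or NeuronParameters()
    reports = []
    for i_nA in currents:
        proto = constant_current_protocol(
            float(i_nA), compartment=compartment, stim_duration=stim_duration
        )
        ra = run_protocol(
            model, params, proto, arithmetic=mode_a[0], gating=mode_a[1],
            lut_step=lut_step,
        )
        rb = run_protocol(
            model, params, proto, arithmetic=mode_b[0], gating=mode_b[1],
            lut_step=lut_step,
        )
        rep = compare_traces(ra, rb)
        rep.meta["current_nA"] = float(i_nA)
        rep.meta["mode_a"] = mode_a
        rep.meta["mode_b"] = mode_b
        reports.append(rep)
    return reports


def lut_resolution_study(
    params: NeuronParameters | None = None,
    protocol: StimulusProtocol | None = None,
    arithmetic: str = "fixed",
    steps: tuple[float, ...] = (2.0, 1.0),
) -> dict[str, float]:
    """Whole-run max voltage error of the no-LUT path and of each table
    resolution against the double-precision direct reference, on the 3 nA
    somatic protocol by default."""
    params = params or NeuronParameters()
    protocol = protocol or constant_current_protocol(3.0)
    ref = run_protocol("single", params, protocol, arithmetic="double",
                       gating="direct")
    out: dict[str, float] = {}
    r = run_protocol("single", params, protocol, arithmetic=arithmetic,
                     gating="direct")
    out["no-lut"] = compare_traces(r, ref).max_abs_voltage_error["soma"]
    for step in steps:
        r = run_protocol("single", params, protocol, arithmetic=arithmetic,
                         gating="lut", lut_step=step)
        out[f"{step:g}mV"] = compare_traces(r, ref).max_abs_voltage_error["soma"]
    return out


def serialize_reports(reports: list[ComparisonReport]) -> str:
    """One text record per comparison (current, modes, errors, deltas)."""
    buf = io.StringIO()
    for rep in reports:
        cur = rep.meta.get("current_nA")
        buf.write(f"current_nA\t{cur}\n")
        buf.write(f"mode_a\t{rep.meta.get('mode_a')}\n")
        buf.write(f"mode_b\t{rep.meta.get('mode_b')}\n")
        for comp, err in rep.max_abs_voltage_error.items():
            buf.write(f"max_abs_voltage_error_mV\t{comp}\t{err!r}\n")
        for comp, d in rep.spike_deltas.items():
            mx = float(np.max(d)) if len(d) else 0.0
            buf.write(f"spike_delta_max_ms\t{comp}\t{mx!r}\t(n={len(d)})\n")
        buf.write(f"spike_count_mismatch\t{rep.spike_count_mismatch}\n")
        buf.write("\n")
    return buf.getvalue()
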