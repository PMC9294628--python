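"""Lookup tables replacing runtime exponentials and divisions.

Two kinds of tables are built:

* voltage-indexed gating tables holding, at 1 mV nodes between -100 and
  +100 mV (the conventional grid), the gate steady states n_inf/m_inf/h_inf
  and the per-step decay factors exp(-dt/tau_x); queried with linear
  interpolation and clamped at the grid ends;
* a time-indexed table of the dCaAP rise/decay waveform A - B at the
  simulation resolution, truncated where the waveform falls below 1e-6 and
  queried by flooring to the grid (the offset from activation is always an
  exact multiple of dt, so no interpolation is needed).

The decay factors are stored as exp(-dt/tau), the stable exponential-Euler
form.  Node values always equal direct evaluation of the tabulated function
in the arithmetic mode the table was quantized for.
"""

from __future__ import annotations

import ast
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dcaap import DCaAPParameters, ab_waveform
from .errors import ConfigurationError, InvalidInputError
from .model_core import GatingState, gating_equilibrium

__all__ = [
    "LookupTable",
    "build_gating_tables",
    "build_ab_table",
    "lookup",
    "gated_step_with_lut",
]

GATING_COLUMNS = ("n_inf", "m_inf", "h_inf", "expfac_n", "expfac_m", "expfac_h")


@dataclass
class LookupTable:
    """Gridded precomputed function values with an interpolation contract.

    ``interpolation`` is "linear" (with clamping outside the domain) or
    "nearest" (floor to the grid, value 0 beyond the last node -- the
    convention of the time-indexed waveform table).  ``meta`` records how the
    table was built (e.g. the timestep baked into decay factors).
    """

    domain_min: float
    domain_max: float
    step: float
    columns: dict[str, np.ndarray]
    interpolation: str = "linear"
    out_of_range: str = "clamp"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigurationError("grid step must be positive")
        span = (self.domain_max - self.domain_min) / self.step
        if abs(span - round(span)) > 1e-9:
            raise ConfigurationError("domain is not an integral number of steps")
        n = self.n_nodes
        for name, col in self.columns.items():
            if len(col) != n:
                raise ConfigurationError(
                    f"column {name!r} has {len(col)} entries, expected {n}"
                )

    @property
    def n_nodes(self) -> int:
        return int(round((self.domain_max - self.domain_min) / self.step)) + 1

    def nodes(self) -> np.ndarray:
        return self.domain_min + self.step * np.arange(self.n_nodes)

    def quantized(self, frac_quantizer) -> "LookupTable":
        """New table with every node value passed through a quantizer
        (all tabulated quantities here live in [0, 1))."""
        cols = {
            k: np.array([frac_quantizer(float(v)) for v in col])
            for k, col in self.columns.items()
        }
        return replace(self, columns=cols)

    # -- simple columnar text round-trip for inspection and fixtures --------

    def to_text(self) -> str:
        buf = io.StringIO()
        names = sorted(self.columns)
        buf.write(f"# domain_min={self.domain_min!r} domain_max={self.domain_max!r} "
                  f"step={self.step!r} interpolation={self.interpolation}\n")
        for key in sorted(self.meta):
            buf.write(f"# meta {key}={self.meta[key]!r}\n")
        buf.write("node\t" + "\t".join(names) + "\n")
        for i, x in enumerate(self.nodes()):
            row = "\t".join(repr(float(self.columns[c][i])) for c in names)
            buf.write(f"{float(x)!r}\t{row}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "LookupTable":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0]
        if not header.startswith("#"):
            raise ConfigurationError("missing table header line")
        fields = dict(
            tok.split("=", 1) for tok in header[1:].split() if "=" in tok
        )
        meta = {}
        k = 1
        while lines[k].startswith("# meta "):
            key, val = lines[k][len("# meta "):].split("=", 1)
            try:
                meta[key] = ast.literal_eval(val)
            except (ValueError, SyntaxError):
                meta[key] = val
            k += 1
        names = lines[k].split("\t")[1:]
        rows = [ln.split("\t") for ln in lines[k + 1:]]
        cols = {
            nm: np.array([float(r[i + 1]) for r in rows]) for i, nm in enumerate(names)
        }
        return cls(
            domain_min=float(fields["domain_min"]),
            domain_max=float(fields["domain_max"]),
            step=float(fields["step"]),
            columns=cols,
            interpolation=fields.get("interpolation", "linear"),
            meta=meta,
        )


def build_gating_tables(
    v_min: float = -100.0,
    v_max: float = 100.0,
    step: float = 1.0,
    dt: float = 0.1,
) -> LookupTable:
    """Tabulate x_inf and exp(-dt/tau_x) for the three gates on a voltage
    grid; 1 mV steps between -100 and +100 mV by default (201 nodes)."""
    if step <= 0:
        raise ConfigurationError("grid step must be positive")
    if not v_min < v_max:
        raise ConfigurationError("v_min must be below v_max")
    n = int(round((v_max - v_min) / step)) + 1
    cols = {name: np.empty(n) for name in GATING_COLUMNS}
    for i in range(n):
        v = v_min + i * step
        eq = gating_equilibrium(v)
        cols["n_inf"][i] = eq.n_inf
        cols["m_inf"][i] = eq.m_inf
        cols["h_inf"][i] = eq.h_inf
        cols["expfac_n"][i] = math.exp(-dt / eq.tau_n)
        cols["expfac_m"][i] = math.exp(-dt / eq.tau_m)
        cols["expfac_h"][i] = math.exp(-dt / eq.tau_h)
    return LookupTable(
        domain_min=v_min,
        domain_max=v_max,
        step=step,
        columns=cols,
        interpolation="linear",
        meta={"dt": dt, "kind": "gating"},
    )


def build_ab_table(
    dt_res: float = 0.1,
    p: DCaAPParameters | None = None,
    floor: float = 1e-6,
) -> LookupTable:
    """Tabulate the A - B waveform from t - t' = 0 at ``dt_res`` resolution,
    truncated at the first node past the peak where the value drops below
    ``floor`` (the waveform is treated as 0 beyond the table)."""
    if dt_res <= 0:
        raise ConfigurationError("table resolution must be positive")
    p = p or DCaAPParameters()
    vals = []
    i = 0
    while True:
        t = i * dt_res  # exact node abscissa, no accumulated float drift
        w = ab_waveform(t, p)
        if t > p.delta_t_prime and w < floor:
            break
        vals.append(w)
        i += 1
        if t > 10000.0:  # safety: waveform must decay
            raise ConfigurationError("A-B waveform did not decay below floor")
    return LookupTable(
        domain_min=0.0,
        domain_max=dt_res * (len(vals) - 1),
        step=dt_res,
        columns={"ab": np.array(vals)},
        interpolation="nearest",
        meta={"dt": dt_res, "kind": "ab", "floor": floor},
    )


def lookup(table: LookupTable, x: float) -> dict[str, float]:
    """Query every column at ``x``.

    Linear tables interpolate between the bracketing nodes and clamp outside
    the domain; nearest tables floor to the grid and return 0 beyond the last
    node.
    """
    if table.interpolation == "nearest":
        i = math.floor((x - table.domain_min) / table.step + 1e-12)
        out = {}
        for name, col in table.columns.items():
            if i < 0:
                out[name] = float(col[0])
            elif i >= len(col):
                out[name] = 0.0
            else:
                out[name] = float(col[i])
        return out
    u = (x - table.domain_min) / table.step
    n = table.n_nodes
    i = int(math.floor(u))
    if i < 0:
        i, frac = 0, 0.0
    elif i >= n - 1:
        i, frac = n - 2, 1.0
    else:
        frac = u - i
    out = {}
    for name, col in table.columns.items():
        v0 = float(col[i])
        v1 = float(col[i + 1])
        out[name] = v0 + frac * (v1 - v0)
    return out


def gated_step_with_lut(
    gates: GatingState, v: float, table: LookupTable, dt: float
) -> GatingState:
    """Advance all three gates one step using interpolated table values:
    x' = x_inf + (x - x_inf) * expfac_x, evaluated in the product form
    x_inf*(1 - expfac) + x*expfac (identical algebraically; it keeps the
    whole update inside the [0,1) number range)."""
    if abs(table.meta.get("dt", -1.0) - dt) > 1e-12:
        raise ConfigurationError(
            f"table was built for dt={table.meta.get('dt')}, not dt={dt}"
        )
    vals = lookup(table, v)
    out = {}
    for gate in ("n", "m", "h"):
        x = getattr(gates, gate)
        xi = vals[f"{gate}_inf"]
        ef = vals[f"expfac_{gate}"]
        out[gate] = xi * (1.0 - ef) + x * ef
    return GatingState(m=out["m"], h=out["h"], n=out["n"])
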