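"""Result serialization: delimited-text traces, spike lists and comparison
reports.  Identical runs produce byte-identical files (floats are written
with repr, which round-trips)."""

from __future__ import annotations

import os

from .errors import PyramidalError
from .solver import SimulationResult
from .validation import ComparisonReport, serialize_reports

__all__ = ["write_results"]


def write_results(
    result: SimulationResult,
    report: ComparisonReport | None = None,
    outdir: str = "results",
) -> list[str]:
    """Write traces.tsv, spikes.txt and (optionally) report.txt under
    ``outdir``; returns the list of paths written."""
    try:
        os.makedirs(outdir, exist_ok=True)
    except OSError as exc:
        raise PyramidalError(f"cannot create output directory {outdir}: {exc}")

    written = []

    cols = [("time_ms", result.time), ("v_soma_mV", result.v_soma)]
    if result.v_dend is not None:
        cols.append(("v_dend_mV", result.v_dend))
    if result.gates:
        for name in ("m", "h", "n"):
            cols.append((f"gate_{name}", result.gates[name]))
    path = os.path.join(outdir, "traces.tsv")
    with open(path, "w") as fh:
        fh.write("\t".join(name for name, _ in cols) + "\n")
        n = len(result.time)
        for i in range(n):
            fh.write("\t".join(repr(float(col[i])) for _, col in cols) + "\n")
    written.append(path)

    path = os.path.join(outdir, "spikes.txt")
    with open(path, "w") as fh:
        fh.write("# somatic spike times (ms)\n")
        for t in result.soma_spikes:
            fh.write(f"{float(t)!r}\n")
        if result.v_dend is not None:
            fh.write("# dCaAP onset times (ms)\n")
            for t in result.dcaap_onsets:
                fh.write(f"{float(t)!r}\n")
    written.append(path)

    path = os.path.join(outdir, "metadata.txt")
    with open(path, "w") as fh:
        for key in sorted(result.metadata):
            fh.write(f"{key}\t{result.metadata[key]!r}\n")
    written.append(path)

    if report is not None:
        path = os.path.join(outdir, "report.txt")
        with open(path, "w") as fh:
            fh.write(serialize_reports([report]))
        written.append(path)
    return written
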