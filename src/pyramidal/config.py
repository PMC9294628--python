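"""YAML run-configuration parsing with schema validation.

The configuration mirrors the library objects: model selection, arithmetic
and gating modes, neuron parameter overrides and the stimulus protocol.
Unknown keys are rejected by name; omitted keys fall back to the model's
default parameter values (dt = 0.1 ms, spike threshold -20 mV, published
channel constants, calibrated geometry).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .dcaap import DCaAPParameters
from .errors import ConfigurationError
from .model_core import HHChannelParameters, SynapseParameters
from .solver import (
    GeometryParameters,
    NeuronParameters,
    SPIKE_THRESHOLD,
    StimulusProtocol,
    SynapseGroup,
    Waveform,
)

__all__ = ["RunConfiguration", "parse_config"]

log = logging.getLogger("pyramidal")

_PARAM_SECTIONS = {
    "hh": HHChannelParameters,
    "dcaap": DCaAPParameters,
    "synapse": SynapseParameters,
    "geometry": GeometryParameters,
}


@dataclass
class RunConfiguration:
    model: str = "single"
    arithmetic: str = "double"
    gating: str = "direct"
    lut_step: float = 1.0
    dt: float = 0.1
    threshold: float = SPIKE_THRESHOLD
    record_gates: bool = False
    output_dir: str = "results"
    verbosity: str = "info"
    params: NeuronParameters = field(default_factory=NeuronParameters)
    protocol: StimulusProtocol | None = None

    def effective_protocol(self) -> StimulusProtocol:
        if self.protocol is not None:
            return self.protocol
        # canonical default run: 3 nA somatic step for 2 s after settling
        return StimulusProtocol(
            duration=2100.0,
            dt=self.dt,
            soma_current=Waveform.constant(3.0, 100.0, 2100.0),
        )


def _check_keys(section: dict, allowed, where: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigurationError(f"unknown key {key!r} in {where}")


def _build_params(section: dict) -> NeuronParameters:
    _check_keys(section, _PARAM_SECTIONS, "parameters")
    kwargs = {}
    for name, cls in _PARAM_SECTIONS.items():
        sub = section.get(name, {})
        if not isinstance(sub, dict):
            raise ConfigurationError(f"parameters.{name} must be a mapping")
        fields = {f.name for f in dataclasses.fields(cls)}
        _check_keys(sub, fields, f"parameters.{name}")
        kwargs[name] = cls(**sub)
    return NeuronParameters(**kwargs)


def _build_waveform(spec, where: str) -> Waveform:
    if isinstance(spec, dict):
        _check_keys(spec, {"kind", "amplitude", "t0", "t1", "v0", "v1"}, where)
        kind = spec.get("kind", "constant")
        if kind == "constant":
            return Waveform.constant(
                float(spec["amplitude"]), float(spec["t0"]), float(spec["t1"])
            )
        if kind == "ramp":
            return Waveform.ramp(
                float(spec["t0"]), float(spec["t1"]),
                float(spec.get("v0", 0.0)), float(spec["v1"]),
            )
        raise ConfigurationError(f"unknown waveform kind {kind!r} in {where}")
    if isinstance(spec, list):
        segs = []
        for i, seg in enumerate(spec):
            _check_keys(seg, {"t0", "t1", "v0", "v1"}, f"{where}[{i}]")
            segs.append(
                (float(seg["t0"]), float(seg["t1"]),
                 float(seg["v0"]), float(seg.get("v1", seg["v0"])))
            )
        return Waveform(segs)
    raise ConfigurationError(f"{where} must be a mapping or a list of segments")


def _build_synapses(spec, where: str) -> tuple[SynapseGroup, ...]:
    if not isinstance(spec, list):
        raise ConfigurationError(f"{where} must be a list of synapse groups")
    groups = []
    for i, grp in enumerate(spec):
        _check_keys(grp, {"events", "n"}, f"{where}[{i}]")
        groups.append(
            SynapseGroup(events=tuple(float(t) for t in grp["events"]),
                         n=int(grp.get("n", 1)))
        )
    return tuple(groups)


def _build_protocol(section: dict, dt: float) -> StimulusProtocol:
    allowed = {
        "duration", "dt", "soma_current", "dend_current",
        "soma_synapses", "dend_synapses",
    }
    _check_keys(section, allowed, "protocol")
    if "duration" not in section:
        raise ConfigurationError("protocol requires a duration")
    kwargs = {
        "duration": float(section["duration"]),
        "dt": float(section.get("dt", dt)),
    }
    for side in ("soma", "dend"):
        cur = section.get(f"{side}_current")
        if cur is not None:
            kwargs[f"{side}_current"] = _build_waveform(cur, f"protocol.{side}_current")
        syn = section.get(f"{side}_synapses")
        if syn is not None:
            kwargs[f"{side}_synapses"] = _build_synapses(syn, f"protocol.{side}_synapses")
    return StimulusProtocol(**kwargs)


def parse_config(document: str | dict | None) -> RunConfiguration:
    """Parse and validate a YAML configuration document (text or mapping).

    Raises ConfigurationError naming the offending key on schema violations;
    echoes the effective configuration to the package logger.
    """
    if document is None:
        raw: dict = {}
    elif isinstance(document, str):
        raw = yaml.safe_load(document) or {}
    else:
        raw = dict(document)
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")

    allowed = {
        "model", "arithmetic", "gating", "lut_step", "dt", "threshold",
        "record_gates", "output_dir", "verbosity", "parameters", "protocol",
    }
    _check_keys(raw, allowed, "configuration")

    cfg = RunConfiguration()
    for key in ("model", "arithmetic", "gating", "output_dir", "verbosity"):
        if key in raw:
            setattr(cfg, key, str(raw[key]))
    if cfg.model not in ("single", "two"):
        raise ConfigurationError(f"model must be 'single' or 'two', got {cfg.model!r}")
    if cfg.arithmetic not in ("double", "fixed"):
        raise ConfigurationError(
            f"arithmetic must be 'double' or 'fixed', got {cfg.arithmetic!r}"
        )
    if cfg.gating not in ("direct", "lut"):
        raise ConfigurationError(f"gating must be 'direct' or 'lut', got {cfg.gating!r}")
    for key in ("lut_step", "dt", "threshold"):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    if cfg.dt <= 0:
        raise ConfigurationError("dt must be positive")
    if cfg.lut_step <= 0:
        raise ConfigurationError("lut_step must be positive")
    if "record_gates" in raw:
        cfg.record_gates = bool(raw["record_gates"])
    if "parameters" in raw:
        cfg.params = _build_params(raw["parameters"] or {})
    if "protocol" in raw:
        cfg.protocol = _build_protocol(raw["protocol"] or {}, cfg.dt)

    log.info("effective configuration: %s", cfg)
    return cfg
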