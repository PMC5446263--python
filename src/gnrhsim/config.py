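"""Run configuration: validated YAML/JSON in, dataclasses out.

A run file selects a model (``minimal`` or ``network``), a pulse
protocol, optional parameter overrides, scan axes, a gate spec and a
population spec.  Unknown keys are rejected with every offending key
named, and each loaded configuration carries a provenance block (a
stable hash of its normalized content plus solver tolerances) that the
writers embed in output headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._ode import DEFAULT_ATOL, DEFAULT_RTOL
from .gates import GateSpec
from .infotheory import PopulationSpec
from .minimal import EffectorKinetics, MinimalParams
from .network import NetworkParams
from .pulses import PulseProtocol

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]

_PROTOCOL_KEYS = {"amplitude_M", "width_min", "period_min", "horizon_min",
                  "baseline_M"}


class ConfigError(ValueError):
    """Raised on parse or validation failure; lists every offending key."""


@dataclass
class RunConfig:
    model: str = "network"
    protocol: PulseProtocol = field(default_factory=lambda: PulseProtocol(
        amplitude=1e-7, width=5.0, period=60.0, horizon=960.0))
    minimal_params: MinimalParams = field(default_factory=MinimalParams)
    network_params: NetworkParams = field(default_factory=NetworkParams)
    gate: GateSpec = field(default_factory=GateSpec)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    scan_periods: tuple[float, ...] = (5.0, 15.0, 30.0, 60.0, 120.0, 240.0, 480.0)
    scan_concentrations: tuple[float, ...] = (
        1e-11, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)
    seed: int = 0
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def provenance(self) -> dict:
        """Stable provenance block for output headers."""
        return {
            "config_sha256": self.digest(),
            "seed": self.seed,
            "rtol": self.rtol,
            "atol": self.atol,
            "model": self.model,
        }

    def digest(self) -> str:
        blob = json.dumps(dump_config(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _protocol_from_dict(raw: dict, errors: list[str]) -> PulseProtocol | None:
    unknown = set(raw) - _PROTOCOL_KEYS
    for key in sorted(unknown):
        errors.append(f"protocol: unknown key {key!r}")
    try:
        return PulseProtocol(
            amplitude=float(raw.get("amplitude_M", 1e-7)),
            width=float(raw.get("width_min", 5.0)),
            period=float(raw.get("period_min", 60.0)),
            horizon=float(raw.get("horizon_min", 960.0)),
            baseline=float(raw.get("baseline_M", 0.0)),
        )
    except (TypeError, ValueError) as exc:
        errors.append(f"protocol: {exc}")
        return None


def _params_from_dict(cls, raw: dict, label: str, errors: list[str]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    for key in sorted(unknown):
        errors.append(f"{label}: unknown key {key!r}")
    kwargs = {k: v for k, v in raw.items() if k in names}
    if cls is MinimalParams:
        for eff in ("e1", "e2", "e3"):
            if eff in kwargs and isinstance(kwargs[eff], dict):
                kwargs[eff] = EffectorKinetics(**kwargs[eff])
    if cls is PopulationSpec:
        for tup in ("stimulus_levels",):
            if tup in kwargs:
                kwargs[tup] = tuple(float(v) for v in kwargs[tup])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{label}: {exc}")
        return None


def load_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML/JSON run file (or a pre-parsed dict).

    All defaults are filled; on failure a :class:`ConfigError` listing
    every offending key is raised.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {source}: {exc}") from exc
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("run configuration must be a mapping")

    known = {"model", "protocol", "minimal_params", "network_params",
             "gate", "population", "scan_periods", "scan_concentrations",
             "seed", "rtol", "atol"}
    errors = [f"unknown top-level key {k!r}" for k in sorted(set(raw) - known)]

    model = raw.get("model", "network")
    if model not in ("minimal", "network"):
        errors.append(f"model must be 'minimal' or 'network', got {model!r}")

    protocol = _protocol_from_dict(raw.get("protocol", {}) or {}, errors)
    minimal = _params_from_dict(
        MinimalParams, raw.get("minimal_params", {}) or {}, "minimal_params",
        errors)
    network = _params_from_dict(
        NetworkParams, raw.get("network_params", {}) or {}, "network_params",
        errors)
    gate = _params_from_dict(GateSpec, raw.get("gate", {}) or {}, "gate", errors)
    population = _params_from_dict(
        PopulationSpec, raw.get("population", {}) or {}, "population", errors)

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    return RunConfig(
        model=model,
        protocol=protocol,
        minimal_params=minimal,
        network_params=network,
        gate=gate,
        population=population,
        scan_periods=tuple(float(v) for v in raw.get(
            "scan_periods", RunConfig.scan_periods)),
        scan_concentrations=tuple(float(v) for v in raw.get(
            "scan_concentrations", RunConfig.scan_concentrations)),
        seed=int(raw.get("seed", 0)),
        rtol=float(raw.get("rtol", DEFAULT_RTOL)),
        atol=float(raw.get("atol", DEFAULT_ATOL)),
    )


def dump_config(cfg: RunConfig) -> dict:
    """Round-trippable plain-dict form of a configuration."""
    proto = cfg.protocol
    return {
        "model": cfg.model,
        "protocol": {
            "amplitude_M": proto.amplitude,
            "width_min": proto.width,
            "period_min": proto.period,
            "horizon_min": proto.horizon,
            "baseline_M": proto.baseline,
        },
        "minimal_params": {
            eff: dataclasses.asdict(getattr(cfg.minimal_params, eff))
            for eff in ("e1", "e2", "e3")
        },
        "network_params": dataclasses.asdict(cfg.network_params),
        "gate": {**dataclasses.asdict(cfg.gate), "mode": cfg.gate.mode.value},
        "population": dataclasses.asdict(cfg.population),
        "scan_periods": list(cfg.scan_periods),
        "scan_concentrations": list(cfg.scan_concentrations),
        "seed": cfg.seed,
        "rtol": cfg.rtol,
        "atol": cfg.atol,
    }
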