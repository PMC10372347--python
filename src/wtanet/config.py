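"""Run configuration files and run manifests.

Configs are YAML or JSON mappings mirroring :class:`wtanet.protocol.TrialConfig`;
every omitted key falls back to the model's default constants, every present
key is validated against the type invariants, and unknown keys are rejected
with the offending name.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
from dataclasses import dataclass, field

import yaml

from .params import ConductanceRow, ConductanceTable, NeuronParams, SynapseParams
from .protocol import StimulusProtocol, TrialConfig

__all__ = ["load_config", "config_to_dict", "RunManifest"]

_NESTED = {
    "stimulus": StimulusProtocol,
    "pyramidal": NeuronParams,
    "interneuron": NeuronParams,
    "synapses": SynapseParams,
}


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}; valid keys: {sorted(valid)}")
    return data


def _build_conductances(data: dict) -> ConductanceTable:
    _build(ConductanceTable, data, "conductances")
    kwargs = {}
    for cls_name in ("pyramidal", "interneuron"):
        if cls_name in data:
            row = _build(ConductanceRow, data[cls_name], f"conductances.{cls_name}")
            default = getattr(ConductanceTable(), cls_name)
            merged = {f.name: row.get(f.name, getattr(default, f.name))
                      for f in dataclasses.fields(ConductanceRow)}
            kwargs[cls_name] = ConductanceRow(**merged)
    return ConductanceTable(**kwargs)


def load_config(path) -> TrialConfig:
    """Load and validate a trial configuration from a YAML or JSON file.

    An empty file yields the complete default configuration.  Raises
    ValueError naming the key for unknown keys, and propagates the dataclass
    invariant errors (e.g. negative time constants) for bad values.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> TrialConfig:
    """Build a validated TrialConfig from a (possibly partial) mapping."""
    _build(TrialConfig, data, "config")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED:
            cls = _NESTED[key]
            sub = _build(cls, value, key)
            default = getattr(TrialConfig(), key)
            merged = {f.name: sub.get(f.name, getattr(default, f.name))
                      for f in dataclasses.fields(cls)}
            kwargs[key] = cls(**merged)
        elif key == "conductances":
            kwargs[key] = _build_conductances(value)
        else:
            kwargs[key] = value
    return TrialConfig(**kwargs)


def config_to_dict(cfg: TrialConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(getattr(obj, k)) for k in obj.__dataclass_fields__}
        return obj
    return enc(cfg)


@dataclass
class RunManifest:
    """Record of one experiment run, sufficient to reproduce it."""

    config_digest: str
    base_seed: int
    trial_seeds: list
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""
    software_version: str = ""
    config: dict = field(default_factory=dict)

    @classmethod
    def begin(cls, cfg: TrialConfig, base_seed: int) -> "RunManifest":
        from . import __version__
        return cls(config_digest=cfg.digest(), base_seed=base_seed, trial_seeds=[],
                   started=datetime.datetime.now().isoformat(),
                   software_version=__version__, config=config_to_dict(cfg))

    def finish(self) -> None:
        self.finished = datetime.datetime.now().isoformat()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def verify(self, base_dir=".") -> None:
        """Check the stored config digest and the existence of listed outputs."""
        cfg = config_from_dict(self.config)
        if cfg.digest() != self.config_digest:
            raise ValueError("config digest mismatch: manifest was edited or config schema changed")
        missing = [p for p in self.outputs
                   if not os.path.exists(os.path.join(base_dir, p))]
        if missing:
            raise FileNotFoundError(f"missing outputs: {missing}")
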