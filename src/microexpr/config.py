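"""Run configuration: YAML file + CLI overrides resolved into one object.

A run config nests the per-stage configs under sections ``evm``, ``flow``,
``train``, ``synth`` and ``model``; every stochastic stage derives its
seed from the single run ``seed`` so two runs with identical configs
produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .evm import EvmConfig
from .fixtures import SynthConfig
from .flow import FlowConfig
from .model import ArchitectureSpec
from .train import TrainConfig

_SECTIONS = {
    "evm": EvmConfig,
    "flow": FlowConfig,
    "train": TrainConfig,
    "synth": SynthConfig,
    "model": ArchitectureSpec,
}

_TOP_LEVEL = {"seed", "log_level"}


@dataclass
class RunConfig:
    evm: EvmConfig = field(default_factory=EvmConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    model: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # one run seed drives every stage
        self.train.seed = self.seed
        self.synth.seed = self.seed

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "log_level": self.log_level}
        for name in _SECTIONS:
            section = getattr(self, name)
            out[name] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(section).items()
            }
        return out

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _build_section(cls, values: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(
            f"unknown keys in section {section!r}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in values:
            continue
        v = values[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; ``overrides`` maps dotted keys
    (``"train.lambda_da"`` or top-level ``"seed"``) onto replacement
    values.  Unknown keys raise :class:`ConfigError` listing them."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        raw = loaded

    unknown = set(raw) - set(_SECTIONS) - _TOP_LEVEL
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    for key, value in (overrides or {}).items():
        if key in _TOP_LEVEL:
            raw[key] = value
            continue
        if "." not in key:
            raise ConfigError(f"unknown override key: {key!r}")
        section, name = key.split(".", 1)
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section: {section!r}")
        raw.setdefault(section, {})[name] = value

    kwargs = {}
    for name, cls in _SECTIONS.items():
        section_values = raw.get(name, {})
        if not isinstance(section_values, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section_values, name)
    return RunConfig(seed=int(raw.get("seed", 0)),
                     log_level=str(raw.get("log_level", "INFO")), **kwargs)
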