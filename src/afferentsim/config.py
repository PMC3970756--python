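"""Run configuration: schema-validated YAML/JSON round-tripping.

A :class:`RunConfig` aggregates the model parameterization, the
stimulus protocol and per-command analysis options, all defaulting to
the reference values used throughout the package.  Unknown keys are
rejected with the offending key path, and every artifact written by the
CLI embeds the short hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model_core import CellModel
from .simulate import StimulusProtocol

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_PROTOCOL_KEYS = {"T_total", "dt", "I_hold", "steps", "record_dt"}
_SECTION_KEYS = {
    "bifurcate": {"I_range", "n_samples", "simulate_cycles"},
    "map": {"gNa_grid", "gK_grid", "I_range", "context_overrides", "refine_boundary"},
    "classify": {"I_hold", "duration", "ladder", "I_max", "dt"},
    "predict": {"classifier", "magnitudes"},
    "cohort": {
        "kind", "n_cells", "cv", "injury", "classifier", "titrate",
    },
    "stats": {"table", "counts", "sidedness", "test"},
}
_TOP_KEYS = {"model", "protocol", "seed"} | set(_SECTION_KEYS)


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """Full configuration of one CLI run."""

    model: dict = field(default_factory=lambda: CellModel().to_dict())
    protocol: dict = field(
        default_factory=lambda: {"T_total": 1200.0, "dt": 0.02,
                                 "I_hold": 0.0, "steps": [], "record_dt": 0.05}
    )
    seed: int = 0
    sections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.build_model()  # validates model block
        bad = set(self.protocol) - _PROTOCOL_KEYS
        if bad:
            raise ConfigError(f"unknown protocol keys: {sorted(bad)}")
        for name, opts in self.sections.items():
            if name not in _SECTION_KEYS:
                raise ConfigError(f"unknown section {name!r}")
            bad = set(opts) - _SECTION_KEYS[name]
            if bad:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")

    def build_model(self) -> CellModel:
        try:
            return CellModel.from_dict(self.model)
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"invalid model block: {exc}") from exc

    def build_protocol(self, **overrides) -> StimulusProtocol:
        kw = {**self.protocol, **overrides}
        kw["steps"] = tuple(tuple(s) for s in kw.get("steps", ()))
        return StimulusProtocol(**kw)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def to_dict(self) -> dict:
        d = {"model": self.model, "protocol": self.protocol, "seed": self.seed}
        d.update(self.sections)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        bad = set(d) - _TOP_KEYS
        if bad:
            raise ConfigError(f"unknown top-level keys: {sorted(bad)}")
        sections = {k: v for k, v in d.items() if k in _SECTION_KEYS}
        kw = {}
        for k in ("model", "protocol", "seed"):
            if k in d:
                kw[k] = d[k]
        return cls(sections=sections, **kw)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical JSON form."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    # JSON round trip coerces numpy scalars/arrays to plain Python types
    data = json.loads(json.dumps(cfg.to_dict(), default=float))
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=2)
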