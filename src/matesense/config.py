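"""Run configuration: YAML/TOML parsing, validation and provenance records.

A run config has a flat top level (subcommand, seed, output directory,
verbosity) plus one optional section per model component.  Unknown keys are
rejected rather than ignored, so typos fail loudly.  Every CLI run writes a
provenance record (the config echo, package version and seed) next to its
outputs.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "dump_config", "write_provenance"]

_SECTIONS = ("communication", "dose_response", "encounter", "fitness",
             "synthetic", "stats")
_TOP_KEYS = {"subcommand", "seed", "out_dir", "verbosity", *_SECTIONS}


@dataclass
class RunConfig:
    subcommand: str = ""
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1
    communication: dict = field(default_factory=dict)
    dose_response: dict = field(default_factory=dict)
    encounter: dict = field(default_factory=dict)
    fitness: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section in _SECTIONS:
            if section in data and not isinstance(data[section], dict):
                raise ValueError(f"config section {section!r} must be a mapping")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or TOML, by extension) config file."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def write_provenance(out_dir: str | Path, config: RunConfig) -> Path:
    """Write the provenance record (config + version + seed) for a run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"package": "matesense", "version": __version__,
              "seed": config.seed, "config": config.to_dict()}
    path = out_dir / "provenance.yaml"
    path.write_text(yaml.safe_dump(record, sort_keys=False))
    return path
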