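"""Run manifests and configuration loading for the command-line layer."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunManifest", "load_config", "ConfigError", "config_hash"]


class ConfigError(ValueError):
    """Configuration file is missing, malformed, or has unknown keys."""


#: allowed keys per config section for the `simulate` command
_SIMULATE_SCHEMA = {
    "geometry": {"kind", "H", "R", "membrane_thickness", "probe_points", "rim_height"},
    "material": {"E", "nu", "D", "membrane"},
    "bcs": {"bottom_mech", "drained_traction"},
    "load": {"P_eff", "t_r"},
    "solver": {
        "constitutive", "end_time", "dt_init", "adaptive", "growth", "max_dt",
        "nx", "nz", "newton_tol", "newton_max_iter", "n_snapshots", "store_history",
    },
}


def load_config(path, schema: dict | None = None) -> dict:
    """Read a YAML/JSON config document; optionally validate its keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        blob = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(blob, dict):
        raise ConfigError(f"config root must be a mapping, got {type(blob).__name__}")
    if schema is not None:
        validate_config(blob, schema)
    return blob


def validate_config(blob: dict, schema: dict) -> None:
    unknown_sections = set(blob) - set(schema)
    if unknown_sections:
        raise ConfigError(f"unknown config section(s): {sorted(unknown_sections)}")
    for section, keys in schema.items():
        sub = blob.get(section, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = set(sub) - keys
        if bad:
            raise ConfigError(f"unknown key(s) in {section!r}: {sorted(bad)}")


def config_hash(obj) -> str:
    """Stable content hash of a config mapping."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    command: str
    config_hash: str
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    seed: int | None = None
    software_version: str = ""
    started: float = 0.0
    finished: float = 0.0

    @classmethod
    def start(cls, command: str, config, inputs=(), seed=None) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config_hash=config_hash(config),
            inputs=[str(p) for p in inputs],
            seed=seed,
            software_version=__version__,
            started=time.time(),
        )

    def finish(self, outputs, path) -> Path:
        self.outputs = [str(p) for p in outputs]
        self.finished = time.time()
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path
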