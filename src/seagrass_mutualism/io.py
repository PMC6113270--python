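"""Config files, run manifests and output plumbing shared by the CLI.

One flat YAML/JSON config file serves every pipeline stage, with one
section per stage plus a ``parameters`` section holding the model
parameters under their standard symbols.  Unknown keys are rejected
loudly; command-line flags override config values, which override package
defaults.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ModelParameters

__all__ = ["ConfigError", "load_config", "section", "load_parameters", "RunManifest"]

SECTIONS = (
    "parameters", "simulate", "bifurcate", "sensitivity",
    "ensemble", "potential", "synthify", "reproduce",
)


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


def load_config(path: str | Path | None) -> dict:
    """Read the shared config file (YAML or JSON); ``None`` -> empty config."""
    if path is None:
        return {}
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse config {path}: {err}") from err
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping of sections")
    unknown = set(data) - set(SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    return data


def section(config: dict, name: str, allowed: tuple[str, ...]) -> dict:
    """Extract one stage section, rejecting unknown keys."""
    raw = config.get(name, {})
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    unknown = set(raw) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    return dict(raw)


def load_parameters(config: dict) -> ModelParameters:
    """Model parameters from the ``parameters`` section (defaults if absent)."""
    raw = config.get("parameters", {}) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config section 'parameters' must be a mapping")
    try:
        return ModelParameters.from_dict(raw)
    except ValueError as err:
        raise ConfigError(str(err)) from err


def _utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


@dataclass
class RunManifest:
    """Provenance record for one CLI run, written before any stage output."""

    subcommand: str
    seed: int | None
    resolved_config: dict
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    started_utc: str = field(default_factory=_utcnow)
    finished_utc: str | None = None

    def path_in(self, out_dir: Path) -> Path:
        return out_dir / f"{self.subcommand}_manifest.json"

    def write(self, out_dir: Path) -> Path:
        out_dir.mkdir(parents=True, exist_ok=True)
        path = self.path_in(out_dir)
        payload = {
            "subcommand": self.subcommand,
            "seed": self.seed,
            "resolved_config": self.resolved_config,
            "outputs": self.outputs,
            "package_version": self.package_version,
            "started_utc": self.started_utc,
            "finished_utc": self.finished_utc,
        }
        path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
        return path

    def finish(self, out_dir: Path) -> Path:
        self.finished_utc = _utcnow()
        return self.write(out_dir)


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.generic):
            return obj.item()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
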