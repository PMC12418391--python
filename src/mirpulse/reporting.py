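"""Run configuration and standard-format output.

Every shell-level computation is described by a :class:`RunConfig` (a
command name plus its options) read from a YAML or JSON file.  Results are
written as long-format CSV tables with a JSON sidecar carrying everything
needed to re-run: the config itself, its hash, the seed, the solver
settings and the package version.  Identical (config, seed) pairs produce
bitwise-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .errors import ConfigError
from .metrics import FrequencyResponse
from .models import Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_sidecar",
    "write_trajectory",
    "write_frequency_response",
    "write_table",
]


@dataclass(frozen=True)
class RunConfig:
    """A fully serializable description of one run: command + options."""

    command: str
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"command": self.command, "options": self.options}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "command" not in d:
            raise ConfigError("config missing 'command'")
        return cls(command=str(d["command"]), options=dict(d.get("options", {})))


def load_config(path: str | Path, command: str | None = None) -> RunConfig:
    """Load a RunConfig from YAML or JSON.

    The file may either be a full ``{command, options}`` mapping or a bare
    options mapping (then ``command`` must be supplied by the caller).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(data).__name__}")
    if "command" in data:
        cfg = RunConfig.from_dict(data)
        if command is not None and cfg.command != command:
            raise ConfigError(f"config is for command {cfg.command!r}, expected {command!r}")
        return cfg
    if command is None:
        raise ConfigError("bare options config needs an explicit command")
    return RunConfig(command=command, options=data)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_sidecar(path: str | Path, config: RunConfig, seed: int | None = None, **extra) -> None:
    payload = {
        "package": "mirpulse",
        "version": _version,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": seed,
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """CSV with a time column and one column per state component."""
    traj.to_frame().to_csv(path, index=False)


def write_frequency_response(resp: FrequencyResponse, path: str | Path) -> None:
    """CSV with (n, frequency, fr_pulse) rows plus scalar fr_const / tau rows."""
    df = resp.to_frame().astype(object)
    scalars = pd.DataFrame(
        {"n": ["fr_const", "tau"], "frequency": ["", ""], "fr_pulse": [resp.fr_const, resp.tau]}
    )
    pd.concat([df, scalars], ignore_index=True).to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, index=index)
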