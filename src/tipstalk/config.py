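"""Run-configuration loading and validation (YAML).

A config file carries the model parameters under their published names
(``lambda`` for the optimum distance; ``W`` accepts the literal string
``"inf"``) plus optional command-specific options.  Unknown keys are
rejected with the offending key path so typos never silently fall back
to defaults.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import yaml

from .core_model import INFINITE, ModelParams
from .errors import ConfigError, InvalidParameterError

__all__ = ["RunConfig", "load_config", "params_from_mapping", "params_to_mapping"]

SCHEMA_VERSION = 1

#: Model-parameter keys as they appear in config files.
_PARAM_KEYS = {"b0", "K", "kd", "kf0", "h", "lambda", "W", "n_cells", "hill"}
#: Command-specific option keys accepted alongside the parameters.
_OPTION_KEYS = {
    "spacing", "spacings", "seed", "t_end", "tol", "magnitude",
    "K_range", "kf0_range", "n_grid", "schema_version",
}

_REQUIRED = ("b0", "K", "kd", "kf0")


class RunConfig:
    """Validated configuration: model parameters plus extra options."""

    def __init__(self, params: ModelParams, options: dict[str, Any]):
        self.params = params
        self.options = options

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RunConfig(params={self.params!r}, options={self.options!r})"


def _parse_W(value: Any) -> float:
    if isinstance(value, str):
        if value.strip().lower() in {"inf", "infinite", "infinity"}:
            return INFINITE
        raise ConfigError(f"W: string value must be 'inf', got {value!r}")
    w = float(value)
    if math.isnan(w) or w < 0:
        raise ConfigError(f"W: must be >= 0 or 'inf', got {value!r}")
    return w


def params_from_mapping(data: dict[str, Any]) -> ModelParams:
    """Build :class:`ModelParams` from config keys, applying defaults."""
    for key in _REQUIRED:
        if key not in data:
            raise ConfigError(f"missing required parameter {key!r}")
    kwargs = dict(
        b0=data["b0"], K=data["K"], kd=data["kd"], kf0=data["kf0"],
        h=data.get("h", 0.0),
        lam=data.get("lambda", 10.0),
        W=_parse_W(data.get("W", "inf")),
        n_cells=data.get("n_cells", 12),
        hill=data.get("hill", 2.0),
    )
    for key in ("b0", "K", "kd", "kf0", "h", "lam", "hill"):
        try:
            kwargs[key] = float(kwargs[key])
        except (TypeError, ValueError):
            raise ConfigError(f"{key}: expected a number, got {kwargs[key]!r}")
    try:
        kwargs["n_cells"] = int(kwargs["n_cells"])
        return ModelParams(**kwargs)
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameter value: {exc}") from exc


def params_to_mapping(params: ModelParams) -> dict[str, Any]:
    """Inverse of :func:`params_from_mapping` (for sidecar metadata)."""
    return {
        "b0": params.b0, "K": params.K, "kd": params.kd, "kf0": params.kf0,
        "h": params.h, "lambda": params.lam,
        "W": "inf" if math.isinf(params.W) else params.W,
        "n_cells": params.n_cells, "hill": params.hill,
    }


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file.

    Raises :class:`ConfigError` naming the key on any unknown key,
    wrong type or violated invariant; defaults (``h=0``, ``W="inf"``,
    ``n_cells=12``, ``hill=2``) are applied for absent optional keys.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file does not parse as YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _PARAM_KEYS - _OPTION_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    params = params_from_mapping({k: v for k, v in raw.items() if k in _PARAM_KEYS})
    options = {k: v for k, v in raw.items() if k in _OPTION_KEYS}
    options.setdefault("schema_version", SCHEMA_VERSION)
    return RunConfig(params=params, options=options)
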