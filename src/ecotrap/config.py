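"""Structured configuration for sweeps.

One YAML file holds every tunable of the three tiers with the study
defaults baked in; anything the file omits keeps its default, and CLI
flags override the file.  ``load_config(None)`` returns the defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["default_config", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Bad or missing configuration."""


def default_config() -> dict[str, Any]:
    return {
        "grids": {
            "prop_controlled": [round(p / 10, 1) for p in range(1, 10)],
            "mortality": [0.1, 0.5, 0.9],
            "gamma": [0.1, 1.0],
            "sites": ["Mary River", "Macquarie Marshes", "Paroo River"],
        },
        "logistic": {
            "r_m": 0.792,
            "A_total": 1000.0,
            "N0_total": 1000.0,
            "horizon_months": 600,
        },
        "rangeland": {
            "area_total_km2": 1000.0,
            "V0": 295.0,
            "K0_per_km2": 45.0,
            "P0_per_km2": 4.0,
            "horizon_months": 600,
            "rainfall": {"mean_mm": 193.0, "sd_mm": 90.0},
        },
        "shooting": {
            "hours": 7.5,
            "sessions_per_month": 1,
            "scale_with_area": False,
        },
        "sweep": {
            "n_reps": 1000,
            "base_seed": 0,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in out:
            raise ConfigError(f"unknown configuration key: {key!r}")
        if isinstance(out[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: Optional[str]) -> dict[str, Any]:
    """Merge a YAML config file over the defaults.

    Raises :class:`ConfigError` (naming the path) when the file is
    missing or malformed; unknown keys are rejected rather than ignored.
    """
    cfg = default_config()
    if path is None:
        return cfg
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"config file not found: {p}")
    try:
        user = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config file {p}: {exc}") from exc
    if not isinstance(user, dict):
        raise ConfigError(f"config file {p} must contain a mapping")
    return _merge(cfg, user)
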