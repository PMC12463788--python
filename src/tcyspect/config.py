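"""Packaged configuration defaults.

All physics constants (energy windows, collimator geometry, spectrum
sensitivities, phantom layout, dead-time model) ship as a single YAML file so
that every number entering the simulation is declared data, not code.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

_CACHE: dict[str, Any] | None = None


def load_defaults() -> dict[str, Any]:
    """Return a deep copy of the packaged default configuration."""
    global _CACHE
    if _CACHE is None:
        with resources.files("tcyspect.data").joinpath("defaults.yaml").open() as fh:
            _CACHE = yaml.safe_load(fh)
    return copy.deepcopy(_CACHE)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config, overlaying the packaged defaults.

    Top-level sections present in ``path`` replace the corresponding default
    section wholesale; absent sections fall back to the packaged values.
    """
    cfg = load_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                merged = cfg[key]
                merged.update(val)
            else:
                cfg[key] = val
    return cfg
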