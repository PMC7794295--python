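"""YAML run configuration.

Sections (all optional, all overridable on the command line):

    parameters:   free_atom_table: <path>, alpha_scale: <float or {frag: f}>
    damping_mbd:  a, beta
    damping_dcs:  a, beta
    grid:         spacing, padding
    scan:         start, stop, num   (Angstrom)
    seeds:        mc: <int>
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .coulomb import DEFAULT_MC_SEED
from .errors import ValidationError
from .oscillators import DampingParams
from .workflows import MethodSettings

__all__ = ["load_config", "settings_from_config"]

_DEFAULTS: dict[str, dict[str, Any]] = {
    "parameters": {"free_atom_table": None, "alpha_scale": 1.0},
    "damping_mbd": {"a": 6.0, "beta": 0.83},
    "damping_dcs": {"a": 10.12, "beta": 1.4},
    "grid": {"spacing": 0.25, "padding": 6.0},
    "scan": {"start": 4.0, "stop": 12.0, "num": 17},
    "seeds": {"mc": DEFAULT_MC_SEED},
}


def load_config(path: str | Path | None = None) -> dict[str, dict[str, Any]]:
    """Defaults merged (shallow, per section) with a YAML file if given."""
    config = {section: dict(values) for section, values in _DEFAULTS.items()}
    if path is None:
        return config
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise ValidationError(f"config {path} must be a mapping of sections")
    for section, values in loaded.items():
        if section not in config:
            raise ValidationError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValidationError(f"config section {section!r} must be a mapping")
        config[section].update(values)
    return config


def settings_from_config(config: dict[str, dict[str, Any]]) -> MethodSettings:
    return MethodSettings(
        damping_mbd=DampingParams.mbd(**config["damping_mbd"]),
        damping_dcs=DampingParams.dcs(**config["damping_dcs"]),
    )
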