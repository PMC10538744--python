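"""Structured-text (YAML) configuration handling.

A config file is a mapping with optional sections ``model``, ``simulate``,
``sweep`` and ``scenario``. The ``model`` section holds the flat parameter
mapping (keys: kappa, gamma_A, gamma_B, delta_A, delta_B, tau, ell, l_A,
l_B); unknown keys are rejected and a missing tau/ell raises an error that
names the preset values. CLI flags override file values.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model_core import DomainError, ModelParams

__all__ = ["load_config", "load_params", "save_params"]

_SECTIONS = ("model", "simulate", "sweep", "scenario")


def load_config(path: str | Path) -> dict:
    """Load and section-validate a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise DomainError(f"config root must be a mapping, got {type(data)}")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise DomainError(
            f"unknown config sections {sorted(unknown)}; "
            f"expected a subset of {_SECTIONS}")
    return data


def load_params(path: str | Path,
                overrides: dict | None = None) -> ModelParams:
    """Build ModelParams from a config file's model section plus overrides."""
    data = load_config(path)
    model = dict(data.get("model", {}))
    if overrides:
        model.update({k: v for k, v in overrides.items() if v is not None})
    return ModelParams.from_dict(model)


def save_params(params: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"model": params.to_dict()}, fh,
                       default_flow_style=False, sort_keys=True)
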