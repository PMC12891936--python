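"""Configuration loading and validation.

A run is configured by a YAML mapping whose keys mirror
:class:`~schooldyn.model.SimParams`; unspecified keys take the standard
defaults (N=100, z_r=1 BL, alpha=270 deg, theta_max=40 deg, U=3 BL per
time unit, sigma=0.01). Angles are given in degrees, as conventionally
printed, and converted to radians internally by the model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import yaml

from .model import SimParams

__all__ = ["load_config", "params_from_mapping", "params_to_mapping"]

_FIELDS = {f.name: f for f in dataclasses.fields(SimParams)}


def params_from_mapping(mapping: Mapping[str, Any] | None,
                        base: SimParams | None = None) -> SimParams:
    """Build SimParams from a plain mapping, rejecting unknown keys."""
    mapping = dict(mapping or {})
    unknown = set(mapping) - set(_FIELDS)
    if unknown:
        raise KeyError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}; "
            f"valid keys: {', '.join(sorted(_FIELDS))}"
        )
    base = base or SimParams()
    try:
        return dataclasses.replace(base, **mapping)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration value: {exc}") from exc


def params_to_mapping(params: SimParams) -> dict[str, Any]:
    return dataclasses.asdict(params)


def load_config(path: str | Path, overrides: Mapping[str, Any] | None = None) -> SimParams:
    """Load SimParams from a YAML file; ``overrides`` (e.g. CLI flags)
    take precedence over file values. An empty file yields the defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    params = params_from_mapping(raw)
    if overrides:
        params = params_from_mapping(
            {k: v for k, v in overrides.items() if v is not None}, base=params
        )
    return params
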