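"""Scenario/engine configuration parsing for the command-line interface.

A configuration file is flat YAML: the scenario definition (``model``,
``label``, ``params``, ``initial_state``, ``horizon_days``, optional
``provenance``) plus an optional ``abm`` section with engine knobs
(``dt``, ``n_runs``, ``base_seed``, ``mode``, ``record_every``,
``rate_mode``).  Unknown keys are errors; omitted engine knobs fall back to
the documented defaults.
"""

from __future__ import annotations

import os
from dataclasses import fields, replace
from typing import Dict, Optional, Tuple

import yaml

from .abm import AbmConfig
from .exceptions import ConfigError, ScenarioError
from .models import BUILTIN_LABELS, ScenarioSpec, load_scenario

__all__ = ["parse_config", "apply_overrides"]

_ABM_KEYS = {f.name for f in fields(AbmConfig)}


def parse_config(path_or_label: str) -> Tuple[ScenarioSpec, AbmConfig]:
    """Resolve a built-in label or a YAML file into validated specs."""
    if path_or_label in BUILTIN_LABELS:
        return load_scenario(path_or_label), AbmConfig()
    if not os.path.exists(path_or_label):
        raise ScenarioError(
            f"unknown scenario {path_or_label!r}; available built-ins: {', '.join(BUILTIN_LABELS)}"
        )
    with open(path_or_label, "r", encoding="utf-8") as handle:
        try:
            data = yaml.safe_load(handle)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" (line {mark.line + 1})" if mark is not None else ""
            raise ConfigError(f"cannot parse {path_or_label!r}{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path_or_label!r} must contain a mapping")
    abm_section = data.pop("abm", {})
    if abm_section is None:
        abm_section = {}
    if not isinstance(abm_section, dict):
        raise ConfigError("the 'abm' section must be a mapping")
    unknown = set(abm_section) - _ABM_KEYS
    if unknown:
        raise ConfigError(f"unknown abm keys: {sorted(unknown)}; expected {sorted(_ABM_KEYS)}")
    scenario = ScenarioSpec.from_dict(data)
    config = AbmConfig(**abm_section)
    return scenario, config


def apply_overrides(
    config: AbmConfig,
    dt: Optional[float] = None,
    n_runs: Optional[int] = None,
    base_seed: Optional[int] = None,
    mode: Optional[str] = None,
    rate_mode: Optional[str] = None,
    record_every: Optional[int] = None,
) -> AbmConfig:
    """Return a config with command-line overrides applied and re-validated."""
    changes: Dict[str, object] = {}
    for name, value in (
        ("dt", dt),
        ("n_runs", n_runs),
        ("base_seed", base_seed),
        ("mode", mode),
        ("rate_mode", rate_mode),
        ("record_every", record_every),
    ):
        if value is not None:
            changes[name] = value
    return replace(config, **changes) if changes else config
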