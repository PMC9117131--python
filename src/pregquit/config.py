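"""Run-configuration files for the analysis drivers.

A run configuration is a YAML or JSON mapping with optional sections
``simulate``, ``classify``, ``analyze``, ``bf`` and ``power``; the
``simulate`` section holds :class:`pregquit.simulate.SimulationConfig`
overrides by field name.
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path
from typing import Any, Dict

import yaml

from .simulate import SimulationConfig

SECTIONS = ("simulate", "classify", "analyze", "bf", "power")


def load_run_config(path) -> Dict[str, Any]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    cfg = (json.loads(text) if path.suffix == ".json"
           else yaml.safe_load(text)) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    unknown = set(cfg) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
    return cfg


def simulation_config_from_mapping(mapping: Dict[str, Any]) -> SimulationConfig:
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
    coerced = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in mapping.items()}
    return SimulationConfig(**coerced)
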