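"""YAML scenario-configuration files.

A configuration document has optional sections ``environment``,
``network``, ``skyloo``, ``municipal`` and ``grid``; every key must name a
field of the corresponding config dataclass, and unknown keys fail before
any run.  See ``fs-abm --help`` for how grids are launched from files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .environment import EnvironmentConfig
from .errors import ConfigError
from .municipal import MunicipalConfig
from .runner import ScenarioGrid
from .skyloo import SkylooConfig

__all__ = ["load_config", "grid_from_dict"]


def _build(cls, section: dict, section_name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    for key in section:
        if key not in allowed:
            raise ConfigError(key, f"unknown key in '{section_name}' section")
    if "land_size_range" in section:
        section = {**section, "land_size_range": tuple(section["land_size_range"])}
    return cls(**section)


def grid_from_dict(doc: dict) -> ScenarioGrid:
    if not isinstance(doc, dict):
        raise ConfigError("config", "document must be a mapping of sections")
    known = {"environment", "network", "skyloo", "municipal", "grid"}
    for key in doc:
        if key not in known:
            raise ConfigError(key, f"unknown section (expected one of {sorted(known)})")
    env = _build(EnvironmentConfig, doc.get("environment", {}), "environment")
    sk = _build(SkylooConfig, doc.get("skyloo", {}), "skyloo")
    mu = _build(MunicipalConfig, doc.get("municipal", {}), "municipal")
    net = doc.get("network", {})
    for key in net:
        if key not in ("k", "p_rewire"):
            raise ConfigError(key, "unknown key in 'network' section")
    g = doc.get("grid", {})
    grid = ScenarioGrid(
        model=g.get("model", "skyloo"),
        scenarios=g.get("scenarios", {"default": {}}),
        repeats=int(g.get("repeats", 100)),
        base_seed=int(g.get("base_seed", 0)),
        env=env,
        skyloo=sk,
        municipal=mu,
        network_k=int(net.get("k", 4)),
        network_p_rewire=float(net.get("p_rewire", 0.2)),
    )
    grid.validate()
    env.validate()
    sk.validate()
    mu.validate()
    return grid


def load_config(path) -> ScenarioGrid:
    """Parse a YAML scenario file into a validated :class:`ScenarioGrid`."""
    with open(Path(path)) as fh:
        doc = yaml.safe_load(fh) or {}
    return grid_from_dict(doc)
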