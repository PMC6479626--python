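"""Scenario grids, Monte-Carlo repetition and aggregation.

A :class:`ScenarioGrid` names a set of parameter overrides per scenario and
a repeat count (the study defaults: 1000 repeats for the adoption model,
250 for the municipal site).  Repeat ``r`` of every scenario runs with seed
``base_seed + r``, so scenarios are compared on paired seeds and the whole
grid is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import EnvironmentConfig
from .errors import ConfigError
from .municipal import MunicipalConfig, run_municipal
from .skyloo import SkylooConfig, run_skyloo_replicate

__all__ = ["ScenarioGrid", "SummaryTable", "run_scenario_grid", "write_outputs"]


@dataclass
class ScenarioGrid:
    """One grid of named scenarios over a base configuration."""

    model: str  # "skyloo" | "municipal"
    scenarios: dict = field(default_factory=lambda: {"default": {}})
    repeats: int = 100
    base_seed: int = 0
    env: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    skyloo: SkylooConfig = field(default_factory=SkylooConfig)
    municipal: MunicipalConfig = field(default_factory=MunicipalConfig)
    network_k: int = 4
    network_p_rewire: float = 0.2
    keep_raw: bool = False

    def validate(self) -> None:
        if self.model not in ("skyloo", "municipal"):
            raise ConfigError("model", "must be 'skyloo' or 'municipal'")
        if self.repeats < 1:
            raise ConfigError("repeats", "must be at least 1")
        if not self.scenarios:
            raise ConfigError("scenarios", "at least one scenario is required")
        if self.model == "skyloo":
            allowed = {f.name for f in dataclasses.fields(SkylooConfig)}
            allowed |= {f.name for f in dataclasses.fields(EnvironmentConfig)}
        else:
            allowed = {f.name for f in dataclasses.fields(MunicipalConfig)}
        for name, overrides in self.scenarios.items():
            for key in overrides:
                if key not in allowed:
                    raise ConfigError(
                        key, f"unknown override in scenario '{name}' for model '{self.model}'"
                    )

    def scenario_configs(self, name: str):
        """Base configs with this scenario's overrides applied."""
        overrides = self.scenarios[name]
        if self.model == "skyloo":
            sk_fields = {f.name for f in dataclasses.fields(SkylooConfig)}
            sk = replace(self.skyloo, **{k: v for k, v in overrides.items() if k in sk_fields})
            env = replace(self.env, **{k: v for k, v in overrides.items() if k not in sk_fields})
            return env, sk
        return replace(self.municipal, **overrides)


@dataclass
class SummaryTable:
    """Aggregated per-tick statistics and end-of-run scalars for a grid."""

    model: str
    repeats: int
    base_seed: int
    per_tick: dict  # scenario -> DataFrame of mean/sd/percentile bands
    scalars: pd.DataFrame  # one row per scenario, end-of-run means/sds
    manifest: dict
    raw: dict | None = None  # scenario -> list of per-repeat DataFrames


def _aggregate(frames: list[pd.DataFrame]) -> pd.DataFrame:
    cols = [c for c in frames[0].columns if c != "tick"]
    stack = np.stack([f[cols].to_numpy(dtype=float) for f in frames])  # (rep, tick, col)
    out = {"tick": frames[0]["tick"].to_numpy()}
    for j, c in enumerate(cols):
        block = stack[:, :, j]
        out[f"{c}_mean"] = block.mean(axis=0)
        out[f"{c}_sd"] = block.std(axis=0, ddof=0)
        out[f"{c}_q025"] = np.percentile(block, 2.5, axis=0)
        out[f"{c}_q975"] = np.percentile(block, 97.5, axis=0)
    return pd.DataFrame(out)


def run_scenario_grid(grid: ScenarioGrid, progress=None) -> SummaryTable:
    """Execute every scenario x repeat and aggregate the output series.

    ``progress`` is an optional callable ``(scenario, repeat)`` for logging.
    """
    grid.validate()
    per_tick: dict[str, pd.DataFrame] = {}
    raw: dict[str, list[pd.DataFrame]] = {}
    scalar_rows = []
    for name in grid.scenarios:
        frames = []
        for r in range(grid.repeats):
            seed = grid.base_seed + r
            if grid.model == "skyloo":
                env, sk = grid.scenario_configs(name)
                res = run_skyloo_replicate(env, sk, seed, k=grid.network_k,
                                           p_rewire=grid.network_p_rewire)
            else:
                res = run_municipal(grid.scenario_configs(name), seed)
            frames.append(res.series)
            if progress is not None:
                progress(name, r)
        per_tick[name] = _aggregate(frames)
        if grid.keep_raw:
            raw[name] = frames
        finals = pd.concat([f.iloc[[-1]] for f in frames])
        row = {"scenario": name, "repeats": grid.repeats}
        for c in finals.columns:
            if c == "tick":
                continue
            row[f"final_{c}_mean"] = float(finals[c].mean())
            row[f"final_{c}_sd"] = float(finals[c].std(ddof=0))
        scalar_rows.append(row)

    manifest = {
        "model": grid.model,
        "repeats": grid.repeats,
        "base_seed": grid.base_seed,
        "seeds": [grid.base_seed + r for r in range(grid.repeats)],
        "network": {"k": grid.network_k, "p_rewire": grid.network_p_rewire},
        "environment": dataclasses.asdict(grid.env),
        "skyloo": dataclasses.asdict(grid.skyloo),
        "municipal": dataclasses.asdict(grid.municipal),
        "scenarios": grid.scenarios,
    }
    return SummaryTable(
        model=grid.model,
        repeats=grid.repeats,
        base_seed=grid.base_seed,
        per_tick=per_tick,
        scalars=pd.DataFrame(scalar_rows),
        manifest=manifest,
        raw=raw or None,
    )


def write_outputs(st: SummaryTable, directory) -> list[Path]:
    """Write one per-tick CSV per scenario, a scalar summary and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in st.per_tick.items():
        path = directory / f"{st.model}_{name}_series.csv"
        frame.to_csv(path, index=False)
        written.append(path)
    summary_path = directory / f"{st.model}_summary.csv"
    st.scalars.to_csv(summary_path, index=False)
    written.append(summary_path)
    manifest_path = directory / f"{st.model}_manifest.json"
    try:
        from importlib.metadata import version

        pkg_version = version("fsabm")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    with open(manifest_path, "w") as fh:
        json.dump({"package_version": pkg_version, **st.manifest}, fh, indent=2)
    written.append(manifest_path)
    return written
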