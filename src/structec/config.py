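"""Run-configuration parsing.

A run configuration is a YAML mapping with optional ``simulation``,
``grid``, ``inversion`` and ``pipeline`` sections mirroring the
corresponding dataclasses.  Unknown sections or keys are a hard error,
so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .bmr import GridSpec
from .errors import ConfigError
from .experiment import PipelineSettings
from .invert import InversionSettings
from .io import load_yaml_config
from .simulate import SimulationConfig

__all__ = ["RunConfig", "load_run_config"]


def _build(cls, mapping: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    fixed = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in mapping.items()
    }
    try:
        return cls(**fixed)
    except TypeError as e:
        raise ConfigError(f"invalid section {section!r}: {e}") from e


@dataclasses.dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig
    pipeline: PipelineSettings


def load_run_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    doc = load_yaml_config(path) if path else {}
    known = {"simulation", "grid", "inversion", "pipeline"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
    sim_map = dict(doc.get("simulation", {}))
    if seed is not None:
        sim_map["seed"] = seed
    sim = _build(SimulationConfig, sim_map, "simulation")
    grid = _build(GridSpec, dict(doc.get("grid", {})), "grid")
    inv = _build(InversionSettings, dict(doc.get("inversion", {})), "inversion")
    pipe_map = dict(doc.get("pipeline", {}))
    pipe_map["grid_spec"] = grid
    pipe_map["inversion"] = inv
    pipe = _build(PipelineSettings, pipe_map, "pipeline")
    return RunConfig(sim, pipe)
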