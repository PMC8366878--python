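"""Pipeline configuration: YAML file plus per-stage blocks."""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import CurtailmentCriteria
from .model import ModelConfig
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "load_config"]


def _build(cls, block: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}' block: {', '.join(sorted(unknown))}")
    coerced = dict(block)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in coerced[f.name]
            )
    return cls(**coerced)


@dataclass
class PipelineConfig:
    output_dir: Path
    tracks: Path | None = None
    turbines: Path | None = None
    seed: int = 0
    criteria: CurtailmentCriteria = field(default_factory=CurtailmentCriteria)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    safer_threshold: float = 0.95
    riskier_threshold: float = 0.05
    approach_mode: str = "inner_cylinder"


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; the seed cascades into every stage."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    paths = raw.get("paths", {})
    if "output_dir" not in paths:
        raise ValueError("config missing required key: paths.output_dir")
    seed = int(raw.get("seed", 0))
    sim_block = dict(raw.get("simulation", {}))
    sim_block.setdefault("seed", seed)
    model_block = dict(raw.get("model", {}))
    model_block.setdefault("seed", seed)
    summary_block = raw.get("summary", {})
    return PipelineConfig(
        output_dir=Path(paths["output_dir"]),
        tracks=Path(paths["tracks"]) if "tracks" in paths else None,
        turbines=Path(paths["turbines"]) if "turbines" in paths else None,
        seed=seed,
        criteria=_build(CurtailmentCriteria, raw.get("criteria", {}), "criteria"),
        simulation=_build(SimulationConfig, sim_block, "simulation"),
        model=_build(ModelConfig, model_block, "model"),
        safer_threshold=float(summary_block.get("safer_threshold", 0.95)),
        riskier_threshold=float(summary_block.get("riskier_threshold", 0.05)),
        approach_mode=str(raw.get("approach_mode", "inner_cylinder")),
    )
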