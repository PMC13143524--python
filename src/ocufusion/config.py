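"""Run configuration: one serializable YAML document per experiment.

A run re-launched from its saved config and seed reproduces its fold
splits, and — in deterministic mode (the default; all stochastic steps
draw from seeded generators) — its metric tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig


@dataclass
class DataSection:
    manifest: str | None = None  # CSV path or dataset directory
    synthetic: dict | None = None  # SyntheticSpec keyword arguments


@dataclass
class EvalSection:
    k_folds: int = 5
    roc_curves: bool = False


@dataclass
class RunConfig:
    data: DataSection = field(default_factory=DataSection)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalSection = field(default_factory=EvalSection)
    out_dir: str = "runs/run0"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"data", "model", "train", "eval", "out_dir", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            data=DataSection(**raw.get("data", {})),
            model=ModelConfig(**raw.get("model", {})),
            train=TrainConfig(**raw.get("train", {})),
            eval=EvalSection(**raw.get("eval", {})),
            out_dir=raw.get("out_dir", "runs/run0"),
            seed=int(raw.get("seed", 0)),
        )

    def with_seed(self, seed: int) -> "RunConfig":
        d = asdict(self)
        d["seed"] = seed
        d["train"]["seed"] = seed
        return RunConfig.from_dict(d)
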