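"""Run configuration: one YAML-serializable object holding every tunable.

``RunConfig`` nests the per-stage parameter groups (phantom, engine,
protocol, optimizer weights, both networks, evaluation) so that a single
config file plus the seeds fully determines a pipeline run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .anatomy import PhantomConfig
from .dose_engine import EngineConfig
from .fd_net import FDNetConfig
from .fm_net import FMNetConfig
from .pipeline import ExperimentConfig
from .planner import ObjectiveWeights, OptimizerConfig, ProtocolConfig


@dataclass(frozen=True)
class EvalConfig:
    gamma_dose_pct: float = 3.0
    gamma_dist_mm: float = 3.0
    gamma_cutoff_fraction: float = 0.10
    roi_margin_mm: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, in one serializable object."""

    seed: int = 0
    n_cases: int = 40
    train_fraction: float = 0.75
    preset: str = "coarse"          # 'coarse' or 'full' geometry scale
    phantom: PhantomConfig = field(default_factory=PhantomConfig.coarse)
    engine: EngineConfig = field(default_factory=EngineConfig.coarse)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    fd: FDNetConfig = field(default_factory=FDNetConfig.coarse)
    fm: FMNetConfig = field(default_factory=FMNetConfig.coarse)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    @staticmethod
    def full(**overrides) -> "RunConfig":
        base = dict(
            preset="full",
            n_cases=100,
            train_fraction=0.85,
            phantom=PhantomConfig(),
            engine=EngineConfig(),
            fd=FDNetConfig(),
            fm=FMNetConfig(),
        )
        base.update(overrides)
        return RunConfig(**base)

    def experiment(self) -> ExperimentConfig:
        return ExperimentConfig(
            n_cases=self.n_cases,
            train_fraction=self.train_fraction,
            phantom=self.phantom,
            engine=self.engine,
            protocol=self.protocol,
            optimizer=self.optimizer,
            fd=self.fd,
            fm=self.fm,
            roi_margin_mm=self.evaluation.roi_margin_mm,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_yaml())
        return path

    @staticmethod
    def from_yaml(text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        return _build(RunConfig, raw)

    @staticmethod
    def load(path: str | Path) -> "RunConfig":
        return RunConfig.from_yaml(Path(path).read_text())


_GROUPS = {
    "phantom": PhantomConfig,
    "engine": EngineConfig,
    "protocol": ProtocolConfig,
    "optimizer": OptimizerConfig,
    "fd": FDNetConfig,
    "fm": FMNetConfig,
    "evaluation": EvalConfig,
    "weights": ObjectiveWeights,
}


def _build(cls, raw: dict):
    """Reconstruct nested frozen dataclasses from plain YAML data."""
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in raw.items():
        if key not in fields:
            raise ValueError(f"unknown config key {key!r} for {cls.__name__}")
        if key in _GROUPS and isinstance(value, dict):
            kwargs[key] = _build(_GROUPS[key], value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)
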