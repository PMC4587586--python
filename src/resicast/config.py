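"""Run configuration: a validated schema for the whole pipeline.

Loaded from YAML (unknown keys are rejected) and translated into the
dataclasses each module consumes.  Defaults reproduce the standard
protocol: min-max scaling fitted on the full series, an 80/10/10
chronological split, a GA-searched hybrid base forecaster, ANN residual
correction, and ten seeded repetitions selected by validation fitness.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .hybrid import GAParams
from .mlp import TrainOptions
from .series import SplitSpec
from .correction import StopPolicy

__all__ = ["RunConfig", "load_config", "config_from_dict"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SplitConfig(_Strict):
    train: float = 0.8
    val: float = 0.1
    test: float = 0.1

    def to_spec(self) -> SplitSpec:
        return SplitSpec(self.train, self.val, self.test)


class NormalizationConfig(_Strict):
    fit_on: Literal["full", "train"] = "full"


class MetricsConfig(_Strict):
    scale: Literal["normalized", "original"] = "normalized"
    u_denominator: Literal["outputs", "targets"] = "outputs"
    variant: Literal["printed", "classical"] = "printed"
    mape_epsilon: float = 1e-8

    def kwargs(self) -> dict:
        return {
            "u_denominator": self.u_denominator,
            "variant": self.variant,
            "mape_epsilon": self.mape_epsilon,
        }


class TrainConfig(_Strict):
    max_iterations: int = 1000
    generalization_loss_pct: float = 5.0
    min_progress: float = 1e-6
    progress_window: int = 5

    def to_options(self) -> TrainOptions:
        return TrainOptions(
            self.max_iterations,
            self.generalization_loss_pct,
            self.min_progress,
            self.progress_window,
        )


class HybridConfig(_Strict):
    mutation_prob: float = 0.10
    pop_size: int = 10
    max_generations: int = 1000
    min_fitness_progress: float = 1e-4
    acceptable_fitness_error: float = 0.01
    max_lags: int = 10
    max_hidden: int = 20
    max_outer_iterations: int = 10
    crossover_rate: float = 0.9
    tournament_size: int = 2
    elitism: int = 1
    progress_patience: int = 10
    phase_adjustment: Literal["affine_shift", "none"] = "affine_shift"

    def to_params(self, seed: int = 0) -> GAParams:
        return GAParams(
            mutation_prob=self.mutation_prob,
            pop_size=self.pop_size,
            max_generations=self.max_generations,
            min_fitness_progress=self.min_fitness_progress,
            acceptable_fitness_error=self.acceptable_fitness_error,
            max_lags=self.max_lags,
            max_hidden=self.max_hidden,
            max_outer_iterations=self.max_outer_iterations,
            seed=seed,
            crossover_rate=self.crossover_rate,
            tournament_size=self.tournament_size,
            elitism=self.elitism,
            progress_patience=self.progress_patience,
            phase_adjustment=self.phase_adjustment,
        )


class MLPBaseConfig(_Strict):
    n_lags: int = 3
    n_hidden: int = 4
    trainer: Literal["lm", "scg", "rprop", "oss"] = "lm"


class BaseModelConfig(_Strict):
    kind: Literal["hybrid", "mlp"] = "hybrid"
    hybrid: HybridConfig = Field(default_factory=HybridConfig)
    mlp: MLPBaseConfig = Field(default_factory=MLPBaseConfig)


class ACFConfig(_Strict):
    bound: Literal["two_over_sqrt_n", "two_s"] = "two_over_sqrt_n"
    tolerance: float = 0.0
    max_lag: int | None = None


class StopConfig(_Strict):
    mape_increase_threshold: float = 0.05
    patience: int = 1
    max_corrections: int = 5

    def to_policy(self) -> StopPolicy:
        return StopPolicy(self.mape_increase_threshold, self.patience, self.max_corrections)


class CorrectionConfig(_Strict):
    method: Literal["ann", "hs"] = "ann"
    hidden_sweep: list[int] = Field(default_factory=lambda: list(range(1, 21)))
    max_acf_lags: int = 10
    lag_mode: Literal["consecutive", "exceeding"] = "consecutive"
    hybrid: HybridConfig = Field(default_factory=HybridConfig)
    stop: StopConfig = Field(default_factory=StopConfig)
    acf: ACFConfig = Field(default_factory=ACFConfig)
    selection: Literal["stop_rule", "best_val_fitness"] = "stop_rule"


class ExperimentConfig(_Strict):
    repetitions: int = 10
    selection: Literal["best_val_fitness", "last"] = "best_val_fitness"


class RunConfig(_Strict):
    """Top-level configuration for one correction run."""

    split: SplitConfig = Field(default_factory=SplitConfig)
    normalization: NormalizationConfig = Field(default_factory=NormalizationConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    base: BaseModelConfig = Field(default_factory=BaseModelConfig)
    correction: CorrectionConfig = Field(default_factory=CorrectionConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check_split(self) -> "RunConfig":
        self.split.to_spec()  # raises on invalid proportions
        return self


def config_from_dict(data: dict) -> RunConfig:
    return RunConfig.model_validate(data or {})


def load_config(path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
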