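"""YAML-backed pipeline configuration with strict validation.

Unknown keys are rejected at every level; per-stage seeds are derived
from the global seed by fixed offsets so individual stages are
independently reproducible.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from damil.keyset import CrlConfig
from damil.model import DamilConfig
from damil.synthetic import SyntheticCohortSpec
from damil.training import TrainConfig

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 0, "splits": 1, "train": 2, "model": 3}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_rc: int = 50
    n_nrc: int = 50
    slides_per_patient: tuple[int, int] = (1, 1)
    n_instances: tuple[int, int] = (30, 60)
    dim: int = 64
    witness_rate: float = 0.2
    effect_size: float = 4.0
    true_hr: float = 2.3
    censor_horizon: float = 60.0


class PreprocessSection(_Strict):
    sat_threshold: int = 8
    median_radius: int = 2
    min_tissue_frac: float = 0.5
    patch_size: int = 896
    encoder_dim: int = 768


class TumorBulkSection(_Strict):
    threshold: float = 0.5
    closing_radius: int = 1
    min_object_cells: int = 8
    use_convex_hull: bool = True


class CrlSection(_Strict):
    rank_energy: float = 0.90
    max_rank: int = 32
    keys_per_slide: int = 4


class ModelSection(_Strict):
    hidden_dim: int = 512
    gate_dim: int = 256


class TrainSection(_Strict):
    learning_rate: float = 8e-5
    weight_decay: float = 1e-5
    min_epochs: int = 5
    patience: int = 5
    max_epochs: int = 50
    k_folds: int = 5
    val_fraction: float = 1.0 / 6.0


class EvalSection(_Strict):
    threshold: float = 0.5
    aggregate_rule: str = "max"
    horizon: float = 60.0

    @model_validator(mode="after")
    def _check_rule(self):
        if self.aggregate_rule not in ("max", "mean"):
            raise ValueError("aggregate_rule must be 'max' or 'mean'")
        return self


class PipelineConfig(_Strict):
    seed: int = 0
    synthetic_data: CohortSection = Field(default_factory=CohortSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    tumor_bulk: TumorBulkSection = Field(default_factory=TumorBulkSection)
    crl: CrlSection = Field(default_factory=CrlSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)

    def stage_seed(self, stage: str) -> int:
        return self.seed + SEED_OFFSETS[stage]

    def cohort_spec(self) -> SyntheticCohortSpec:
        return SyntheticCohortSpec(
            **self.synthetic_data.model_dump(), seed=self.stage_seed("simulate")
        )

    def crl_config(self) -> CrlConfig:
        return CrlConfig(**self.crl.model_dump())

    def model_config_for(self, dim: int) -> DamilConfig:
        return DamilConfig(
            dim=dim,
            hidden_dim=self.model.hidden_dim,
            gate_dim=self.model.gate_dim,
            seed=self.stage_seed("model"),
        )

    def train_config(self) -> TrainConfig:
        sec = self.train.model_dump()
        sec.pop("k_folds")
        sec.pop("val_fraction")
        return TrainConfig(**sec, seed=self.stage_seed("train"))


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
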