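"""Validated pipeline configuration (YAML-backed).

Defaults reproduce the study design: participant-level 0.8 split,
quantile probabilities (0.25, 0.5, 0.75), 95% bands, full-cycle
evaluation window.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from gaitfosr.model import ModelConfig
from gaitfosr.outcomes import OUTCOMES


class ModelSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_basis_t: int = 20
    n_basis_x: int = 8
    n_basis_tensor_t: int = 8
    n_basis_subject: int = 20
    degree: int = 3
    penalty_order: int = 2
    include_random: bool = True
    smoothing: str = "REML"
    lambda_default: float = 1.0
    lambda_overrides: dict[str, float] = Field(default_factory=dict)
    domain_extension: float = 0.01
    max_iter: int = 200
    tol: float = 1e-3

    @field_validator("smoothing")
    @classmethod
    def _check_smoothing(cls, v: str) -> str:
        if v not in ("REML", "GCV", "fixed"):
            raise ValueError(f"smoothing must be REML, GCV or fixed, got {v!r}")
        return v

    def to_model_config(self) -> ModelConfig:
        return ModelConfig(**self.model_dump())


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: ModelSettings = Field(default_factory=ModelSettings)
    train_fraction: float = 0.8
    split_seed: int = 0
    quantile_probs: tuple[float, float, float] = (0.25, 0.5, 0.75)
    level: float = 0.95
    evaluation_window: tuple[int, int] | None = None
    outcomes: list[str] = Field(default_factory=lambda: list(OUTCOMES))

    @field_validator("train_fraction")
    @classmethod
    def _check_fraction(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {v}")
        return v

    @field_validator("level")
    @classmethod
    def _check_level(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError(f"level must be in (0, 1), got {v}")
        return v

    @field_validator("outcomes")
    @classmethod
    def _check_outcomes(cls, v: list[str]) -> list[str]:
        unknown = set(v) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes {sorted(unknown)}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
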