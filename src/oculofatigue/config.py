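"""Validated configuration: one auditable place for every constant.

The config file is YAML with three sections (``detector``, ``features``,
``model``) plus top-level ``kss_threshold`` and ``seed``; unknown keys
are rejected.  CLI flags override file values.  Every output file embeds
the SHA-256 hash of the effective config for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from oculofatigue.errors import ConfigurationError
from oculofatigue.event_detection import DetectorParams
from oculofatigue.oculometrics import FeatureParams


class DetectorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sg_window_samples: int = 19
    sg_order: int = 2
    pt_init_dps: float = Field(100.0, gt=0)
    pt_sd_factor: float = Field(6.0, gt=0)
    onset_sd_factor: float = Field(3.0, gt=0)
    pt_tolerance_dps: float = Field(1.0, gt=0)
    min_saccade_s: float = Field(0.010, gt=0)
    min_fixation_s: float = Field(0.040, gt=0)
    min_blink_s: float = Field(0.010, gt=0)
    blink_margin_samples: int = Field(2, ge=0)
    pupil_cutoff_hz: float = Field(4.0, gt=0)
    pupil_filter_order: int = Field(3, ge=1)
    refine_on: str = "raw"

    def to_params(self) -> DetectorParams:
        return DetectorParams(**self.model_dump())


class FeatureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    long_blink_s: float = Field(0.200, gt=0)
    long_fixation_s: float = Field(0.900, gt=0)
    ibi_cap_s: float = Field(20.0, gt=0)
    double_blink_gap_s: float = Field(0.700, gt=0)
    tbs_cap_s: float = Field(0.700, gt=0)
    isi_cap_s: float = Field(0.250, gt=0)
    gaze_shift_deg: float = Field(2.0, gt=0)
    fixation_pair_gap_s: float = Field(0.100, gt=0)

    def to_params(self) -> FeatureParams:
        return FeatureParams(**self.model_dump())


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: str = "dt_ensemble"
    n_learners: int = Field(50, ge=1)
    max_splits: int = Field(5, ge=1)
    error_goal: float = Field(0.25, gt=0, lt=0.5)
    max_margin: float = Field(1.0, gt=0)
    posterior_threshold: float = Field(0.5, ge=0, le=1)


class Config(BaseModel):
    model_config = ConfigDict(extra="forbid")

    detector: DetectorConfig = DetectorConfig()
    features: FeatureConfig = FeatureConfig()
    model: ModelConfig = ModelConfig()
    kss_threshold: int = Field(5, ge=1, le=10)
    seed: int = 0

    @field_validator("kss_threshold")
    @classmethod
    def _threshold_in_scale(cls, v: int) -> int:
        return v

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None) -> Config:
    if path is None:
        return Config()
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return Config(**raw)
    except FileNotFoundError:
        raise ConfigurationError(f"config file not found: {path}") from None
    except Exception as exc:  # pydantic / yaml errors -> one schema message
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc
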