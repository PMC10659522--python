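"""Pipeline configuration: defaults, YAML round-trip, validation.

Defaults mirror the analysis conventions the pipeline implements: QC
cross-protocol correlation threshold 0.7, outlier weight threshold 0.1,
calibration in 5-year age bands, age strata 20-35 then 5-year bands to 70
then open-ended, VIF threshold 5, elastic-net mixing 0.5, FDR significance
q < 0.05, association significance p < 0.001, 7-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]

DEFAULT_AGE_STRATA = [[20, 35], [35, 40], [40, 45], [45, 50], [50, 55],
                      [55, 60], [60, 65], [65, 70], [70, None]]


@dataclass
class SimulateConfig:
    n_per_cohort: int = 400
    n_metabolites: int = 40
    outlier_fraction: float = 0.02
    outlier_magnitude: float = 10.0
    censor_time: float = 15.0


@dataclass
class QcConfig:
    r_threshold: float = 0.7
    missing_rule: float = 0.5


@dataclass
class OutlierConfig:
    weight_threshold: float = 0.1
    retained_variance: float = 0.99


@dataclass
class CalibrateConfig:
    reference: str = "whitegate"
    age_bin_width: float = 5.0
    estimator: str = "median"


@dataclass
class VifConfig:
    threshold: float = 5.0


@dataclass
class ModelConfig:
    alpha: float = 0.5
    cv_folds: int = 5
    n_lambda: int = 60
    mars_max_terms: int | None = None
    mars_max_knots: int = 12
    gcv_penalty: float = 3.0


@dataclass
class SignificanceConfig:
    q_threshold: float = 0.05
    p_threshold: float = 0.001
    i2_high: float = 0.75
    i2_low: float = 0.25


@dataclass
class CvConfig:
    k: int = 7


@dataclass
class PipelineConfig:
    seed: int = 1
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    outliers: OutlierConfig = field(default_factory=OutlierConfig)
    calibrate: CalibrateConfig = field(default_factory=CalibrateConfig)
    age_strata: list = field(default_factory=lambda: [list(b) for b in DEFAULT_AGE_STRATA])
    vif: VifConfig = field(default_factory=VifConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    cv: CvConfig = field(default_factory=CvConfig)

    def validate(self) -> None:
        if not 0 < self.qc.r_threshold <= 1:
            raise ValueError("qc.r_threshold must be in (0, 1]")
        if not 0 <= self.outliers.weight_threshold <= 1:
            raise ValueError("outliers.weight_threshold must be in [0, 1]")
        if self.vif.threshold <= 1:
            raise ValueError("vif.threshold must be > 1")
        if not 0 <= self.model.alpha <= 1:
            raise ValueError("model.alpha must be in [0, 1]")
        if self.cv.k < 2:
            raise ValueError("cv.k must be >= 2")
        bands = self.age_strata
        for i in range(1, len(bands)):
            if bands[i - 1][1] is None or bands[i][0] < bands[i - 1][1]:
                raise ValueError("age strata must be ordered and non-overlapping")
        if bands and bands[-1][1] is not None:
            raise ValueError("final age stratum must be open-ended")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(
            seed=int(d.get("seed", 1)),
            simulate=SimulateConfig(**d.get("simulate", {})),
            qc=QcConfig(**d.get("qc", {})),
            outliers=OutlierConfig(**d.get("outliers", {})),
            calibrate=CalibrateConfig(**d.get("calibrate", {})),
            age_strata=[list(b) for b in d.get("age_strata", DEFAULT_AGE_STRATA)],
            vif=VifConfig(**d.get("vif", {})),
            model=ModelConfig(**d.get("model", {})),
            significance=SignificanceConfig(**d.get("significance", {})),
            cv=CvConfig(**d.get("cv", {})),
        )
        cfg.validate()
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(d)


def save_config(path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
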