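"""Pipeline configuration: one YAML-serialisable object holding every
stage's parameters, validated against all module preconditions before any
stage runs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .io import ConfigError
from .features import ExtractionParams
from .models import MODEL_FAMILIES
from .simulate import CohortConfig, FatigueEffectSpec, NoiseSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline parameters (simulation, extraction, selection, models)."""

    seed: int = 0
    # --- cohort simulation
    n_participants: int = 18
    segment_duration_s: float = 300.0
    pad_s: float = 10.0
    noise: dict = field(
        default_factory=lambda: {
            "force_N": 0.5, "acc_ms2": 0.15, "gyr_dps": 2.0,
            "ang_deg": 0.25, "drift_deg_per_s": 0.05,
        }
    )
    between_subject_sd: dict = field(
        default_factory=lambda: {
            "peaks": 0.10, "amplitudes": 0.10, "tremor": 0.10,
            "cycle_duration_s": 0.05,
        }
    )
    effects: dict = field(
        default_factory=lambda: {
            "Imp_MA": 1.30, "Imp_LA": 1.30, "theta_Sag_Max": 1.20,
            "theta_Sag_Ran": 1.20, "alpha_Res_CV": 0.70,
        }
    )
    # --- segmentation & feature extraction
    cycle_threshold_N: float = 10.0
    region_threshold_N: float = 1.0
    min_stance_s: float = 0.2
    min_swing_s: float = 0.1
    window_s: float = 10.0
    overlap_s: float = 8.0
    count_mode: str = "formula"
    min_cycles_per_window: int = 3
    swing_only: bool = False
    # --- selection & models
    families: list = field(default_factory=lambda: list(MODEL_FAMILIES))
    cv_folds: int = 5
    cv_seed: int = 0
    tune_budget: int = 1
    sfs_max_features: int | None = None
    alpha: float = 0.05
    run_ablation: bool = True
    run_single_feature: bool = True
    # --- artifacts
    write_recordings: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # ---- builders (each constructor re-validates its module's contract)
    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(**self.noise)

    def effect_spec(self) -> FatigueEffectSpec:
        return FatigueEffectSpec(factors=dict(self.effects))

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_participants=self.n_participants,
            segment_duration_s=self.segment_duration_s,
            pad_s=self.pad_s,
            seed=self.seed,
            between_subject_sd=dict(self.between_subject_sd),
            noise=self.noise_spec(),
        )

    def extraction_params(self) -> ExtractionParams:
        return ExtractionParams(
            cycle_threshold_N=self.cycle_threshold_N,
            region_threshold_N=self.region_threshold_N,
            min_stance_s=self.min_stance_s,
            min_swing_s=self.min_swing_s,
            window_s=self.window_s,
            overlap_s=self.overlap_s,
            count_mode=self.count_mode,
            min_cycles_per_window=self.min_cycles_per_window,
            segment_duration_s=self.segment_duration_s,
            swing_only=self.swing_only,
        )

    def validate(self) -> None:
        self.cohort_config()
        self.extraction_params()
        self.effect_spec()
        for fam in self.families:
            if fam not in MODEL_FAMILIES:
                raise ConfigError(f"unknown model family {fam!r}")
        if not self.families:
            raise ConfigError("at least one model family is required")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.tune_budget < 1:
            raise ConfigError("tune_budget must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    # ---- (de)serialisation
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
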