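"""Declarative run configuration with strict schema validation.

Every stochastic stage carries an explicit seed derived from the top-level
seed; unknown keys are rejected before any stage runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_subjects: int = 8
    trials_per_speed: int = 2
    strides_per_trial: int = 5
    speeds: list[str] = ["slow", "self_selected", "fast"]
    fs: float = 100.0


class AugmentationSection(_Strict):
    offset_sigma: float = 5.0
    knot_sigma: float = 0.2
    n_knots: int = 7
    methods: list[str] = ["offset", "mag_warp", "offset+mag_warp",
                          "time_warp", "time+mag_warp"]


class NoiseSection(_Strict):
    sigma_gyro: float = 0.03
    sigma_acc: float = 0.2
    sigma_mount_deg: float = 2.0
    soft_tissue_amp: float = 0.0


class ModelSection(_Strict):
    hidden: int = 32
    n_layers: int = 1
    epochs: int = 30
    batch_size: int = 50


class ExperimentSection(_Strict):
    n_test_subjects: int = 2
    joints: list[str] = ["hip", "knee"]
    variants: list[str] = ["measured", "synthetic", "measured+synthetic"]

    @field_validator("joints")
    @classmethod
    def _joints_known(cls, v):
        bad = set(v) - {"hip", "knee"}
        if bad:
            raise ValueError(f"unknown joints {sorted(bad)}")
        return v


class RunConfig(_Strict):
    seed: int = 0
    outdir: str = "runs/default"
    cohort: CohortSection = CohortSection()
    augmentation: AugmentationSection = AugmentationSection()
    noise: NoiseSection = NoiseSection()
    model: ModelSection = ModelSection()
    experiment: ExperimentSection = ExperimentSection()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_experiment_config(self):
        from .augment import AugmentationParams
        from .experiment import ExperimentConfig
        from .imu import NoiseParams

        return ExperimentConfig(
            n_subjects=self.cohort.n_subjects,
            trials_per_speed=self.cohort.trials_per_speed,
            strides_per_trial=self.cohort.strides_per_trial,
            speeds=tuple(self.cohort.speeds),
            n_test_subjects=self.experiment.n_test_subjects,
            joints=tuple(self.experiment.joints),
            variants=tuple(self.experiment.variants),
            noise=NoiseParams(
                sigma_gyro=self.noise.sigma_gyro,
                sigma_acc=self.noise.sigma_acc,
                sigma_mount_deg=self.noise.sigma_mount_deg,
                soft_tissue_amp=self.noise.soft_tissue_amp,
            ),
            augmentation=AugmentationParams(
                offset_sigma=self.augmentation.offset_sigma,
                knot_sigma=self.augmentation.knot_sigma,
                n_knots=self.augmentation.n_knots,
                methods=tuple(self.augmentation.methods),
                seed=self.seed,
            ),
            epochs=self.model.epochs,
            hidden=self.model.hidden,
            n_layers=self.model.n_layers,
            batch_size=self.model.batch_size,
            seed=self.seed,
        )
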