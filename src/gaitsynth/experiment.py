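"""End-to-end training-variant experiment on a synthetic cohort.

Reproduces the design of a synthetic-training-data study at desk scale:
generate a cohort, segment gait cycles, emulate measured IMU recordings
(noise + mounting error) for every cycle, create 5:1 augmented synthetic
cycles from the training subjects only, train hip and knee BiLSTM models on
the measured / synthetic / measured+synthetic variants, and evaluate every
model on the measured-role recordings of held-out test subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import AugmentationParams, augment_dataset
from .chain import SensorMount, default_mounts
from .cohort import PairedStride, build_paired_dataset, generate_cohort, subject_chains
from .imu import NoiseParams
from .nn import ModelConfig, build_model, train
from .preprocess import (DatasetSplit, TrainingSample, assemble_variant,
                         make_split, pad_and_pack, segment_cycles)
from .stats import DOF_NAMES, ComparisonResult, EvalRecord, aggregate_table, cycle_metrics, manova_tukey
from .trial import InputError, KinematicTrial

_NO_NOISE = NoiseParams(sigma_gyro=0.0, sigma_acc=0.0, sigma_mount_deg=0.0)


@dataclass
class ExperimentConfig:
    """Desk-scale experiment defaults.

    The cohort and network sizes are reduced relative to a full lab study
    (8 subjects, a few trials per speed, hidden size 32) so a complete
    3-variant x 2-joint experiment runs on a laptop CPU in minutes; the
    pipeline itself is scale-free.
    """

    n_subjects: int = 8
    trials_per_speed: int = 2
    strides_per_trial: int = 5
    speeds: tuple[str, ...] = ("slow", "self_selected", "fast")
    n_test_subjects: int = 2
    joints: tuple[str, ...] = ("hip", "knee")
    variants: tuple[str, ...] = ("measured", "synthetic", "measured+synthetic")
    noise: NoiseParams = field(default_factory=NoiseParams)
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    epochs: int = 30
    hidden: int = 32
    n_layers: int = 1
    batch_size: int = 50
    seed: int = 0
    subject_variability: float = 1.0


@dataclass
class PreparedData:
    split: DatasetSplit
    measured: dict[str, list[TrainingSample]]   # per joint, training subjects
    synthetic: dict[str, list[TrainingSample]]  # per joint, training subjects
    test: dict[str, list[TrainingSample]]       # per joint, test subjects
    n_cycles: int
    n_synthetic: int


def _pack_pairs(pairs: list[PairedStride], joint: str, role: str) -> list[TrainingSample]:
    traces = [(p.imu_measured if role == "measured" else p.imu_clean, p.trial)
              for p in pairs]
    samples = pad_and_pack(traces, joint)
    for s, pair in zip(samples, pairs):
        s.provenance = pair.imu_measured[0].provenance if role == "measured" \
            else pair.imu_clean[0].provenance
    return samples


def prepare_datasets(cfg: ExperimentConfig) -> PreparedData:
    """Generate cohort, segment, simulate, augment and pack all datasets."""
    trials = generate_cohort(
        n_subjects=cfg.n_subjects, trials_per_speed=cfg.trials_per_speed,
        strides_per_trial=cfg.strides_per_trial, speeds=cfg.speeds,
        seed=cfg.seed, subject_variability=cfg.subject_variability,
    )
    chains = subject_chains(trials)
    cycles: list[KinematicTrial] = []
    for tr in trials:
        cycles.extend(segment_cycles(tr, tr.meta["heel_z"]))
    if not cycles:
        raise InputError("cohort produced no gait cycles")
    split = make_split([c.subject_id for c in cycles], cfg.n_test_subjects,
                       seed=cfg.seed)
    train_set = set(split.train_subjects)
    train_cycles = [c for c in cycles if c.subject_id in train_set]

    # measured role: noisy emulation for everyone (train + test)
    measured_pairs = build_paired_dataset(cycles, chains, noise=cfg.noise,
                                          seed=cfg.seed + 1)
    # synthetic role: 5:1 augmentation of training subjects, clean re-simulation
    aug = augment_dataset(train_cycles, replace(cfg.augmentation, seed=cfg.seed + 2))
    synth_pairs = build_paired_dataset(aug, chains, noise=_NO_NOISE,
                                       seed=cfg.seed + 3)

    measured, synthetic, test = {}, {}, {}
    for joint in cfg.joints:
        packed = _pack_pairs(measured_pairs, joint, "measured")
        measured[joint] = [s for s in packed if s.subject_id in train_set]
        test[joint] = [s for s in packed if s.subject_id not in train_set]
        synthetic[joint] = _pack_pairs(synth_pairs, joint, "synthetic")
    return PreparedData(split=split, measured=measured, synthetic=synthetic,
                        test=test, n_cycles=len(cycles), n_synthetic=len(aug))


@dataclass
class ExperimentReport:
    records: list[EvalRecord]
    table: pd.DataFrame
    comparison: ComparisonResult | None
    split: DatasetSplit
    counts: dict[str, int]
    loss_histories: dict[tuple[str, str], list[float]]

    def joint_average_rmse(self, variant: str, joint: str) -> float:
        sel = self.table[(self.table.variant == variant)
                         & (self.table.joint == joint)
                         & (self.table.dof == "average")]
        return float(sel["rmse_mean"].iloc[0])


def evaluate_model(model, test_samples: list[TrainingSample], variant: str,
                   joint: str) -> list[EvalRecord]:
    pred = model.predict(test_samples)
    records = []
    for p, s in zip(pred, test_samples):
        r, rmse, nrmse, ok = cycle_metrics(p, s.target, s.mask)
        records.append(EvalRecord(
            cycle_id=s.cycle_id, subject_id=s.subject_id, variant=variant,
            joint=joint, r=r, rmse=rmse, nrmse=nrmse, nrmse_valid=ok,
        ))
    return records


def plot_prediction_traces(model, samples: list[TrainingSample], path,
                           n_cycles: int = 3) -> None:
    """Predicted versus reference angle traces for a few test cycles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred = model.predict(samples[:n_cycles])
    fig, axes = plt.subplots(n_cycles, 3, figsize=(10, 2.5 * n_cycles),
                             squeeze=False, sharex=True)
    for i, s in enumerate(samples[:n_cycles]):
        n = s.length
        for d, name in enumerate(("flex-ext", "add-abd", "int-ext")):
            ax = axes[i][d]
            ax.plot(s.target[:n, d], "k-", lw=1, label="reference")
            ax.plot(pred[i][:n, d], "r--", lw=1, label="predicted")
            if i == 0:
                ax.set_title(name)
        axes[i][0].set_ylabel(f"{s.cycle_id}\n(deg)", fontsize=7)
    axes[0][0].legend(fontsize=7)
    axes[-1][1].set_xlabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(cfg: ExperimentConfig,
                   data: PreparedData | None = None) -> ExperimentReport:
    """Train all variant/joint models and compare them on the test subjects."""
    data = data if data is not None else prepare_datasets(cfg)
    records: list[EvalRecord] = []
    histories: dict[tuple[str, str], list[float]] = {}
    for joint in cfg.joints:
        for vi, variant in enumerate(cfg.variants):
            samples = assemble_variant(data.measured[joint], data.synthetic[joint],
                                       variant, data.split)
            mcfg = ModelConfig(
                joint=joint, n_layers=cfg.n_layers, hidden=cfg.hidden,
                epochs=cfg.epochs, batch_size=cfg.batch_size,
                seed=cfg.seed + 1000 * vi,
            )
            model = build_model(mcfg)
            histories[(joint, variant)] = train(model, samples, mcfg)
            records.extend(evaluate_model(model, data.test[joint], variant, joint))
    table = aggregate_table(records)
    comparison = manova_tukey(records) if len(cfg.variants) >= 2 else None
    counts = dict(
        cycles=data.n_cycles,
        synthetic=data.n_synthetic,
        train_measured=len(data.measured[cfg.joints[0]]),
        test=len(data.test[cfg.joints[0]]),
    )
    return ExperimentReport(records=records, table=table, comparison=comparison,
                            split=data.split, counts=counts,
                            loss_histories=histories)
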