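"""Staged pipeline runner with config-hash caching.

Stages run in order: cohort generation, dataset preparation (segmentation,
IMU simulation, augmentation, packing), training + evaluation.  Each stage
records a hash of the configuration keys it depends on in ``manifest.json``
inside the run directory; rerunning with an unchanged config reuses the
stage outputs instead of recomputing them.  Training is the slow stage, so
iterating on evaluation settings does not redo simulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .experiment import prepare_datasets, run_experiment
from .io import write_mot
from .trial import InputError

log = logging.getLogger("gaitsynth")


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _manifest(outdir: Path) -> dict:
    p = outdir / "manifest.json"
    return json.loads(p.read_text()) if p.exists() else {}


def _save_manifest(outdir: Path, man: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(man, indent=2, default=str))


def run_pipeline(config: RunConfig) -> Path:
    """Execute (or resume) the full pipeline; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _manifest(outdir)
    ecfg = config.to_experiment_config()

    data_key = _hash(dict(seed=config.seed,
                          cohort=config.cohort.model_dump(),
                          noise=config.noise.model_dump(),
                          augmentation=config.augmentation.model_dump(),
                          test=config.experiment.n_test_subjects))
    data_file = outdir / "datasets.pkl"
    if man.get("datasets") == data_key and data_file.exists():
        log.info("datasets stage: cache hit (%s)", data_key)
        data = pickle.loads(data_file.read_bytes())
    else:
        log.info("datasets stage: generating cohort and packing datasets")
        try:
            data = prepare_datasets(ecfg)
        except Exception as exc:
            raise InputError(f"stage 'datasets' failed: {exc}") from exc
        data_file.write_bytes(pickle.dumps(data))
        man["datasets"] = data_key
        man["counts"] = dict(cycles=data.n_cycles, synthetic=data.n_synthetic)
        _save_manifest(outdir, man)

    run_key = _hash(dict(data=data_key, model=config.model.model_dump(),
                         experiment=config.experiment.model_dump()))
    table_file = outdir / "results_table.csv"
    if man.get("train_eval") == run_key and table_file.exists():
        log.info("train/eval stage: cache hit (%s)", run_key)
        return outdir
    log.info("train/eval stage: training %d models",
             len(ecfg.joints) * len(ecfg.variants))
    try:
        report = run_experiment(ecfg, data=data)
    except Exception as exc:
        raise InputError(f"stage 'train_eval' failed: {exc}") from exc
    report.table.to_csv(table_file, index=False)
    report.comparison.tukey.to_csv(outdir / "tukey.csv", index=False)
    summary = dict(
        counts=report.counts,
        split=dict(train=report.split.train_subjects, test=report.split.test_subjects),
        manova=dict(wilks_lambda=report.comparison.wilks_lambda,
                    p_value=report.comparison.p_value,
                    ok=report.comparison.manova_ok),
        joint_average_rmse={
            f"{j}/{v}": report.joint_average_rmse(v, j)
            for j in ecfg.joints for v in ecfg.variants
        },
        augmented_ratio=(report.counts["synthetic"] / max(1, report.counts["cycles"] - report.counts["test"])),
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    man["train_eval"] = run_key
    _save_manifest(outdir, man)
    return outdir


def validate_simulation(config: RunConfig, n_trials: int = 3) -> pd.DataFrame:
    """Finite-difference fidelity report for the virtual IMU chain.

    Simulates a few cohort trials and compares every sensor channel against
    its finite-difference recomputation (r, RMSE, max abs error per channel).
    """
    from .chain import default_mounts
    from .cohort import generate_cohort
    from .finite_difference import simulation_fidelity_table
    from .kinematics import forward_kinematics

    if config.cohort.n_subjects < 1:
        raise InputError("empty cohort: n_subjects must be at least 1")
    trials = generate_cohort(
        n_subjects=min(config.cohort.n_subjects, n_trials),
        trials_per_speed=1, strides_per_trial=3,
        speeds=tuple(config.cohort.speeds), seed=config.seed,
    )
    if not trials:
        raise InputError("empty cohort")
    mounts = default_mounts()
    tables = []
    for tr in trials[:n_trials]:
        poses = forward_kinematics(tr.meta["chain"], tr, mounts)
        tab = simulation_fidelity_table(poses, mounts)
        tab.insert(0, "subject", tr.subject_id)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def export_cohort(config: RunConfig, outdir) -> list[Path]:
    """Write the generated cohort as .mot files plus a cohort manifest."""
    from .cohort import generate_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = generate_cohort(
        n_subjects=config.cohort.n_subjects,
        trials_per_speed=config.cohort.trials_per_speed,
        strides_per_trial=config.cohort.strides_per_trial,
        speeds=tuple(config.cohort.speeds),
        fs=config.cohort.fs, seed=config.seed,
    )
    paths = []
    manifest = []
    for i, tr in enumerate(trials):
        p = outdir / f"{tr.subject_id}_{tr.speed}_{tr.meta['trial_id']:02d}.mot"
        write_mot(tr, p)
        paths.append(p)
        manifest.append(dict(file=p.name, subject=tr.subject_id, speed=tr.speed,
                             n_strides=len(tr.heel_strikes)))
    (outdir / "cohort_manifest.json").write_text(json.dumps(
        dict(seed=config.seed, n_subjects=config.cohort.n_subjects,
             n_trials=len(trials), trials=manifest), indent=2))
    return paths
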