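"""Readers and writers for OpenSim-style motion files and IMU CSV traces.

Kinematic trials travel as ``.mot``/``.sto`` text files: a small header
(``nRows``, ``nColumns``, ``inDegrees``), an ``endheader`` line, then a
tab-separated table whose first column is ``time``.  Pelvis root pose is
stored alongside the seven joint-angle columns (position in metres,
orientation as extrinsic x-y-z Euler angles in degrees) so a trial file is
self-contained for forward kinematics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .chain import JOINT_COLUMNS
from .imu import IMUTrace
from .trial import InputError, KinematicTrial

_PELVIS_COLS = ("pelvis_tx", "pelvis_ty", "pelvis_tz",
                "pelvis_rx", "pelvis_ry", "pelvis_rz")


def write_mot(trial: KinematicTrial, path) -> None:
    path = Path(path)
    euler = Rotation.from_quat(trial.pelvis_quat).as_euler("xyz", degrees=True)
    table = np.column_stack([trial.time, trial.angles, trial.pelvis_pos, euler])
    cols = ("time",) + JOINT_COLUMNS + _PELVIS_COLS
    with open(path, "w") as fh:
        fh.write(f"{path.stem}\nversion=1\n")
        fh.write(f"nRows={len(trial)}\nnColumns={len(cols)}\n")
        fh.write("inDegrees=yes\n")
        fh.write(f"subject={trial.subject_id}\nspeed={trial.speed}\n")
        if len(trial.heel_strikes):
            fh.write("heelStrikes=" + ",".join(map(str, trial.heel_strikes.tolist())) + "\n")
        fh.write("endheader\n")
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, table, fmt="%.10g", delimiter="\t")


def read_mot(path) -> KinematicTrial:
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if line.lower() == "endheader":
                break
            if "=" in line:
                k, v = line.split("=", 1)
                header[k.strip()] = v.strip()
        else:
            raise InputError(f"{path}: no endheader line")
        df = pd.read_csv(fh, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    if "time" not in df.columns:
        raise InputError(f"{path}: first column must be 'time'")
    missing = [c for c in JOINT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing joint columns {missing}")
    t = df["time"].to_numpy()
    if header.get("inDegrees", "yes").lower() not in ("yes", "true"):
        raise InputError(f"{path}: only inDegrees=yes files are supported")
    angles = df[list(JOINT_COLUMNS)].to_numpy()
    n = len(t)
    if all(c in df.columns for c in _PELVIS_COLS):
        pos = df[list(_PELVIS_COLS[:3])].to_numpy()
        quat = Rotation.from_euler(
            "xyz", df[list(_PELVIS_COLS[3:])].to_numpy(), degrees=True
        ).as_quat()
    else:
        pos = np.zeros((n, 3))
        quat = np.tile([0.0, 0.0, 0.0, 1.0], (n, 1))
    fs = 1.0 / np.median(np.diff(t)) if n > 1 else 100.0
    strikes = np.array([int(s) for s in header.get("heelStrikes", "").split(",") if s],
                       dtype=int)
    return KinematicTrial(
        time=t, angles=angles, pelvis_pos=pos, pelvis_quat=quat,
        fs=float(round(fs, 6)),
        subject_id=header.get("subject", path.stem),
        speed=header.get("speed", "self_selected"),
        heel_strikes=strikes,
    )


def write_imu_csv(trace: IMUTrace, path) -> None:
    df = pd.DataFrame({
        "time": trace.time,
        "gyro_x": trace.gyro[:, 0], "gyro_y": trace.gyro[:, 1], "gyro_z": trace.gyro[:, 2],
        "acc_x": trace.acc[:, 0], "acc_y": trace.acc[:, 1], "acc_z": trace.acc[:, 2],
    })
    df.to_csv(path, index=False)


def read_imu_csv(path, sensor: str = "", fs: float | None = None,
                 provenance: str = "simulated") -> IMUTrace:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    if fs is None:
        fs = float(round(1.0 / np.median(np.diff(t)), 6))
    return IMUTrace(
        sensor=sensor or Path(path).stem,
        time=t,
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        fs=fs, provenance=provenance,
    )


def write_imu_set(traces: list[IMUTrace], outdir, stem: str = "") -> Path:
    """One CSV per sensor plus a JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in traces:
        name = f"{stem + '_' if stem else ''}{tr.sensor}.csv"
        write_imu_csv(tr, outdir / name)
        entries.append(dict(sensor=tr.sensor, file=name, fs=tr.fs,
                            provenance=tr.provenance, n=len(tr)))
    manifest = outdir / f"{stem + '_' if stem else ''}manifest.json"
    manifest.write_text(json.dumps({"sensors": entries}, indent=2))
    return manifest
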