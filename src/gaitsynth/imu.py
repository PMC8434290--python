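"""Virtual IMU signal synthesis and measured-sensor emulation.

A virtual IMU rigidly attached to a segment reports

* gyroscope: the segment's angular velocity rotated into the sensor's local
  frame, ``R_sensor(t)^T @ omega_earth(t)`` (rad/s);
* accelerometer: the free (gravity-less) acceleration of the mount point,
  kept in the earth frame (m/s^2).  Commercial IMUs differ here — many
  report specific force in the sensor frame — so this convention is stated
  prominently: it matches the frame in which simulated and measured
  accelerations are compared in this pipeline.

``emulate_measured`` layers real-sensor imperfections (white noise, mount
misalignment, optional soft-tissue ringing at heel strike) on a clean trace
so a fully synthetic cohort can play both the "measured" and "synthetic"
roles of a training-data experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .chain import ConfigurationError, SensorMount
from .trial import InputError, PoseTrajectory
from .kinematics import body_angular_velocity, point_acceleration

PROVENANCES = ("simulated", "synthetic", "measured_emulated")


@dataclass
class IMUTrace:
    """Six-channel trace for one sensor: gyro (sensor frame) + free
    acceleration (earth frame)."""

    sensor: str
    time: np.ndarray
    gyro: np.ndarray   # (n, 3) rad/s, sensor frame
    acc: np.ndarray    # (n, 3) m/s^2, earth frame
    fs: float
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        n = len(self.time)
        if self.gyro.shape != (n, 3) or self.acc.shape != (n, 3):
            raise InputError("gyro/acc must be (n, 3)")
        if not (np.all(np.isfinite(self.gyro)) and np.all(np.isfinite(self.acc))):
            raise InputError("non-finite IMU samples")
        if self.provenance not in PROVENANCES:
            raise InputError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.time)

    def channels(self) -> np.ndarray:
        """(n, 6) array ordered [acc_x, acc_y, acc_z, gyro_x, gyro_y, gyro_z]."""
        return np.hstack([self.acc, self.gyro])


@dataclass(frozen=True)
class NoiseParams:
    """Measured-sensor emulation parameters.

    Defaults emulate research-grade, on-board-fused sensors: modest white
    noise and a couple of degrees of mounting uncertainty.  The soft-tissue
    artifact (damped oscillation at heel strike) is off by default.
    """

    sigma_gyro: float = 0.03        # rad/s, per axis
    sigma_acc: float = 0.2          # m/s^2, per axis
    sigma_mount_deg: float = 2.0    # deg, per axis, one draw per trial
    soft_tissue_amp: float = 0.0    # m/s^2; 0 disables
    soft_tissue_f0: float = 10.0    # Hz
    soft_tissue_zeta: float = 0.3   # damping ratio

    def __post_init__(self) -> None:
        for name in ("sigma_gyro", "sigma_acc", "sigma_mount_deg", "soft_tissue_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


def simulate_imu(poses: PoseTrajectory, mounts: list[SensorMount],
                 fs_out: float | None = None) -> list[IMUTrace]:
    """Simulate the four virtual IMUs from a pose trajectory.

    Per mount, the gyroscope channel is the segment angular velocity
    expressed in the sensor frame and the accelerometer channel is the free
    acceleration of the mount point in the earth frame, optionally resampled
    to ``fs_out`` by cubic interpolation.
    """
    if fs_out is not None and not fs_out > 0:
        raise InputError("fs_out must be positive")
    traces = []
    for m in mounts:
        body = f"imu_{m.name}"
        if body not in poses.orientations:
            raise ConfigurationError(
                f"mount {m.name!r} (segment {m.segment!r}) absent from pose trajectory"
            )
        omega = body_angular_velocity(poses, body)
        R_s = Rotation.from_quat(poses.orientations[body])
        gyro = R_s.inv().apply(omega)
        acc = point_acceleration(poses, m.segment, np.asarray(m.position))
        t, fs = poses.time, poses.fs
        if fs_out is not None and abs(fs_out - poses.fs) > 1e-9:
            t_new = np.arange(int(np.floor((t[-1] - t[0]) * fs_out)) + 1) / fs_out + t[0]
            gyro = CubicSpline(t, gyro, axis=0)(t_new)
            acc = CubicSpline(t, acc, axis=0)(t_new)
            t, fs = t_new, fs_out
        traces.append(IMUTrace(m.name, t, gyro, acc, fs, provenance="simulated"))
    return traces


def emulate_measured(trace: IMUTrace, noise: NoiseParams,
                     rng_seed: int | np.random.Generator = 0,
                     heel_strike_times: np.ndarray | None = None) -> IMUTrace:
    """Turn a clean simulated trace into a measured-sensor stand-in.

    Adds per-channel white Gaussian noise, applies one random mount
    misalignment rotation per trial (N(0, sigma_mount_deg) per axis) to both
    channel triplets, and optionally injects an exponentially damped
    oscillation into the acceleration at each heel strike (soft-tissue
    artifact).  Deterministic under the seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    gyro, acc = trace.gyro.copy(), trace.acc.copy()
    if noise.sigma_mount_deg > 0:
        mis = Rotation.from_euler(
            "xyz", rng.normal(0.0, noise.sigma_mount_deg, 3), degrees=True
        )
        gyro = mis.inv().apply(gyro)
        acc = mis.inv().apply(acc)
    if noise.soft_tissue_amp > 0 and heel_strike_times is not None:
        wn = 2 * np.pi * noise.soft_tissue_f0
        wd = wn * np.sqrt(1 - noise.soft_tissue_zeta**2)
        for ths in np.atleast_1d(heel_strike_times):
            dt = trace.time - ths
            m = dt >= 0
            ring = noise.soft_tissue_amp * np.exp(-noise.soft_tissue_zeta * wn * dt[m]) * np.sin(wd * dt[m])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            acc[m] += ring[:, None] * direction
    if noise.sigma_gyro > 0:
        gyro = gyro + rng.normal(0.0, noise.sigma_gyro, gyro.shape)
    if noise.sigma_acc > 0:
        acc = acc + rng.normal(0.0, noise.sigma_acc, acc.shape)
    return replace(trace, gyro=gyro, acc=acc, provenance="measured_emulated")
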