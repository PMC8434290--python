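"""Finite-difference cross-checks for the differential kinematics.

These routines recompute angular velocity and point acceleration along a
different numerical path than the production code (orientation-difference
quotients and a global dense position spline, versus recursive joint-rate
propagation and local stencils), so agreement between the two is a real
consistency check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .trial import InputError, PoseTrajectory

_H = 5e-4  # s; half-step of the central difference (1 kHz effective)


def fd_angular_velocity(poses: PoseTrajectory, body: str,
                        h: float = _H) -> np.ndarray:
    """Earth-frame angular velocity from orientation difference quotients.

    Interior samples use the axis-angle of R(t+h) R(t-h)^T over 2h; edge
    samples a second-order one-sided (Richardson) variant.
    """
    src = poses._source
    if src is None:
        raise InputError("finite-difference oracle needs a kinematic source")
    t = poses.time

    def R_at(tq):
        return src.poses_at(tq)[body][0]

    inner = (t - h >= src.t0) & (t + h <= src.t1)
    omega = np.empty((len(t), 3))
    ti = t[inner]
    omega[inner] = (R_at(ti + h) * R_at(ti - h).inv()).as_rotvec() / (2 * h)
    for i in np.flatnonzero(~inner):
        s = 1.0 if t[i] - src.t0 < h else -1.0
        R0 = R_at(np.array([t[i]]))
        w1 = (R_at(np.array([t[i] + s * h])) * R0.inv()).as_rotvec() / (s * h)
        w2 = (R_at(np.array([t[i] + 2 * s * h])) * R0.inv()).as_rotvec() / (2 * s * h)
        omega[i] = 2 * w1[0] - w2[0]
    return omega


def fd_point_acceleration(poses: PoseTrajectory, body: str, local_point,
                          fs_dense: float = 1000.0) -> np.ndarray:
    """Acceleration as the second derivative of a dense global position
    spline (1 kHz resampling of the point's earth-frame path)."""
    src = poses._source
    if src is None:
        raise InputError("finite-difference oracle needs a kinematic source")
    td = np.arange(src.t0, src.t1 + 0.5 / fs_dense, 1.0 / fs_dense)
    td = np.clip(td, src.t0, src.t1)
    p = src.point_position(td, body, np.asarray(local_point, float))
    return CubicSpline(td, p, axis=0)(poses.time, 2)


def simulation_fidelity_table(poses: PoseTrajectory, mounts) -> pd.DataFrame:
    """Per-sensor, per-axis r and RMSE between the production IMU channels
    and their finite-difference recomputation (the synthetic analogue of a
    measured-versus-simulated sensor comparison)."""
    from .imu import simulate_imu

    traces = simulate_imu(poses, mounts)
    rows = []
    for m, tr in zip(mounts, traces):
        body = f"imu_{m.name}"
        R_s = Rotation.from_quat(poses.orientations[body])
        gyro_fd = R_s.inv().apply(fd_angular_velocity(poses, body))
        acc_fd = fd_point_acceleration(poses, m.segment, np.asarray(m.position))
        for kind, a, b in (("gyro", tr.gyro, gyro_fd), ("acc", tr.acc, acc_fd)):
            for ax in range(3):
                x, y = a[:, ax], b[:, ax]
                r = np.corrcoef(x, y)[0, 1] if x.std() > 1e-12 and y.std() > 1e-12 else np.nan
                rows.append(dict(
                    sensor=m.name, channel=f"{kind}_{'xyz'[ax]}",
                    r=r, rmse=float(np.sqrt(np.mean((x - y) ** 2))),
                    max_abs_err=float(np.abs(x - y).max()),
                ))
    return pd.DataFrame(rows)
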