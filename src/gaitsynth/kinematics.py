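"""Forward kinematics and rigid-body differential kinematics.

Joint-angle trajectories are represented internally as cubic splines, so
segment poses can be evaluated at arbitrary times and angular velocities
follow analytically from the spline derivatives by recursive propagation
down the chain (``omega_child = omega_parent + R_parent @ omega_rel``).
Accelerations follow the same analytic route: joint-angle spline second
derivatives propagated with the rigid-body recursion
``a_child = a_parent + alpha x r + omega x (omega x r)``, so velocity and
acceleration channels are exact derivatives of the interpolated motion
rather than finite-difference estimates.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline
from scipy.spatial.transform import Rotation, RotationSpline

from .chain import (
    HIP_SIGNS,
    KNEE_SIGNS,
    JOINT_COLUMNS,
    ConfigurationError,
    LimbChain,
    SensorMount,
    default_mounts,
    joint_rotation,
    hinge_rotation,
)
from .trial import InputError, KinematicTrial, PoseTrajectory

# internal differentiation step: fine enough that the jerk discontinuities
# at the 100 Hz spline knots of typical gait data cost < 1e-2 m/s^2
_FD_STEP = 2e-5  # s

# unit vectors of the intrinsic Y-X-Z joint rotation axes
_EY = np.array([0.0, 1.0, 0.0])
_EX = np.array([1.0, 0.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])


def _spline(t: np.ndarray, y: np.ndarray):
    k = min(3, len(t) - 1)
    if k == 3:
        return CubicSpline(t, y, axis=0)
    return make_interp_spline(t, y, k=k, axis=0)


class _FKSource:
    """Spline representation of a trial plus the chain/mount geometry."""

    def __init__(self, chain: LimbChain, trial: KinematicTrial,
                 mounts: list[SensorMount]):
        self.chain = chain
        self.mounts = mounts
        self.t0 = float(trial.time[0])
        self.t1 = float(trial.time[-1])
        self.angles = _spline(trial.time, np.deg2rad(trial.angles))
        self.pelvis_pos = _spline(trial.time, trial.pelvis_pos)
        self.pelvis_rot = RotationSpline(trial.time, Rotation.from_quat(trial.pelvis_quat))

    # -- pose evaluation ---------------------------------------------------
    def poses_at(self, times: np.ndarray) -> dict[str, tuple[Rotation, np.ndarray]]:
        times = np.asarray(times, dtype=float)
        a_deg = np.rad2deg(self.angles(times))
        ch = self.chain
        R_pelvis = self.pelvis_rot(times)
        p_pelvis = self.pelvis_pos(times)

        R_hip = joint_rotation(a_deg[:, 0:3], HIP_SIGNS)
        R_thigh = R_pelvis * R_hip
        p_thigh = p_pelvis + R_pelvis.apply(ch.proximal_offset("thigh"))

        R_knee = joint_rotation(a_deg[:, 3:6], KNEE_SIGNS)
        R_shank = R_thigh * R_knee
        p_shank = p_thigh + R_thigh.apply(ch.proximal_offset("shank"))

        R_foot = R_shank * hinge_rotation(a_deg[:, 6])
        p_foot = p_shank + R_shank.apply(ch.proximal_offset("foot"))

        out = {
            "pelvis": (R_pelvis, p_pelvis),
            "thigh": (R_thigh, p_thigh),
            "shank": (R_shank, p_shank),
            "foot": (R_foot, p_foot),
        }
        for m in self.mounts:
            R_seg, p_seg = out[m.segment]
            out[f"imu_{m.name}"] = (
                R_seg * m.rotation,
                p_seg + R_seg.apply(np.asarray(m.position)),
            )
        return out

    def point_position(self, times: np.ndarray, body: str,
                       local_point: np.ndarray) -> np.ndarray:
        poses = self.poses_at(times)
        if body not in poses:
            raise ConfigurationError(f"unknown body {body!r}")
        R, p = poses[body]
        return p + R.apply(local_point)

    # -- differential kinematics by recursive propagation ------------------
    def rigid_kinematics(self, times: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Per segment: earth-frame omega (rad/s), alpha (rad/s^2) and the
        free acceleration of the segment origin (m/s^2), all analytic.

        Propagation down the chain with the standard rigid-body recursions
          omega_c = omega_p + R_p w_rel
          alpha_c = alpha_p + R_p dw_rel + omega_p x (R_p w_rel)
          a_c     = a_p + alpha_p x r + omega_p x (omega_p x r),  r = R_p r_off
        where w_rel / dw_rel are the joint's relative angular velocity and
        acceleration expressed in the parent frame.
        """
        times = np.asarray(times, dtype=float)
        key = (times.shape, times.tobytes())
        cached = getattr(self, "_kin_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        a = self.angles(times)
        da = self.angles(times, 1)
        dda = self.angles(times, 2)
        signs = np.concatenate([HIP_SIGNS, KNEE_SIGNS, [-1.0]])
        b, db, ddb = a * signs, da * signs, dda * signs

        def joint_rel(bj, dbj, ddbj):
            """(w_rel, dw_rel) of an intrinsic Y-X-Z joint, parent frame."""
            R1 = Rotation.from_euler("y", bj[:, [0]])
            R12 = R1 * Rotation.from_euler("x", bj[:, [1]])
            w1 = dbj[:, [0]] * _EY
            w2 = R1.apply(dbj[:, [1]] * _EX)
            w3 = R12.apply(dbj[:, [2]] * _EZ)
            dw = (
                ddbj[:, [0]] * _EY
                + R1.apply(ddbj[:, [1]] * _EX) + np.cross(w1, w2)
                + R12.apply(ddbj[:, [2]] * _EZ) + np.cross(w1 + w2, w3)
            )
            return w1 + w2 + w3, dw

        R_pelvis = self.pelvis_rot(times)
        out: dict[str, dict[str, np.ndarray]] = {}
        out["pelvis"] = dict(
            omega=R_pelvis.apply(self.pelvis_rot(times, 1)),
            alpha=R_pelvis.apply(self.pelvis_rot(times, 2)),
            acc=self.pelvis_pos(times, 2),
        )
        poses = self.poses_at(times)
        joints = {
            "thigh": ("pelvis", joint_rel(b[:, 0:3], db[:, 0:3], ddb[:, 0:3])),
            "shank": ("thigh", joint_rel(b[:, 3:6], db[:, 3:6], ddb[:, 3:6])),
            "foot": ("shank", (db[:, [6]] * _EY, ddb[:, [6]] * _EY)),
        }
        for child, (parent, (w_rel, dw_rel)) in joints.items():
            R_p, _ = poses[parent]
            par = out[parent]
            r = R_p.apply(self.chain.proximal_offset(child))
            out[child] = dict(
                omega=par["omega"] + R_p.apply(w_rel),
                alpha=par["alpha"] + R_p.apply(dw_rel)
                      + np.cross(par["omega"], R_p.apply(w_rel)),
                acc=par["acc"] + np.cross(par["alpha"], r)
                    + np.cross(par["omega"], np.cross(par["omega"], r)),
            )
        self._kin_cache = (key, out)
        return out

    def angular_velocity(self, times: np.ndarray, body: str) -> np.ndarray:
        return self.rigid_kinematics(times)[self._segment_of(body)]["omega"]

    def point_acceleration(self, times: np.ndarray, body: str,
                           local_point: np.ndarray) -> np.ndarray:
        seg = self._segment_of(body)
        local_point = np.asarray(local_point, dtype=float)
        if body != seg:  # sensor body: express the point in the segment frame
            m = next(m for m in self.mounts if f"imu_{m.name}" == body)
            local_point = np.asarray(m.position) + m.rotation.apply(local_point)
        kin = self.rigid_kinematics(times)[seg]
        if not np.any(local_point):
            return kin["acc"]
        poses = self.poses_at(times)
        r = poses[seg][0].apply(local_point)
        return (kin["acc"] + np.cross(kin["alpha"], r)
                + np.cross(kin["omega"], np.cross(kin["omega"], r)))

    def _segment_of(self, body: str) -> str:
        if body in ("pelvis", "thigh", "shank", "foot"):
            return body
        for m in self.mounts:
            if f"imu_{m.name}" == body:
                return m.segment
        raise ConfigurationError(f"unknown body {body!r}")


def forward_kinematics(chain: LimbChain, trial: KinematicTrial,
                       mounts: list[SensorMount] | None = None) -> PoseTrajectory:
    """Earth-frame poses of all segments and sensor mounts at every sample.

    Hip and knee rotations are applied as intrinsic Euler sequences
    (flexion, then ad-abduction, then axial rotation); the ankle is a hinge.
    Sensor poses are the segment poses composed with the rigid mount offsets.
    """
    if trial.angles.shape[1] != chain.n_dof:
        raise ConfigurationError(
            f"trial has {trial.angles.shape[1]} DoF, chain expects {chain.n_dof}"
        )
    mounts = default_mounts() if mounts is None else mounts
    src = _FKSource(chain, trial, mounts)
    poses = src.poses_at(trial.time)
    return PoseTrajectory(
        time=trial.time.copy(),
        orientations={b: R.as_quat() for b, (R, _) in poses.items()},
        positions={b: p.copy() for b, (_, p) in poses.items()},
        fs=trial.fs,
        _source=src,
    )


def body_angular_velocity(poses: PoseTrajectory, body: str) -> np.ndarray:
    """Earth-frame angular velocity of ``body`` (rad/s), one row per sample.

    Computed by recursive propagation along the chain from the joint-angle
    spline rates; for pose trajectories without a kinematic source (e.g.
    loaded from file) it falls back to a rotation-spline derivative of the
    stored orientations.
    """
    if len(poses) < 5:
        raise InputError("angular velocity needs at least 5 samples")
    if poses._source is not None:
        return poses._source.angular_velocity(poses.time, body)
    if body not in poses.orientations:
        raise ConfigurationError(f"unknown body {body!r}")
    rs = RotationSpline(poses.time, Rotation.from_quat(poses.orientations[body]))
    return rs(poses.time).apply(rs(poses.time, 1))


# five-point second-derivative stencils (offsets in units of h)
_STENCILS = {
    (-2, -1, 0, 1, 2): np.array([-1, 16, -30, 16, -1]) / 12.0,
    (0, 1, 2, 3, 4): np.array([35, -104, 114, -56, 11]) / 12.0,
    (-1, 0, 1, 2, 3): np.array([11, -20, 6, 4, -1]) / 12.0,
    (-3, -2, -1, 0, 1): np.array([-1, 4, 6, -20, 11]) / 12.0,
    (-4, -3, -2, -1, 0): np.array([11, -56, 114, -104, 35]) / 12.0,
}


def _second_derivative(f, times: np.ndarray, t0: float, t1: float,
                       h: float = _FD_STEP) -> np.ndarray:
    """d2/dt2 of a vector function via 5-point stencils, one-sided at edges."""
    out = np.empty((len(times), 3))
    groups: dict[tuple, list[int]] = {}
    for i, t in enumerate(times):
        lo = int(np.ceil(np.round((t0 - t) / h, 9)))
        hi = int(np.floor(np.round((t1 - t) / h, 9)))
        off = next(o for o in _STENCILS if o[0] >= lo and o[-1] <= hi)
        groups.setdefault(off, []).append(i)
    for off, idx in groups.items():
        idx = np.asarray(idx)
        tq = (times[idx][:, None] + np.asarray(off) * h).ravel()
        vals = f(tq).reshape(len(idx), 5, 3)
        out[idx] = np.einsum("s,nsd->nd", _STENCILS[off], vals) / h**2
    return out


def point_acceleration(poses: PoseTrajectory, body: str,
                       local_point) -> np.ndarray:
    """Free (gravity-less) earth-frame acceleration of a body-fixed point.

    The second time derivative of the point's earth-frame position; gravity
    is deliberately excluded.  Analytic (recursive rigid-body propagation)
    when the trajectory carries its kinematic source; finite differences of
    the stored pose samples otherwise.
    """
    if len(poses) < 7:
        raise InputError("point acceleration needs at least 7 samples")
    local_point = np.asarray(local_point, dtype=float)
    if not np.all(np.isfinite(local_point)):
        raise InputError("local point must be finite")
    t = poses.time
    if poses._source is not None:
        return poses._source.point_acceleration(t, body, local_point)
    if float(t[-1] - t[0]) < 9 * _FD_STEP:
        raise InputError("trial too short for stable second derivatives")
    if body not in poses.orientations:
        raise ConfigurationError(f"unknown body {body!r}")
    rs = RotationSpline(t, Rotation.from_quat(poses.orientations[body]))
    ps = _spline(t, poses.positions[body])
    f = lambda tq: ps(tq) + rs(tq).apply(local_point)
    return _second_derivative(f, t, float(t[0]), float(t[-1]))


def heel_trajectory(poses: PoseTrajectory, chain: LimbChain) -> np.ndarray:
    """Earth-frame heel-point position (n, 3); input to heel-strike detection."""
    if "foot" not in poses.orientations:
        raise ConfigurationError("pose trajectory has no foot body")
    R = Rotation.from_quat(poses.orientations["foot"])
    return poses.positions["foot"] + R.apply(np.asarray(chain.heel_offset))
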