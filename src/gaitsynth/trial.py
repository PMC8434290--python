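"""Kinematic trial and pose trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .chain import JOINT_COLUMNS


class InputError(ValueError):
    """Raised for invalid trial / signal inputs."""


@dataclass
class KinematicTrial:
    """One (possibly multi-stride) gait trial on a uniform time base.

    ``angles`` is (n, 7) in degrees with columns ordered as
    :data:`gaitsynth.chain.JOINT_COLUMNS`; the pelvis root pose (earth frame)
    rides along so that forward kinematics can be run on the trial alone.
    ``heel_strikes`` holds ground-truth heel-strike sample indices when the
    trial came from the cohort generator.
    """

    time: np.ndarray
    angles: np.ndarray
    pelvis_pos: np.ndarray
    pelvis_quat: np.ndarray  # scalar-last (x, y, z, w)
    fs: float
    subject_id: str = "s0"
    speed: str = "self_selected"
    heel_strikes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.pelvis_pos = np.asarray(self.pelvis_pos, dtype=float)
        self.pelvis_quat = np.asarray(self.pelvis_quat, dtype=float)
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        n = len(self.time)
        if self.angles.shape != (n, len(JOINT_COLUMNS)):
            raise InputError(
                f"angles must be (n, {len(JOINT_COLUMNS)}), got {self.angles.shape}"
            )
        if self.pelvis_pos.shape != (n, 3) or self.pelvis_quat.shape != (n, 4):
            raise InputError("pelvis pose shape mismatch")
        if not self.fs > 0:
            raise InputError("sampling rate must be positive")
        if n >= 2:
            dt = np.diff(self.time)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InputError("time base must be strictly increasing and uniform")
        for arr, what in ((self.angles, "angles"), (self.pelvis_pos, "pelvis position")):
            if not np.all(np.isfinite(arr)):
                raise InputError(f"non-finite values in {what}")
        norms = np.linalg.norm(self.pelvis_quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InputError("pelvis quaternions must be unit norm (1e-9)")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def copy_with(self, **changes) -> "KinematicTrial":
        out = replace(self, **{k: v for k, v in changes.items() if k != "meta"})
        out.meta = dict(changes.get("meta", self.meta))
        return out

    @classmethod
    def static(cls, n: int = 100, fs: float = 100.0, angles_deg=None,
               subject_id: str = "s0") -> "KinematicTrial":
        """A motionless trial at a fixed joint configuration (default neutral)."""
        t = np.arange(n) / fs
        a = np.zeros((n, 7)) if angles_deg is None else np.tile(np.asarray(angles_deg, float), (n, 1))
        return cls(
            time=t, angles=a, pelvis_pos=np.zeros((n, 3)),
            pelvis_quat=np.tile([0.0, 0.0, 0.0, 1.0], (n, 1)), fs=fs,
            subject_id=subject_id,
        )


@dataclass
class PoseTrajectory:
    """Earth-frame pose time series for each body (segments and sensors).

    ``orientations[body]`` is an (n, 4) scalar-last quaternion array and
    ``positions[body]`` an (n, 3) array.  When produced by
    :func:`gaitsynth.kinematics.forward_kinematics` a private handle to the
    source splines is retained so that angular velocities and accelerations
    can be evaluated analytically.
    """

    time: np.ndarray
    orientations: dict[str, np.ndarray]
    positions: dict[str, np.ndarray]
    fs: float
    _source: Any = None

    def bodies(self) -> list[str]:
        return list(self.orientations)

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self):
        """Flatten to a pandas DataFrame (one row per sample, named columns)."""
        import pandas as pd

        data = {"time": self.time}
        for body in self.orientations:
            p, q = self.positions[body], self.orientations[body]
            for i, ax in enumerate("xyz"):
                data[f"{body}_p{ax}"] = p[:, i]
            for i, comp in enumerate(("qx", "qy", "qz", "qw")):
                data[f"{body}_{comp}"] = q[:, i]
        return pd.DataFrame(data)
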