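"""Rigid-body lower-limb chain and sensor mount definitions.

The model is a serial left-limb chain pelvis -> thigh -> shank -> foot.
Hip and knee carry three rotational degrees of freedom each, the ankle is a
single hinge, for seven joint DoF total.  Every segment frame has its origin
at the proximal joint centre and, in the neutral (zero-angle) pose, is
aligned with the earth frame: X anterior (walking direction), Y left,
Z up, with the distal joint centre at (0, 0, -L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

#: fixed joint-angle column order used throughout the package
JOINT_COLUMNS = (
    "hip_flex",
    "hip_add",
    "hip_rot",
    "knee_flex",
    "knee_add",
    "knee_rot",
    "ankle_flex",
)

#: serial chain topology
SEGMENTS = ("pelvis", "thigh", "shank", "foot")

# Intrinsic Euler sequence for the 3-DoF joints: flexion about the
# mediolateral axis first, then ad-abduction about the anterior axis, then
# axial rotation about the longitudinal axis.  Signs are chosen for the left
# limb so that positive hip flexion moves the thigh anteriorly while
# positive knee flexion folds the shank posteriorly.
EULER_SEQ = "YXZ"
HIP_SIGNS = np.array([-1.0, -1.0, -1.0])
KNEE_SIGNS = np.array([1.0, -1.0, -1.0])
EULER_SIGNS = HIP_SIGNS  # default clinical sign convention


def joint_rotation(angles_deg: np.ndarray, signs: np.ndarray = EULER_SIGNS) -> Rotation:
    """Rotation of a 3-DoF joint from (flex, add, rot) clinical angles.

    ``angles_deg`` has shape (3,) or (n, 3); returns the matching Rotation
    (possibly a stack).
    """
    a = np.atleast_2d(np.asarray(angles_deg, dtype=float)) * signs
    rot = Rotation.from_euler(EULER_SEQ, a, degrees=True)
    if np.asarray(angles_deg).ndim == 1:
        return rot[0] if len(rot) == 1 else rot
    return rot


def joint_angles_from_rotation(rot: Rotation, signs: np.ndarray = EULER_SIGNS) -> np.ndarray:
    """Inverse of :func:`joint_rotation`; returns degrees, shape (n, 3)."""
    return np.atleast_2d(rot.as_euler(EULER_SEQ, degrees=True)) * signs


def hinge_rotation(angle_deg: np.ndarray) -> Rotation:
    """Ankle hinge: dorsiflexion about the mediolateral axis."""
    a = np.atleast_1d(np.asarray(angle_deg, dtype=float))
    return Rotation.from_euler("y", -a[:, None], degrees=True)


class ConfigurationError(ValueError):
    """Raised for invalid chain / mount / model configuration."""


@dataclass(frozen=True)
class LimbChain:
    """Anthropometric left lower-limb chain (lengths in metres)."""

    pelvis_half_width: float = 0.12
    thigh_length: float = 0.42
    shank_length: float = 0.41
    foot_length: float = 0.25
    heel_offset: tuple[float, float, float] = (-0.06, 0.0, -0.08)

    def __post_init__(self) -> None:
        for name in ("pelvis_half_width", "thigh_length", "shank_length", "foot_length"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def n_dof(self) -> int:
        return 7

    def proximal_offset(self, segment: str) -> np.ndarray:
        """Offset of a segment's proximal joint centre in its parent frame."""
        if segment == "thigh":  # left hip centre
            return np.array([0.0, self.pelvis_half_width, 0.0])
        if segment == "shank":  # knee centre
            return np.array([0.0, 0.0, -self.thigh_length])
        if segment == "foot":  # ankle centre
            return np.array([0.0, 0.0, -self.shank_length])
        raise ConfigurationError(f"unknown segment {segment!r}")


@dataclass(frozen=True)
class SensorMount:
    """Rigid IMU attachment: position and orientation in the segment frame."""

    segment: str
    position: tuple[float, float, float]
    orientation: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0)  # xyzw
    name: str = ""

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ConfigurationError(f"unknown segment {self.segment!r}")
        q = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            raise ConfigurationError("mount orientation quaternion must be unit norm")
        if not self.name:
            object.__setattr__(self, "name", self.segment)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)


def default_mounts() -> list[SensorMount]:
    """Default 4-sensor configuration: posterior pelvis, lateral thigh and
    shank, dorsal foot.  Placements are package defaults, with small fixed
    mounting rotations so sensor frames do not trivially coincide with
    segment frames."""
    rot = lambda seq, ang: tuple(Rotation.from_euler(seq, ang, degrees=True).as_quat())
    return [
        SensorMount("pelvis", (-0.10, 0.0, 0.02), rot("z", 180.0), "pelvis"),
        SensorMount("thigh", (0.0, 0.09, -0.20), rot("x", -90.0), "thigh"),
        SensorMount("shank", (0.0, 0.05, -0.15), rot("x", -90.0), "shank"),
        SensorMount("foot", (0.08, 0.0, -0.05), rot("y", 10.0), "foot"),
    ]


def load_chain_config(path) -> tuple[LimbChain, list[SensorMount]]:
    """Read a chain + mounts definition from a YAML file.

    Mount orientations may be given as ``quat: [x, y, z, w]`` or
    ``euler_deg: [rx, ry, rz]`` (extrinsic xyz).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    chain = LimbChain(**cfg.get("chain", {}))
    mounts = []
    for m in cfg.get("mounts", []):
        if "euler_deg" in m:
            q = tuple(Rotation.from_euler("xyz", m.pop("euler_deg"), degrees=True).as_quat())
            m["orientation"] = q
        elif "quat" in m:
            m["orientation"] = tuple(m.pop("quat"))
        mounts.append(SensorMount(**m))
    return chain, mounts or default_mounts()
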