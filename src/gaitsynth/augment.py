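"""Kinematic augmentation operators for synthetic gait generation.

Five operators create new joint-angle trials from a source trial:

* ``magnitude_offset`` — one additive offset per trial, drawn from
  N(0 deg, 5 deg), applied to every sample of every joint-angle column;
* ``magnitude_warp`` — element-wise multiplication by a smooth distortion
  vector: a natural cubic spline through 7 knots drawn from N(1, 0.2),
  uniformly spaced over the cycle (endpoints included), shared across all
  columns;
* ``offset_and_warp`` — magnitude warp first, then offset;
* ``time_warp`` — resampling along a smooth monotone time map: the
  normalised cumulative sum of a 7-knot N(1, 0.2) spline;
* ``time_and_magnitude_warp`` — time warp first, then magnitude warp.

Augmented trials carry only new *kinematics*; the matching IMU signals are
regenerated downstream through the rigid-body model, never warped directly,
so every synthetic input/label pair stays physically consistent.  By design
there is no plausibility filter: draws that exceed physiological ranges are
kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation, Slerp

from .trial import InputError, KinematicTrial

METHODS = ("offset", "mag_warp", "offset+mag_warp", "time_warp", "time+mag_warp")


@dataclass(frozen=True)
class AugmentationParams:
    """Distribution parameters of the augmentation draws."""

    offset_mu: float = 0.0
    offset_sigma: float = 5.0   # degrees
    knot_mu: float = 1.0
    knot_sigma: float = 0.2
    n_knots: int = 7
    methods: tuple[str, ...] = METHODS
    per_column_offset: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offset_sigma < 0 or self.knot_sigma < 0:
            raise InputError("sigma values must be non-negative")
        if self.n_knots < 4:
            raise InputError("need at least 4 knots for a cubic spline")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise InputError(f"unknown augmentation methods {sorted(unknown)}")


def _distortion_vector(trial_time: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline through knots uniformly spaced (endpoints
    included) over the trial's time span, evaluated at the sample times."""
    knot_t = np.linspace(trial_time[0], trial_time[-1], len(knots))
    return CubicSpline(knot_t, knots, bc_type="natural")(trial_time)


def _draw_knots(rng: np.random.Generator, p: AugmentationParams) -> np.ndarray:
    return rng.normal(p.knot_mu, p.knot_sigma, p.n_knots)


def magnitude_offset(trial: KinematicTrial, rng: np.random.Generator,
                     params: AugmentationParams = AugmentationParams()) -> KinematicTrial:
    """Add one random offset (per trial, or per column if configured) to all
    joint angles; pelvis root pose is untouched."""
    n_draw = trial.angles.shape[1] if params.per_column_offset else 1
    delta = rng.normal(params.offset_mu, params.offset_sigma, n_draw)
    return trial.copy_with(
        angles=trial.angles + delta,
        meta={**trial.meta, "method": "offset", "offset_deg": delta},
    )


def magnitude_warp(trial: KinematicTrial, rng: np.random.Generator,
                   params: AugmentationParams = AugmentationParams()) -> KinematicTrial:
    """Multiply all joint-angle columns by one shared smooth distortion
    vector (spline through N(1, 0.2) knots)."""
    if len(trial) < params.n_knots:
        raise InputError("trial shorter than the knot count")
    knots = _draw_knots(rng, params)
    d = _distortion_vector(trial.time, knots)
    return trial.copy_with(
        angles=trial.angles * d[:, None],
        meta={**trial.meta, "method": "mag_warp", "knots": knots},
    )


def offset_and_warp(trial: KinematicTrial, rng: np.random.Generator,
                    params: AugmentationParams = AugmentationParams()) -> KinematicTrial:
    """Magnitude warp followed by magnitude offset (warp first, offset second,
    sharing one RNG stream sequentially)."""
    out = magnitude_warp(trial, rng, params)
    out = magnitude_offset(out, rng, params)
    out.meta["method"] = "offset+mag_warp"
    return out


def time_warp(trial: KinematicTrial, rng: np.random.Generator,
              params: AugmentationParams = AugmentationParams()) -> KinematicTrial:
    """Resample the trial along a smooth random monotone time map.

    A spline through 7 N(1, 0.2) knots is evaluated at the n sample
    positions; its cumulative sum divided by n gives the warped cycle
    fractions tau, clamped to [0, 1].  All joint columns *and* the pelvis
    root pose are resampled at tau on the original grid, so the warped trial
    keeps its sample count while gait events shift inside the cycle.
    """
    n = len(trial)
    if n < params.n_knots:
        raise InputError("trial shorter than the knot count")
    knots = _draw_knots(rng, params)
    s = _distortion_vector(trial.time, knots)
    tau = np.cumsum(s) / n
    # normalised original grid chosen so that s == 1 gives the identity map
    u = np.arange(1, n + 1) / n
    tau = np.clip(tau, u[0], u[-1])
    ang = CubicSpline(u, trial.angles, axis=0)(tau)
    pos = CubicSpline(u, trial.pelvis_pos, axis=0)(tau)
    quat = Slerp(u, Rotation.from_quat(trial.pelvis_quat))(tau).as_quat()
    return trial.copy_with(
        angles=ang, pelvis_pos=pos, pelvis_quat=quat,
        meta={**trial.meta, "method": "time_warp", "knots": knots, "tau": tau},
    )


def time_and_magnitude_warp(trial: KinematicTrial, rng: np.random.Generator,
                            params: AugmentationParams = AugmentationParams()) -> KinematicTrial:
    """Time warp followed by magnitude warp."""
    out = time_warp(trial, rng, params)
    out = magnitude_warp(out, rng, params)
    out.meta["method"] = "time+mag_warp"
    return out


_DISPATCH = {
    "offset": magnitude_offset,
    "mag_warp": magnitude_warp,
    "offset+mag_warp": offset_and_warp,
    "time_warp": time_warp,
    "time+mag_warp": time_and_magnitude_warp,
}


def augment_dataset(trials: list[KinematicTrial],
                    params: AugmentationParams = AugmentationParams()) -> list[KinematicTrial]:
    """Apply every enabled method once to every trial (default 5:1 ratio).

    Output order is (trial, method)-major and deterministic under the seed;
    each output is tagged with its method and source trial.
    """
    if not trials:
        raise InputError("no trials to augment")
    rng = np.random.default_rng(params.seed)
    out = []
    for i, trial in enumerate(trials):
        for method in params.methods:
            aug = _DISPATCH[method](trial, rng, params)
            aug.meta["source"] = trial.meta.get("cycle_id", i)
            aug.meta["provenance"] = "synthetic"
            out.append(aug)
    return out
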