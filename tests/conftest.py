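import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitsynth.chain import LimbChain, default_mounts
from gaitsynth.cohort import generate_cohort, subject_chains
from gaitsynth.preprocess import segment_cycles
from gaitsynth.trial import KinematicTrial


@pytest.fixture(scope="session")
def chain():
    return LimbChain()


@pytest.fixture(scope="session")
def mounts():
    return default_mounts()


def make_smooth_trial(seed: int, n: int = 220, fs: float = 100.0,
                      amp: float = 25.0) -> KinematicTrial:
    """Band-limited random 7-DoF trial with a moving pelvis root."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    angles = np.zeros((n, 7))
    for j in range(7):
        for f in (0.7, 1.3, 2.1):
            angles[:, j] += rng.uniform(0.2, 1.0) * amp * np.sin(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    pos = np.column_stack([
        1.2 * t + 0.02 * np.sin(2 * np.pi * 1.8 * t),
        0.02 * np.sin(2 * np.pi * 0.9 * t + 1.0),
        0.02 * np.sin(2 * np.pi * 1.8 * t + 0.3),
    ])
    euler = np.column_stack([
        3.0 * np.sin(2 * np.pi * 0.9 * t),
        2.0 * np.sin(2 * np.pi * 1.8 * t + 0.7),
        4.0 * np.sin(2 * np.pi * 0.9 * t + 1.4),
    ])
    quat = Rotation.from_euler("xyz", euler, degrees=True).as_quat()
    return KinematicTrial(time=t, angles=angles, pelvis_pos=pos,
                          pelvis_quat=quat, fs=fs, subject_id=f"r{seed}")


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 3 speeds x 2 trials of 5 strides, with ground truth."""
    return generate_cohort(n_subjects=3, trials_per_speed=2,
                           strides_per_trial=5, seed=42)


@pytest.fixture(scope="session")
def small_cycles(small_cohort):
    cycles = []
    for tr in small_cohort:
        cycles.extend(segment_cycles(tr, tr.meta["heel_z"]))
    return cycles


@pytest.fixture(scope="session")
def small_chains(small_cohort):
    return subject_chains(small_cohort)
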