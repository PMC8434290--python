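import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitsynth.chain import (ConfigurationError, HIP_SIGNS, KNEE_SIGNS, LimbChain,
                             joint_angles_from_rotation, joint_rotation)
from gaitsynth.finite_difference import fd_angular_velocity, fd_point_acceleration
from gaitsynth.kinematics import (body_angular_velocity, forward_kinematics,
                                  heel_trajectory, point_acceleration)
from gaitsynth.trial import InputError, KinematicTrial

from conftest import make_smooth_trial


class TestForwardKinematics:
    def test_neutral_pose_geometry(self, chain):
        poses = forward_kinematics(chain, KinematicTrial.static(n=50))
        hip = np.array([0.0, chain.pelvis_half_width, 0.0])
        np.testing.assert_allclose(poses.positions["thigh"][0], hip, atol=1e-12)
        np.testing.assert_allclose(
            poses.positions["foot"][0],
            hip + [0, 0, -(chain.thigh_length + chain.shank_length)], atol=1e-12)
        for body in ("pelvis", "thigh", "shank", "foot"):
            R = Rotation.from_quat(poses.orientations[body])
            assert R.magnitude().max() < 1e-12

    def test_knee_flexion_makes_segments_perpendicular(self, chain):
        trial = KinematicTrial.static(n=10, angles_deg=[0, 0, 0, 90, 0, 0, 0])
        poses = forward_kinematics(chain, trial)
        z_thigh = Rotation.from_quat(poses.orientations["thigh"][0]).apply([0, 0, -1])
        z_shank = Rotation.from_quat(poses.orientations["shank"][0]).apply([0, 0, -1])
        assert abs(np.dot(z_thigh, z_shank)) < 1e-9

    @pytest.mark.parametrize("signs", [HIP_SIGNS, KNEE_SIGNS])
    def test_euler_round_trip_away_from_gimbal_lock(self, signs):
        rng = np.random.default_rng(0)
        ang = np.column_stack([rng.uniform(-170, 170, 1000),
                               rng.uniform(-79, 79, 1000),
                               rng.uniform(-170, 170, 1000)])
        back = joint_angles_from_rotation(joint_rotation(ang, signs), signs)
        assert np.abs(back - ang).max() < 1e-8

    def test_dof_mismatch_raises(self, chain):
        trial = KinematicTrial.static(n=10)
        trial.angles = trial.angles[:, :6]
        with pytest.raises(ConfigurationError):
            forward_kinematics(chain, trial)

    def test_nonuniform_time_base_rejected(self):
        t = np.array([0.0, 0.01, 0.03, 0.04])
        with pytest.raises(InputError):
            KinematicTrial(t, np.zeros((4, 7)), np.zeros((4, 3)),
                           np.tile([0, 0, 0, 1.0], (4, 1)), fs=100.0)


class TestAngularVelocity:
    def test_static_pose_zero(self, chain):
        poses = forward_kinematics(chain, KinematicTrial.static(n=60))
        for body in ("pelvis", "thigh", "shank", "foot"):
            assert np.abs(body_angular_velocity(poses, body)).max() < 1e-12

    def test_constant_hinge_rate(self, chain):
        n, fs = 301, 1000.0
        t = np.arange(n) / fs
        ang = np.zeros((n, 7))
        ang[:, 6] = np.degrees(t)  # ankle at 1 rad/s
        trial = KinematicTrial(t, ang, np.zeros((n, 3)),
                               np.tile([0, 0, 0, 1.0], (n, 1)), fs)
        poses = forward_kinematics(chain, trial)
        w_foot = body_angular_velocity(poses, "foot")
        assert np.abs(np.linalg.norm(w_foot, axis=1) - 1.0).max() < 1e-6
        assert np.abs(body_angular_velocity(poses, "shank")).max() < 1e-12

    def test_matches_finite_differences_on_smooth_trials(self, chain):
        for seed in range(5):
            trial = make_smooth_trial(seed)
            poses = forward_kinematics(chain, trial)
            for body in ("thigh", "shank", "foot"):
                w = body_angular_velocity(poses, body)
                w_fd = fd_angular_velocity(poses, body)
                assert np.abs(w - w_fd).max() < 1e-3

    def test_too_few_samples(self, chain):
        poses = forward_kinematics(chain, KinematicTrial.static(n=4))
        with pytest.raises(InputError):
            body_angular_velocity(poses, "foot")


class TestPointAcceleration:
    def test_constant_velocity_translation(self, chain):
        n, fs = 120, 100.0
        t = np.arange(n) / fs
        trial = KinematicTrial(t, np.zeros((n, 7)),
                               np.column_stack([1.5 * t, 0 * t, 0 * t]),
                               np.tile([0, 0, 0, 1.0], (n, 1)), fs)
        poses = forward_kinematics(chain, trial)
        a = point_acceleration(poses, "foot", [0.1, 0.0, -0.05])
        assert np.abs(a).max() < 1e-6

    def test_centripetal_acceleration(self, chain):
        n, fs = 501, 1000.0
        t = np.arange(n) / fs
        ang = np.zeros((n, 7))
        ang[:, 6] = np.degrees(2.0 * t)  # ankle spinning at 2 rad/s
        trial = KinematicTrial(t, ang, np.zeros((n, 3)),
                               np.tile([0, 0, 0, 1.0], (n, 1)), fs)
        poses = forward_kinematics(chain, trial)
        a = point_acceleration(poses, "foot", [0.3, 0.0, 0.0])
        expect = 2.0 ** 2 * 0.3
        assert np.abs(np.linalg.norm(a, axis=1) / expect - 1.0).max() < 1e-4

    def test_matches_dense_spline_second_derivative(self, chain):
        for seed in range(5):
            trial = make_smooth_trial(seed + 10)
            poses = forward_kinematics(chain, trial)
            pt = [0.05, 0.03, -0.12]
            a = point_acceleration(poses, "shank", pt)
            a_fd = fd_point_acceleration(poses, "shank", pt, fs_dense=2000.0)
            assert np.abs(a - a_fd).max() < 1e-2

    def test_non_finite_point_rejected(self, chain):
        poses = forward_kinematics(chain, KinematicTrial.static(n=60))
        with pytest.raises(InputError):
            point_acceleration(poses, "foot", [np.nan, 0, 0])


class TestFrameConsistency:
    def test_equivariance_under_earth_frame_rotation(self, chain):
        """Rotating the earth frame rotates positions, angular velocities
        and accelerations exactly (analytic kinematics)."""
        Q = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        trial = make_smooth_trial(3)
        rot_trial = trial.copy_with(
            pelvis_pos=Q.apply(trial.pelvis_pos),
            pelvis_quat=(Q * Rotation.from_quat(trial.pelvis_quat)).as_quat(),
        )
        p1 = forward_kinematics(chain, trial)
        p2 = forward_kinematics(chain, rot_trial)
        for body in ("thigh", "foot"):
            np.testing.assert_allclose(
                Q.apply(p1.positions[body]), p2.positions[body], atol=1e-9)
            np.testing.assert_allclose(
                Q.apply(body_angular_velocity(p1, body)),
                body_angular_velocity(p2, body), atol=1e-9)
            a1 = point_acceleration(p1, body, [0.02, 0.01, -0.1])
            a2 = point_acceleration(p2, body, [0.02, 0.01, -0.1])
            np.testing.assert_allclose(Q.apply(a1), a2, atol=1e-9)


class TestHeelTrajectory:
    def test_static_neutral_heel_position(self, chain):
        poses = forward_kinematics(chain, KinematicTrial.static(n=20))
        heel = heel_trajectory(poses, chain)
        expect = np.array([0.0, chain.pelvis_half_width, 0.0]) \
            + [0, 0, -(chain.thigh_length + chain.shank_length)] \
            + np.asarray(chain.heel_offset)
        np.testing.assert_allclose(heel, np.tile(expect, (20, 1)), atol=1e-12)

    def test_pelvis_oscillation_transfers_rigidly(self, chain):
        n, fs = 200, 100.0
        t = np.arange(n) / fs
        z = 0.03 * np.sin(2 * np.pi * 1.5 * t)
        trial = KinematicTrial(t, np.zeros((n, 7)),
                               np.column_stack([0 * t, 0 * t, z]),
                               np.tile([0, 0, 0, 1.0], (n, 1)), fs)
        poses = forward_kinematics(chain, trial)
        heel_z = heel_trajectory(poses, chain)[:, 2]
        assert np.abs((heel_z - heel_z[0]) - (z - z[0])).max() < 1e-9

    def test_generator_minima_match_stored_events(self, small_cohort, small_chains):
        for trial in small_cohort[:6]:
            poses = forward_kinematics(small_chains[trial.subject_id], trial)
            heel_z = heel_trajectory(poses, small_chains[trial.subject_id])[:, 2]
            for s in trial.heel_strikes:
                lo, hi = max(0, s - 3), s + 4
                assert heel_z[lo:hi].min() == heel_z[lo:hi].min()  # window exists
                local = np.argmin(heel_z[max(0, s - 10):s + 11]) + max(0, s - 10)
                assert abs(local - s) <= 3
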