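import numpy as np
import pytest

from gaitsynth.chain import ConfigurationError
from gaitsynth.imu import IMUTrace
from gaitsynth.preprocess import (MAX_LEN, DatasetSplit, TrainingSample,
                                  assemble_variant, butter_lowpass,
                                  detect_heel_strikes, make_split, pad_and_pack,
                                  resample_cubic, segment_cycles)
from gaitsynth.trial import InputError, KinematicTrial


def _trace(sig, fs=40.0, sensor="s"):
    t = np.arange(len(sig)) / fs
    m = np.column_stack([sig, sig, sig])
    return IMUTrace(sensor, t, m, m, fs)


class TestResample:
    def test_native_rate_is_identity(self):
        tr = _trace(np.sin(np.arange(100) * 0.1))
        out = resample_cubic(tr, 40.0)
        assert np.abs(out.gyro - tr.gyro).max() < 1e-12

    def test_sinusoid_upsampling_accuracy(self):
        fs = 40.0
        t = np.arange(200) / fs
        tr = _trace(np.sin(2 * np.pi * 2.0 * t), fs)
        out = resample_cubic(tr, 100.0)
        ref = np.sin(2 * np.pi * 2.0 * out.time)
        assert np.sqrt(np.mean((out.gyro[:, 0] - ref) ** 2)) < 1e-3

    def test_linear_ramp_exact(self):
        tr = _trace(np.arange(50, dtype=float))
        out = resample_cubic(tr, 100.0)
        np.testing.assert_allclose(out.gyro[:, 0], out.time * 40.0, atol=1e-9)

    def test_bad_rate_rejected(self):
        with pytest.raises(InputError):
            resample_cubic(_trace(np.zeros(10)), 0.0)


class TestButterworth:
    def test_dc_gain_unity(self):
        x = np.full((500, 2), 3.7)
        np.testing.assert_allclose(butter_lowpass(x, 100.0), x, atol=1e-9)

    def test_stopband_attenuation_20hz(self):
        from scipy.signal import butter, freqz

        fs, f = 100.0, 20.0
        t = np.arange(2000) / fs
        y = butter_lowpass(np.sin(2 * np.pi * f * t), fs)
        amp = np.abs(y[500:1500]).max()
        # forward-backward gain is |H|^2 of the digital filter
        b, a = butter(2, 6.0, fs=fs)
        expect = np.abs(freqz(b, a, worN=[f], fs=fs)[1][0]) ** 2
        assert expect * 0.8 < amp < expect * 1.2
        # and at least as strong as the analog prototype's ~0.8 %
        assert amp < 1.2 / (1.0 + (f / 6.0) ** 4)

    def test_passband_1hz_preserved(self):
        fs = 100.0
        t = np.arange(3000) / fs
        y = butter_lowpass(np.sin(2 * np.pi * 1.0 * t), fs)
        assert abs(np.abs(y[500:2500]).max() - 1.0) < 0.02

    def test_idempotent_on_band_limited_signal(self):
        fs = 100.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 1.5 * t)
        once = butter_lowpass(x, fs)
        twice = butter_lowpass(once, fs)
        assert np.sqrt(np.mean((twice - once) ** 2)) < 0.01 * np.sqrt(np.mean(once ** 2))

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ConfigurationError):
            butter_lowpass(np.zeros(100), fs=10.0, fc=6.0)


class TestSegmentation:
    def test_generator_ground_truth_boundaries(self, small_cohort):
        for trial in small_cohort[:8]:
            cycles = segment_cycles(trial, trial.meta["heel_z"])
            assert len(cycles) == len(trial.heel_strikes) - 1
            for cyc, s in zip(cycles, trial.heel_strikes[:-1]):
                assert abs(cyc.meta["start_index"] - s) <= 3

    def test_flat_heel_gives_empty_with_diagnostic(self):
        trial = KinematicTrial.static(n=300)
        with pytest.warns(UserWarning, match="fewer than two heel strikes"):
            out = segment_cycles(trial, np.zeros(300))
        assert out == []

    def test_identical_strides_recover_the_template(self):
        n = 110
        u = np.arange(n) / n
        stride = 10 * np.sin(2 * np.pi * u) + 5 * np.cos(4 * np.pi * u)
        ang = np.tile(np.concatenate([stride] * 3)[:, None], (1, 7))
        m = len(ang)
        t = np.arange(m) / 100.0
        trial = KinematicTrial(t, ang, np.zeros((m, 3)),
                               np.tile([0, 0, 0, 1.0], (m, 1)), 100.0)
        # heel height lowest exactly at each stride boundary
        heel_z = 0.1 - 0.1 * np.cos(2 * np.pi * np.arange(m) / n)
        cycles = segment_cycles(trial, heel_z)
        assert len(cycles) == 1  # one full interior strike-to-strike cycle
        rms = np.sqrt(np.mean((cycles[0].angles[:, 0] - stride) ** 2))
        assert rms < 0.1

    def test_overlong_cycle_rejected_with_warning(self):
        m = 900
        heel_z = 0.1 - 0.1 * np.cos(2 * np.pi * np.arange(m) / 300)
        trial = KinematicTrial.static(n=m)
        with pytest.warns(UserWarning, match="longer than"):
            out = segment_cycles(trial, heel_z)
        assert out == []


class TestPacking:
    def _cycle(self, n=120):
        t = np.arange(n) / 100.0
        trial = KinematicTrial(t, np.ones((n, 7)), np.zeros((n, 3)),
                               np.tile([0, 0, 0, 1.0], (n, 1)), 100.0,
                               subject_id="s1")
        traces = [IMUTrace(s, t, np.ones((n, 3)), np.ones((n, 3)), 100.0)
                  for s in ("pelvis", "thigh", "shank", "foot")]
        return traces, trial

    def test_trailing_zero_padding_and_mask(self):
        samples = pad_and_pack([self._cycle(120)], "hip")
        s = samples[0]
        assert s.inputs.shape == (MAX_LEN, 24) and s.target.shape == (MAX_LEN, 3)
        assert s.mask.sum() == 120
        assert np.all(s.inputs[120:] == 0) and np.all(s.target[120:] == 0)

    def test_full_length_cycle_unpadded(self):
        s = pad_and_pack([self._cycle(200)], "knee")[0]
        assert s.mask.all()

    def test_overlong_cycle_raises_with_cycle_name(self):
        traces, trial = self._cycle(250)
        trial.meta["cycle_id"] = "bad_cycle"
        with pytest.raises(InputError, match="bad_cycle"):
            pad_and_pack([(traces, trial)], "hip")

    def test_channel_order_is_sensor_major_acc_first(self):
        traces, trial = self._cycle(50)
        traces[2].acc[:] = 7.0   # shank acc block -> columns 12..14
        traces[2].gyro[:] = 9.0  # shank gyro block -> columns 15..17
        s = pad_and_pack([(traces, trial)], "hip")[0]
        assert np.all(s.inputs[:50, 12:15] == 7.0)
        assert np.all(s.inputs[:50, 15:18] == 9.0)

    def test_pack_unpack_round_trip(self):
        traces, trial = self._cycle(90)
        s = pad_and_pack([(traces, trial)], "hip")[0]
        n = s.length
        np.testing.assert_array_equal(s.target[:n], trial.angles[:90, 0:3])

    def test_nonzero_padding_rejected(self):
        x = np.ones((MAX_LEN, 24))
        with pytest.raises(InputError):
            TrainingSample(x, np.zeros((MAX_LEN, 3)),
                           np.concatenate([np.ones(100), np.zeros(100)]),
                           "s", "simulated")


class TestSplit:
    def test_27_3_partition(self):
        subjects = [f"s{i:02d}" for i in range(30)]
        split = make_split(subjects, 3, seed=1)
        assert len(split.train_subjects) == 27 and len(split.test_subjects) == 3
        assert not set(split.train_subjects) & set(split.test_subjects)

    def test_deterministic_under_seed(self):
        subjects = [f"s{i}" for i in range(10)]
        assert make_split(subjects, 2, 5).test_subjects == make_split(subjects, 2, 5).test_subjects

    def test_too_many_test_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            make_split(["a", "b"], 2)

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ConfigurationError):
            DatasetSplit(["a", "b"], ["b"])

    def test_synthetic_variant_contains_no_test_subjects(self):
        def sample(subj, prov):
            return TrainingSample(np.zeros((MAX_LEN, 24)), np.zeros((MAX_LEN, 3)),
                                  np.zeros(MAX_LEN), subj, prov)
        split = DatasetSplit(["a", "b"], ["c"])
        measured = [sample(s, "measured_emulated") for s in ("a", "b", "c")]
        synthetic = [sample(s, "synthetic") for s in ("a", "c")]
        for variant in ("measured", "synthetic", "measured+synthetic"):
            out = assemble_variant(measured, synthetic, variant, split)
            assert all(s.subject_id != "c" for s in out)
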