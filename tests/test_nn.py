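import numpy as np
import pytest

from gaitsynth.chain import ConfigurationError
from gaitsynth.nn import (FoldPlan, ModelConfig, build_model, knee_default,
                          load_model, masked_rmse, save_model, train,
                          tune_hyperparameters)
from gaitsynth.preprocess import MAX_LEN, TrainingSample
from gaitsynth.trial import InputError


def toy_samples(n, seed=0, length=120, subjects=None, smooth=True):
    """Learnable toy task: targets are linear mixtures of smoothed inputs."""
    rng = np.random.default_rng(seed)
    W = rng.normal(0, 1.0, (24, 3))
    samples = []
    for i in range(n):
        x = np.zeros((MAX_LEN, 24))
        raw = rng.normal(size=(length, 24))
        if smooth:
            k = np.ones(9) / 9
            raw = np.apply_along_axis(lambda c: np.convolve(c, k, "same"), 0, raw)
        x[:length] = raw
        y = np.zeros((MAX_LEN, 3))
        y[:length] = 20.0 * (raw @ W) / np.sqrt(24)
        m = np.zeros(MAX_LEN)
        m[:length] = 1
        sid = subjects[i % len(subjects)] if subjects else f"s{i % 6}"
        samples.append(TrainingSample(x, y, m, sid, "simulated"))
    return samples


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(hidden=8, epochs=5, seed=1, dropout=0.0)


class TestGradients:
    def _setup(self, **kw):
        cfg = ModelConfig(hidden=5, n_layers=kw.pop("n_layers", 1), dropout=0.0,
                          seed=3, dtype="float64", **kw)
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 12, 24))
        M = np.ones((3, 12)); M[:, 9:] = 0; X[:, 9:] = 0
        Y = rng.normal(size=(3, 12, 3)); Y[:, 9:] = 0
        return model, X, Y, M

    @pytest.mark.parametrize("n_layers", [1, 2])
    def test_backprop_matches_finite_differences(self, n_layers):
        model, X, Y, M = self._setup(n_layers=n_layers)
        _, grads = model.loss_and_grad(X, Y, M, train=False)
        rs = np.random.default_rng(1)
        for p, g in zip(model.parameters(), grads):
            for _ in range(3):
                idx = tuple(rs.integers(0, s) for s in p.shape)
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp, _ = model.loss_and_grad(X, Y, M, train=False)
                p[idx] = old - eps
                lm, _ = model.loss_and_grad(X, Y, M, train=False)
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 1e-6 * max(1.0, abs(num))

    def test_padded_targets_do_not_affect_loss(self):
        model, X, Y, M = self._setup()
        l0, g0 = model.loss_and_grad(X, Y, M, train=False)
        Y2 = Y.copy()
        Y2[:, 9:] = 123.0  # only padded rows change
        l1, g1 = model.loss_and_grad(X, Y2, M, train=False)
        assert l0 == l1
        for a, b in zip(g0, g1):
            np.testing.assert_array_equal(a, b)


class TestArchitecture:
    def test_hip_default_builds_and_predicts_200x3(self):
        model = build_model(ModelConfig())  # 1 layer, hidden 32
        s = toy_samples(2, length=150)
        out = model.predict(s)
        assert out.shape == (2, MAX_LEN, 3)

    def test_knee_default_builds(self):
        model = build_model(knee_default())  # 1 layer, hidden 128
        assert model.cfg.hidden == 128
        assert model.n_parameters > 4 * (24 + 128) * 128

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(hidden=0)
        with pytest.raises(ConfigurationError):
            ModelConfig(dropout=1.0)

    def test_parameter_count_deterministic(self):
        a = build_model(ModelConfig(hidden=16, seed=0)).n_parameters
        b = build_model(ModelConfig(hidden=16, seed=99)).n_parameters
        assert a == b

    def test_bidirectional_uses_future_context(self):
        samples = toy_samples(4, seed=2)
        cfg = ModelConfig(hidden=8, epochs=3, seed=0)
        model = build_model(cfg)
        train(model, samples, cfg)
        X = np.stack([s.inputs for s in samples])
        M = np.stack([s.mask for s in samples])
        y_fwd, _ = model.forward(X, M)
        y_rev, _ = model.forward(X[:, ::-1], M[:, ::-1])
        assert np.abs(y_fwd - y_rev[:, ::-1]).max() > 1e-3

    def test_forward_only_ablation_flag(self):
        model = build_model(ModelConfig(hidden=8, bidirectional=False))
        assert model.W1.shape[0] == 8  # head sees H, not 2H


class TestTraining:
    def test_memorizes_identical_samples(self):
        base = toy_samples(1, seed=4, length=100)[0]
        samples = [base] * 50
        cfg = ModelConfig(hidden=16, epochs=200, lr=0.01, seed=0, dropout=0.0)
        model = build_model(cfg)
        train(model, samples, cfg)
        rmse = masked_rmse(model.predict(samples[:1]), samples[:1])
        assert rmse < 1.0

    def test_empty_training_set_rejected(self, tiny_cfg):
        with pytest.raises(InputError):
            train(build_model(tiny_cfg), [], tiny_cfg)

    def test_seeded_loss_history_reproducible(self):
        samples = toy_samples(20, seed=5)
        cfg = ModelConfig(hidden=8, epochs=4, seed=7)
        h1 = train(build_model(cfg), samples, cfg)
        h2 = train(build_model(cfg), samples, cfg)
        assert h1 == h2

    def test_zero_learning_rate_freezes_loss(self):
        samples = toy_samples(10, seed=6)
        cfg = ModelConfig(hidden=8, epochs=4, lr=0.0, seed=1, dropout=0.0)
        hist = train(build_model(cfg), samples, cfg)
        assert max(hist) - min(hist) < 1e-6

    def test_training_reduces_loss(self):
        samples = toy_samples(30, seed=7)
        cfg = ModelConfig(hidden=16, epochs=40, lr=0.005, batch_size=10,
                          seed=2, dropout=0.0)
        hist = train(build_model(cfg), samples, cfg)
        assert hist[-1] < 0.5 * hist[0]


class TestPredict:
    def test_duplicate_inputs_identical_outputs(self, tiny_cfg):
        model = build_model(tiny_cfg)
        s = toy_samples(1, seed=8)
        out = model.predict(s + s)
        np.testing.assert_array_equal(out[0], out[1])

    def test_eval_mode_repeatable_train_mode_not(self, tiny_cfg):
        cfg = ModelConfig(hidden=8, dropout=0.5, seed=1)
        model = build_model(cfg)
        s = toy_samples(2, seed=9)
        X = np.stack([x.inputs for x in s])
        M = np.stack([x.mask for x in s])
        e1, _ = model.forward(X, M, train=False)
        e2, _ = model.forward(X, M, train=False)
        np.testing.assert_array_equal(e1, e2)
        rng = np.random.default_rng(0)
        t1, _ = model.forward(X, M, train=True, rng=rng)
        t2, _ = model.forward(X, M, train=True, rng=rng)
        assert np.abs(t1 - t2).max() > 0

    def test_channel_mismatch_rejected(self, tiny_cfg):
        model = build_model(tiny_cfg)
        with pytest.raises(InputError):
            model.forward(np.zeros((1, MAX_LEN, 12)), np.ones((1, MAX_LEN)))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_cfg):
        samples = toy_samples(10, seed=10)
        model = build_model(tiny_cfg)
        train(model, samples, tiny_cfg)
        p = tmp_path / "m.npz"
        save_model(model, p)
        clone = load_model(p)
        np.testing.assert_array_equal(model.predict(samples), clone.predict(samples))


class TestTuning:
    def test_fold_plan_partitions_subjects(self):
        subjects = [f"s{i}" for i in range(11)]
        plan = FoldPlan.from_subjects(subjects, 5, seed=0)
        flat = [s for f in plan.folds for s in f]
        assert sorted(flat) == sorted(subjects)
        assert all(1 <= len(f) <= 3 for f in plan.folds)

    def test_single_cell_grid_returned(self):
        samples = toy_samples(20, seed=11, subjects=[f"s{i}" for i in range(5)])
        plan = FoldPlan.from_subjects([s.subject_id for s in samples], 5)
        base = ModelConfig(hidden=8, epochs=2, seed=0)
        best, table = tune_hyperparameters(plan, samples, [(1, 8)], base)
        assert best == (1, 8) and set(table) == {(1, 8)}

    def test_argmin_consistent_with_cv_table(self):
        samples = toy_samples(30, seed=12, subjects=[f"s{i}" for i in range(5)])
        plan = FoldPlan.from_subjects([s.subject_id for s in samples], 5)
        base = ModelConfig(epochs=3, seed=0)
        best, table = tune_hyperparameters(plan, samples, [(1, 4), (1, 16)], base)
        assert table[best] == min(table.values())

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            FoldPlan.from_subjects(["a", "b"], 5)
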