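"""BiLSTM sequence-to-sequence regression from IMU channels to joint angles.

The network maps a zero-padded (200, 24) IMU window to a (200, 3) joint-angle
window: one or more bidirectional LSTM layers, a per-timestep fully connected
layer with tanh, dropout 0.5, and a linear output layer.  Training uses Adam
(lr 0.001, beta1 0.9, beta2 0.999) on a masked mean-squared-error loss so
padded timesteps contribute nothing.

Everything — forward pass, backpropagation through time, Adam — is
implemented directly on numpy arrays; training is deterministic under the
configured seed.  Inputs are z-scored per channel with statistics from the
training split (mixed rad/s and m/s^2 channels destabilise training
otherwise) and targets are z-scored symmetrically, with predictions mapped
back to degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chain import ConfigurationError
from .preprocess import TrainingSample
from .trial import InputError

N_INPUT = 24
N_OUTPUT = 3


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the tuned hip model (1 layer, 32)."""

    joint: str = "hip"
    n_layers: int = 1
    hidden: int = 32
    dropout: float = 0.5
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 100
    batch_size: int = 50
    seed: int = 0
    bidirectional: bool = True
    masked_loss: bool = True
    normalize_targets: bool = True
    grad_clip: float = 5.0
    dtype: str = "float32"  # float64 only needed for finite-difference checks

    def __post_init__(self) -> None:
        if self.hidden <= 0 or self.n_layers <= 0:
            raise ConfigurationError("hidden size and layer count must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.joint not in ("hip", "knee"):
            raise ConfigurationError("joint must be 'hip' or 'knee'")


def knee_default() -> ModelConfig:
    """Tuned knee model: 1 BiLSTM layer, hidden size 128."""
    return ModelConfig(joint="knee", n_layers=1, hidden=128)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTMDirection:
    """One direction of one LSTM layer (gate order i, f, g, o)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        k = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-k, k, (d_in, 4 * hidden)).astype(dtype)
        self.Wh = rng.uniform(-k, k, (hidden, 4 * hidden)).astype(dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.H = hidden
        self.dtype = dtype

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, reverse: bool) -> tuple[np.ndarray, dict]:
        B, T, _ = X.shape
        H, dt = self.H, self.dtype
        order = range(T - 1, -1, -1) if reverse else range(T)
        Zx = X @ self.Wx + self.b
        I = np.empty((B, T, H), dt); F = np.empty((B, T, H), dt)
        G = np.empty((B, T, H), dt); O = np.empty((B, T, H), dt)
        C = np.empty((B, T, H), dt); Ct = np.empty((B, T, H), dt)
        Hs = np.empty((B, T, H), dt); Hprev = np.empty((B, T, H), dt)
        h = np.zeros((B, H), dt); c = np.zeros((B, H), dt)
        for t in order:
            Hprev[:, t] = h
            z = Zx[:, t] + h @ self.Wh
            I[:, t] = _sigmoid(z[:, :H])
            F[:, t] = _sigmoid(z[:, H:2 * H])
            G[:, t] = np.tanh(z[:, 2 * H:3 * H])
            O[:, t] = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = F[:, t] * c_prev + I[:, t] * G[:, t]
            C[:, t] = c_prev  # store previous cell for BPTT
            Ct[:, t] = np.tanh(c)
            h = O[:, t] * Ct[:, t]
            Hs[:, t] = h
        cache = dict(X=X, I=I, F=F, G=G, O=O, Cprev=C, Ct=Ct, Hprev=Hprev,
                     reverse=reverse)
        return Hs, cache

    def backward(self, dH: np.ndarray, cache: dict) -> tuple[np.ndarray, list]:
        X, I, F, G, O = cache["X"], cache["I"], cache["F"], cache["G"], cache["O"]
        Cprev, Ct, Hprev = cache["Cprev"], cache["Ct"], cache["Hprev"]
        B, T, H = I.shape
        order = range(T) if cache["reverse"] else range(T - 1, -1, -1)
        dZ = np.empty((B, T, 4 * H), self.dtype)
        dh_next = np.zeros((B, H), self.dtype); dc_next = np.zeros((B, H), self.dtype)
        WhT = self.Wh.T
        for t in order:
            dh = dH[:, t] + dh_next
            do = dh * Ct[:, t]
            dc = dc_next + dh * O[:, t] * (1.0 - Ct[:, t] ** 2)
            di = dc * G[:, t]
            df = dc * Cprev[:, t]
            dg = dc * I[:, t]
            dc_next = dc * F[:, t]
            dz = dZ[:, t]
            dz[:, :H] = di * I[:, t] * (1 - I[:, t])
            dz[:, H:2 * H] = df * F[:, t] * (1 - F[:, t])
            dz[:, 2 * H:3 * H] = dg * (1 - G[:, t] ** 2)
            dz[:, 3 * H:] = do * O[:, t] * (1 - O[:, t])
            dh_next = dz @ WhT
        dWx = np.einsum("btd,bth->dh", X, dZ)
        dWh = np.einsum("btd,bth->dh", Hprev, dZ)
        db = dZ.sum(axis=(0, 1))
        dX = dZ @ self.Wx.T
        return dX, [dWx, dWh, db]


class BiLSTMRegressor:
    """Stacked (Bi)LSTM with a two-layer fully connected head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dt = np.dtype(cfg.dtype).type
        self.dtype = dt
        rng = np.random.default_rng(cfg.seed)
        self.layers: list[list[_LSTMDirection]] = []
        d_in = N_INPUT
        width = 2 * cfg.hidden if cfg.bidirectional else cfg.hidden
        for _ in range(cfg.n_layers):
            dirs = [_LSTMDirection(d_in, cfg.hidden, rng, dt)]
            if cfg.bidirectional:
                dirs.append(_LSTMDirection(d_in, cfg.hidden, rng, dt))
            self.layers.append(dirs)
            d_in = width
        k1 = 1.0 / np.sqrt(width)
        self.W1 = rng.uniform(-k1, k1, (width, cfg.hidden)).astype(dt)
        self.b1 = np.zeros(cfg.hidden, dt)
        k2 = 1.0 / np.sqrt(cfg.hidden)
        self.W2 = rng.uniform(-k2, k2, (cfg.hidden, N_OUTPUT)).astype(dt)
        self.b2 = np.zeros(N_OUTPUT, dt)
        # normalisation statistics (identity until fitted)
        self.x_mean = np.zeros(N_INPUT); self.x_std = np.ones(N_INPUT)
        self.y_mean = np.zeros(N_OUTPUT); self.y_std = np.ones(N_OUTPUT)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        ps = []
        for layer in self.layers:
            for d in layer:
                ps.extend(d.params())
        ps.extend([self.W1, self.b1, self.W2, self.b2])
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, mask: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Normalised-space forward pass; returns (Y_hat, cache).

        ``X`` is (B, T, 24) raw channels, ``mask`` (B, T).  Padded rows stay
        exactly zero after normalisation.
        """
        if X.shape[-1] != N_INPUT:
            raise InputError(f"expected {N_INPUT} input channels, got {X.shape[-1]}")
        m = mask[..., None]
        Xn = ((X - self.x_mean) / self.x_std * m).astype(self.dtype)
        caches = []
        A = Xn
        for layer in self.layers:
            outs = []
            for d, rev in zip(layer, (False, True)):
                Hs, c = d.forward(A, reverse=rev)
                outs.append(Hs)
                caches.append(c)
            A = np.concatenate(outs, axis=-1) if len(outs) > 1 else outs[0]
        Z1 = A @ self.W1 + self.b1
        A1 = np.tanh(Z1)
        if train and self.cfg.dropout > 0:
            if rng is None:
                raise InputError("training-mode forward needs an RNG for dropout")
            keep = 1.0 - self.cfg.dropout
            drop = ((rng.random(A1.shape) < keep) / keep).astype(self.dtype)
            D1 = A1 * drop
        else:
            drop = None
            D1 = A1
        Y = D1 @ self.W2 + self.b2
        cache = dict(lstm=caches, A=A, A1=A1, D1=D1, drop=drop, Xn=Xn, mask=mask)
        return Y, cache

    def backward(self, dY: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradients w.r.t. all parameters, in ``parameters()`` order."""
        D1, A1, A, drop = cache["D1"], cache["A1"], cache["A"], cache["drop"]
        gW2 = np.einsum("bth,btk->hk", D1, dY)
        gb2 = dY.sum(axis=(0, 1))
        dD1 = dY @ self.W2.T
        if drop is not None:
            dD1 = dD1 * drop
        dZ1 = dD1 * (1.0 - A1 ** 2)
        gW1 = np.einsum("bth,btk->hk", A, dZ1)
        gb1 = dZ1.sum(axis=(0, 1))
        dA = dZ1 @ self.W1.T
        grads_lstm: list[np.ndarray] = []
        ci = len(cache["lstm"])
        for layer in reversed(self.layers):
            H = self.cfg.hidden
            if len(layer) > 1:
                parts = [dA[..., :H], dA[..., H:]]
            else:
                parts = [dA]
            dA_next = None
            layer_grads = []
            for d, dH in zip(reversed(layer), reversed(parts)):
                ci -= 1
                dX, gs = d.backward(dH, cache["lstm"][ci])
                dA_next = dX if dA_next is None else dA_next + dX
                layer_grads = gs + layer_grads
            grads_lstm = layer_grads + grads_lstm
            dA = dA_next
        return grads_lstm + [gW1, gb1, gW2, gb2]

    # -- loss ---------------------------------------------------------------
    def loss_and_grad(self, X, Y, mask, train=True, rng=None):
        Yh, cache = self.forward(X, mask, train=train, rng=rng)
        Yn = ((Y - self.y_mean) / self.y_std * mask[..., None]).astype(self.dtype)
        diff = (Yh - Yn)
        if self.cfg.masked_loss:
            m = mask[..., None]
            denom = max(mask.sum() * N_OUTPUT, 1.0)
            loss = float(np.sum(diff ** 2 * m) / denom)
            dY = (2.0 * diff * m / denom).astype(self.dtype)
        else:
            loss = float(np.mean(diff ** 2))
            dY = (2.0 * diff / diff.size).astype(self.dtype)
        return loss, self.backward(dY, cache)

    def predict(self, samples: list[TrainingSample]) -> np.ndarray:
        """Deterministic evaluation-mode predictions in degrees, (B, 200, 3)."""
        X = np.stack([s.inputs for s in samples])
        mask = np.stack([s.mask for s in samples])
        Yh, _ = self.forward(X, mask, train=False)
        return Yh * self.y_std + self.y_mean


def build_model(cfg: ModelConfig) -> BiLSTMRegressor:
    return BiLSTMRegressor(cfg)


def save_model(model: BiLSTMRegressor, path) -> None:
    """Checkpoint: weights + config + normalisation statistics (npz)."""
    import dataclasses
    import json

    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    arrays.update(x_mean=model.x_mean, x_std=model.x_std,
                  y_mean=model.y_mean, y_std=model.y_std)
    cfg_json = json.dumps(dataclasses.asdict(model.cfg))
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> BiLSTMRegressor:
    import json

    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = BiLSTMRegressor(cfg)
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        model.x_mean, model.x_std = data["x_mean"], data["x_std"]
        model.y_mean, model.y_std = data["y_mean"], data["y_std"]
    return model


def _stack(samples: list[TrainingSample]):
    X = np.stack([s.inputs for s in samples])
    Y = np.stack([s.target for s in samples])
    M = np.stack([s.mask for s in samples])
    return X, Y, M


def fit_normalization(model: BiLSTMRegressor, X, Y, M) -> None:
    """Per-channel z-score statistics over valid timesteps of the training
    split only."""
    valid = M.reshape(-1) > 0
    Xf = X.reshape(-1, N_INPUT)[valid]
    model.x_mean = Xf.mean(axis=0)
    model.x_std = np.maximum(Xf.std(axis=0), 1e-8)
    if model.cfg.normalize_targets:
        Yf = Y.reshape(-1, N_OUTPUT)[valid]
        model.y_mean = Yf.mean(axis=0)
        model.y_std = np.maximum(Yf.std(axis=0), 1e-8)


def train(model: BiLSTMRegressor, samples: list[TrainingSample],
          cfg: ModelConfig | None = None) -> list[float]:
    """Adam training on the masked MSE; returns the per-epoch loss history."""
    if not samples:
        raise InputError("empty training set")
    cfg = cfg or model.cfg
    X, Y, M = _stack(samples)
    fit_normalization(model, X, Y, M)
    rng = np.random.default_rng(cfg.seed + 1)
    params = model.parameters()
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    history = []
    step = 0
    n = len(samples)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model.loss_and_grad(X[idx], Y[idx], M[idx], train=True, rng=rng)
            losses.append(loss)
            if cfg.grad_clip > 0:
                gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if gnorm > cfg.grad_clip:
                    grads = [g * (cfg.grad_clip / gnorm) for g in grads]
            step += 1
            for p, g, m1, v1 in zip(params, grads, m_t, v_t):
                m1 *= cfg.beta1; m1 += (1 - cfg.beta1) * g
                v1 *= cfg.beta2; v1 += (1 - cfg.beta2) * g * g
                mhat = m1 / (1 - cfg.beta1 ** step)
                vhat = v1 / (1 - cfg.beta2 ** step)
                p -= cfg.lr * mhat / (np.sqrt(vhat) + 1e-8)
        history.append(float(np.mean(losses)))
    return history


def predict(model: BiLSTMRegressor, samples: list[TrainingSample]) -> np.ndarray:
    return model.predict(samples)


def masked_rmse(pred: np.ndarray, samples: list[TrainingSample]) -> float:
    """RMSE in degrees over valid timesteps and all three DoF."""
    Y = np.stack([s.target for s in samples])
    M = np.stack([s.mask for s in samples])[..., None]
    return float(np.sqrt(np.sum((pred - Y) ** 2 * M) / (M.sum() * N_OUTPUT)))


@dataclass
class FoldPlan:
    """Subject-wise cross-validation folds over the training cohort."""

    folds: list[list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.folds:
            dup = seen & set(f)
            if dup:
                raise ConfigurationError(f"subjects {sorted(dup)} in multiple folds")
            seen |= set(f)

    @classmethod
    def from_subjects(cls, subjects: list[str], n_folds: int = 5,
                      seed: int = 0) -> "FoldPlan":
        subjects = sorted(set(subjects))
        if len(subjects) < n_folds:
            raise ConfigurationError("need at least one subject per fold")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(subjects)
        return cls([sorted(f.tolist()) for f in np.array_split(perm, n_folds)])


def tune_hyperparameters(plan: FoldPlan, samples: list[TrainingSample],
                         grid: list[tuple[int, int]],
                         base_cfg: ModelConfig | None = None):
    """5-fold CV over (n_layers, hidden) candidates.

    Returns ``(best, table)`` where ``table`` maps each candidate to its mean
    validation RMSE across folds; ties break toward the smaller model.
    """
    base_cfg = base_cfg or ModelConfig()
    table: dict[tuple[int, int], float] = {}
    for n_layers, hidden in grid:
        fold_rmse = []
        for k, val_subjects in enumerate(plan.folds):
            val = [s for s in samples if s.subject_id in set(val_subjects)]
            tr = [s for s in samples if s.subject_id not in set(val_subjects)]
            if not val or not tr:
                raise ConfigurationError("empty fold; too few subjects")
            cfg = replace(base_cfg, n_layers=n_layers, hidden=hidden,
                          seed=base_cfg.seed + k)
            model = build_model(cfg)
            train(model, tr, cfg)
            fold_rmse.append(masked_rmse(model.predict(val), val))
        table[(n_layers, hidden)] = float(np.mean(fold_rmse))

    def size(cand):
        return build_model(replace(base_cfg, n_layers=cand[0], hidden=cand[1])).n_parameters

    best = min(table, key=lambda c: (table[c], size(c)))
    return best, table
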