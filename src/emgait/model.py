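"""Stacked bidirectional LSTM for per-timestep stance/swing classification.

The architecture is sequence-to-sequence throughout: a first bidirectional
LSTM layer (200 units per direction by default) followed by three more
bidirectional LSTM layers (100 units), then a cascade of time-distributed
dense layers (100, 50, 25) and a final per-timestep softmax over the two
gait phases; 60% dropout sits between all trainable layers during
training.  With a per-timestep input dimension of 2 this stack has exactly
1,233,677 trainable parameters (324,800 in the first bidirectional layer).

No deep-learning framework is assumed: forward pass, backpropagation
through time, inverted dropout, Adam and early stopping are implemented
directly on numpy arrays (float32).  Given a seed, initialization,
batching and dropout are fully reproducible.

Parameter counting (per layer, input dimension d):

* bidirectional LSTM with u units:  ``8 * u * (d + u + 1)``
  (2 directions x 4 gates x (input weights + recurrent weights + bias));
  the layer's output dimension is ``2 * u``;
* time-distributed dense with m units:  ``(d + 1) * m``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

DTYPE = np.float32


@dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    input_dim: int = 4
    seq_len: int = 500
    bi_units: tuple[int, ...] = (200, 100, 100, 100)
    dense_units: tuple[int, ...] = (100, 50, 25)
    dropout: float = 0.60
    n_classes: int = 2

    def __post_init__(self) -> None:
        self.bi_units = tuple(int(u) for u in self.bi_units)
        self.dense_units = tuple(int(m) for m in self.dense_units)
        if self.input_dim <= 0 or self.seq_len <= 0 or self.n_classes <= 0:
            raise ValueError("all sizes must be positive")
        if any(u <= 0 for u in self.bi_units + self.dense_units):
            raise ValueError("all layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @classmethod
    def reference_counts(cls, **kw) -> "ModelConfig":
        """Preset with per-timestep input dimension 2.

        The printed parameter totals (324,800 first layer; 1,233,677
        overall) are consistent only with 2 input features per timestep,
        although four muscles are recorded; both configurations are
        supported and this preset reproduces the printed counts.
        """
        kw.setdefault("input_dim", 2)
        return cls(**kw)


@dataclass
class TrainConfig:
    """Optimization settings (field defaults; the protocol states none)."""

    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    retrain_fraction: float = 0.30
    patience: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.retrain_fraction <= 1.0:
            raise ValueError("retrain_fraction must lie in (0, 1]")
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form trainable parameter count of the configured stack."""
    d = cfg.input_dim
    total = 0
    for u in cfg.bi_units:
        total += 8 * u * (d + u + 1)
        d = 2 * u
    for m in cfg.dense_units:
        total += (d + 1) * m
        d = m
    total += (d + 1) * cfg.n_classes
    return total


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class BiLSTMPhaseModel:
    """Sequence-to-sequence stance/swing classifier.

    Parameters live in ``self.params`` keyed ``L{i}_{f|b}_{Wx|Wh|bias}``
    for the bidirectional layers and ``D{j}_{W|b}`` for the dense cascade
    (the last dense index is the softmax output layer).
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        self.history: list[dict] = []
        rng = np.random.default_rng(seed)
        d = cfg.input_dim
        for i, u in enumerate(cfg.bi_units):
            for dirn in ("f", "b"):
                self.params[f"L{i}_{dirn}_Wx"] = _glorot(rng, (d, 4 * u))
                self.params[f"L{i}_{dirn}_Wh"] = _glorot(rng, (u, 4 * u))
                bias = np.zeros(4 * u, dtype=DTYPE)
                bias[u:2 * u] = 1.0  # forget-gate bias
                self.params[f"L{i}_{dirn}_bias"] = bias
            d = 2 * u
        widths = list(cfg.dense_units) + [cfg.n_classes]
        for j, m in enumerate(widths):
            self.params[f"D{j}_W"] = _glorot(rng, (d, m))
            self.params[f"D{j}_b"] = np.zeros(m, dtype=DTYPE)
            d = m

    # ------------------------------------------------------------------ #
    def n_parameters(self) -> int:
        """Realized parameter count (sum of array sizes)."""
        return int(sum(p.size for p in self.params.values()))

    # ------------------------------------------------------------------ #
    def _lstm_forward(self, x: np.ndarray, layer: int, dirn: str):
        """One direction of one LSTM layer; returns (H, cache)."""
        Wx = self.params[f"L{layer}_{dirn}_Wx"]
        Wh = self.params[f"L{layer}_{dirn}_Wh"]
        bias = self.params[f"L{layer}_{dirn}_bias"]
        B, T, d = x.shape
        u = Wh.shape[0]
        Xp = x.reshape(B * T, d) @ Wx
        Xp = Xp.reshape(B, T, 4 * u) + bias
        H = np.empty((B, T, u), dtype=DTYPE)
        gates = np.empty((B, T, 4 * u), dtype=DTYPE)  # i, f, g, o (post-nl)
        C = np.empty((B, T, u), dtype=DTYPE)
        TC = np.empty((B, T, u), dtype=DTYPE)
        h = np.zeros((B, u), dtype=DTYPE)
        c = np.zeros((B, u), dtype=DTYPE)
        for t in range(T):
            z = Xp[:, t] + h @ Wh
            i_g = expit(z[:, :u])
            f_g = expit(z[:, u:2 * u])
            g_g = np.tanh(z[:, 2 * u:3 * u])
            o_g = expit(z[:, 3 * u:])
            c = f_g * c + i_g * g_g
            tc = np.tanh(c)
            h = o_g * tc
            gates[:, t, :u] = i_g
            gates[:, t, u:2 * u] = f_g
            gates[:, t, 2 * u:3 * u] = g_g
            gates[:, t, 3 * u:] = o_g
            C[:, t] = c
            TC[:, t] = tc
            H[:, t] = h
        cache = {"x": x, "H": H, "gates": gates, "C": C, "TC": TC}
        return H, cache

    def _lstm_backward(self, dH: np.ndarray, layer: int, dirn: str, cache,
                       grads: dict[str, np.ndarray]) -> np.ndarray:
        Wx = self.params[f"L{layer}_{dirn}_Wx"]
        Wh = self.params[f"L{layer}_{dirn}_Wh"]
        x, H = cache["x"], cache["H"]
        gates, C, TC = cache["gates"], cache["C"], cache["TC"]
        B, T, d = x.shape
        u = Wh.shape[0]
        dZ = np.empty((B, T, 4 * u), dtype=DTYPE)
        dh_next = np.zeros((B, u), dtype=DTYPE)
        dc_next = np.zeros((B, u), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i_g = gates[:, t, :u]
            f_g = gates[:, t, u:2 * u]
            g_g = gates[:, t, 2 * u:3 * u]
            o_g = gates[:, t, 3 * u:]
            tc = TC[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, u), dtype=DTYPE)
            dh = dH[:, t] + dh_next
            dc = dc_next + dh * o_g * (1.0 - tc * tc)
            do = dh * tc
            di = dc * g_g
            dg = dc * i_g
            df = dc * c_prev
            dz = dZ[:, t]
            dz[:, :u] = di * i_g * (1.0 - i_g)
            dz[:, u:2 * u] = df * f_g * (1.0 - f_g)
            dz[:, 2 * u:3 * u] = dg * (1.0 - g_g * g_g)
            dz[:, 3 * u:] = do * o_g * (1.0 - o_g)
            dh_next = dz @ Wh.T
            dc_next = dc * f_g
        Hprev = np.concatenate(
            [np.zeros((B, 1, u), dtype=DTYPE), H[:, :-1]], axis=1)
        dZf = dZ.reshape(B * T, 4 * u)
        grads[f"L{layer}_{dirn}_Wx"] = x.reshape(B * T, d).T @ dZf
        grads[f"L{layer}_{dirn}_Wh"] = Hprev.reshape(B * T, u).T @ dZf
        grads[f"L{layer}_{dirn}_bias"] = dZf.sum(axis=0)
        return (dZf @ Wx.T).reshape(B, T, d)

    # ------------------------------------------------------------------ #
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Per-timestep class probabilities (B, T, n_classes) + cache."""
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[2] != self.cfg.input_dim:
            raise ValueError(
                f"expected input (batch, T, {self.cfg.input_dim}), got {x.shape}"
            )
        p_drop = self.cfg.dropout if training else 0.0
        if p_drop > 0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        caches = []
        out = x
        for i in range(len(self.cfg.bi_units)):
            Hf, cf = self._lstm_forward(out, i, "f")
            Hb_rev, cb = self._lstm_forward(out[:, ::-1], i, "b")
            out = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
            mask = self._dropout_mask(rng, out.shape, p_drop)
            if mask is not None:
                out = out * mask
            caches.append({"f": cf, "b": cb, "mask": mask})
        B, T, _ = out.shape
        widths = list(self.cfg.dense_units) + [self.cfg.n_classes]
        for j, m in enumerate(widths):
            W = self.params[f"D{j}_W"]
            b = self.params[f"D{j}_b"]
            z = out.reshape(B * T, -1) @ W + b
            last = j == len(widths) - 1
            if last:
                z = z - z.max(axis=1, keepdims=True)
                ez = np.exp(z)
                probs = (ez / ez.sum(axis=1, keepdims=True)).reshape(B, T, m)
                caches.append({"a_in": out})
                return probs, caches
            a = np.maximum(z, 0.0).reshape(B, T, m)
            mask = self._dropout_mask(rng, a.shape, p_drop)
            caches.append({"a_in": out, "z_pos": a > 0, "mask": mask})
            out = a * mask if mask is not None else a

    @staticmethod
    def _dropout_mask(rng, shape, p_drop):
        if p_drop <= 0:
            return None
        keep = 1.0 - p_drop
        return (rng.random(shape) < keep).astype(DTYPE) / DTYPE(keep)

    # ------------------------------------------------------------------ #
    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None,
                       training: bool = True):
        """Mean per-timestep cross-entropy and gradients for all params."""
        probs, caches = self.forward(x, training=training, rng=rng)
        B, T, K = probs.shape
        y = np.asarray(y, dtype=np.int64).reshape(B, T)
        flat = probs.reshape(B * T, K)
        idx = np.arange(B * T)
        eps = np.finfo(DTYPE).tiny
        loss = float(-np.log(np.clip(flat[idx, y.ravel()], eps, None)).mean())

        grads: dict[str, np.ndarray] = {}
        dlogits = flat.copy()
        dlogits[idx, y.ravel()] -= 1.0
        dlogits /= B * T

        widths = list(self.cfg.dense_units) + [self.cfg.n_classes]
        dcur = dlogits  # (B*T, m) gradient at current dense layer output z
        for j in range(len(widths) - 1, -1, -1):
            cache = caches[len(self.cfg.bi_units) + j]
            a_in = cache["a_in"]
            d_in = a_in.shape[2]
            A = a_in.reshape(B * T, d_in)
            grads[f"D{j}_W"] = A.T @ dcur
            grads[f"D{j}_b"] = dcur.sum(axis=0)
            dA = dcur @ self.params[f"D{j}_W"].T  # (B*T, d_in)
            if j > 0:
                prev = caches[len(self.cfg.bi_units) + j - 1]
                dA = dA.reshape(B, T, d_in)
                if prev["mask"] is not None:
                    dA = dA * prev["mask"]
                dA = dA.reshape(B * T, d_in) * prev["z_pos"].reshape(B * T, d_in)
                dcur = dA
            else:
                dOut = dA.reshape(B, T, d_in)

        for i in range(len(self.cfg.bi_units) - 1, -1, -1):
            cache = caches[i]
            if cache["mask"] is not None:
                dOut = dOut * cache["mask"]
            u = self.cfg.bi_units[i]
            dHf = dOut[:, :, :u]
            dHb = dOut[:, ::-1, u:]
            dx_f = self._lstm_backward(np.ascontiguousarray(dHf), i, "f",
                                       cache["f"], grads)
            dx_b = self._lstm_backward(np.ascontiguousarray(dHb), i, "b",
                                       cache["b"], grads)
            dOut = dx_f + dx_b[:, ::-1]
        return loss, grads

    # ------------------------------------------------------------------ #
    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic inference-mode probabilities.

        Accepts one sequence (T, C) or a batch (N, T, C); dropout is off.
        """
        x = np.asarray(x, dtype=DTYPE)
        single = x.ndim == 2
        if single:
            x = x[None]
        outs = []
        for i in range(0, x.shape[0], batch_size):
            probs, _ = self.forward(x[i:i + batch_size], training=False)
            outs.append(probs)
        probs = np.concatenate(outs, axis=0)
        return probs[0] if single else probs

    def predict_labels(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Hard per-timestep labels; exact ties resolve to stance (0)."""
        probs = self.predict_proba(x, batch_size=batch_size)
        return (probs[..., 1] > probs[..., 0]).astype(np.int8)

    # ------------------------------------------------------------------ #
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(asdict(self.cfg)))
        np.savez(directory / "weights.npz", **self.params)

    @classmethod
    def load(cls, directory) -> "BiLSTMPhaseModel":
        directory = Path(directory)
        raw = json.loads((directory / "config.json").read_text())
        raw["bi_units"] = tuple(raw["bi_units"])
        raw["dense_units"] = tuple(raw["dense_units"])
        model = cls(ModelConfig(**raw))
        with np.load(directory / "weights.npz") as z:
            for k in model.params:
                model.params[k] = z[k].astype(DTYPE)
        return model


def build_model(cfg: ModelConfig, seed: int = 0) -> BiLSTMPhaseModel:
    """Instantiate the stack; realized size must match the closed form."""
    model = BiLSTMPhaseModel(cfg, seed=seed)
    expected = count_parameters(cfg)
    if model.n_parameters() != expected:
        raise AssertionError(
            f"realized parameter count {model.n_parameters()} != closed form "
            f"{expected}"
        )
    return model


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for k, g in grads.items():
            g = g.astype(DTYPE)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (lr_t * self.m[k] /
                          (np.sqrt(self.v[k]) + self.eps)).astype(DTYPE)


def _epoch_pass(model, X, Y, tc, opt, rng):
    order = rng.permutation(X.shape[0])
    total, nb = 0.0, 0
    for i in range(0, X.shape[0], tc.batch_size):
        sel = order[i:i + tc.batch_size]
        loss, grads = model.loss_and_grads(X[sel], Y[sel], rng=rng,
                                           training=True)
        opt.step(model.params, grads)
        total += loss
        nb += 1
    return total / max(nb, 1)


def evaluate_loss(model: BiLSTMPhaseModel, X, Y, batch_size: int = 64) -> float:
    """Inference-mode mean cross-entropy."""
    total, n = 0.0, 0
    eps = np.finfo(DTYPE).tiny
    for i in range(0, X.shape[0], batch_size):
        probs = model.predict_proba(X[i:i + batch_size], batch_size=batch_size)
        yb = Y[i:i + batch_size]
        p = np.take_along_axis(probs, yb[..., None].astype(np.int64),
                               axis=2)[..., 0]
        total += float(-np.log(np.clip(p, eps, None)).sum())
        n += p.size
    return total / max(n, 1)


def train(model: BiLSTMPhaseModel, ds, tc: TrainConfig) -> BiLSTMPhaseModel:
    """Fit on the train split with early stopping on validation loss.

    Minimizes mean per-timestep cross-entropy with Adam; keeps (and
    restores) the best-validation-loss weights.  With ``epochs=0`` the
    model is returned untouched.
    """
    if tc.epochs == 0:
        return model
    X, Y = ds.arrays("train")
    try:
        Xv, Yv = ds.arrays("val")
    except ValueError:
        Xv = Yv = None
    rng = np.random.default_rng(tc.seed)
    opt = _Adam(model.params, tc.learning_rate)
    best = np.inf
    best_params = None
    bad = 0
    for epoch in range(tc.epochs):
        train_loss = _epoch_pass(model, X, Y, tc, opt, rng)
        rec = {"epoch": epoch, "train_loss": train_loss}
        if Xv is not None:
            val_loss = evaluate_loss(model, Xv, Yv, tc.batch_size)
            rec["val_loss"] = val_loss
            if val_loss < best - 1e-6:
                best = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad = 0
            else:
                bad += 1
        model.history.append(rec)
        if Xv is not None and bad > tc.patience:
            break
    if best_params is not None:
        model.params = best_params
    return model


def partial_retrain(model: BiLSTMPhaseModel, ds_1500,
                    tc: TrainConfig) -> BiLSTMPhaseModel:
    """Continue optimizing all weights on a seeded subset of 1500 Hz windows.

    A random ``retrain_fraction`` (default 30%) of the training sequences
    is drawn without replacement; validation-based early stopping applies
    when the dataset carries a validation split.
    """
    X, Y = ds_1500.arrays("train")
    rng = np.random.default_rng(tc.seed)
    n_keep = max(1, int(round(tc.retrain_fraction * X.shape[0])))
    keep = rng.choice(X.shape[0], size=n_keep, replace=False)
    sub_X, sub_Y = X[keep], Y[keep]

    try:
        Xv, Yv = ds_1500.arrays("val")
    except ValueError:
        Xv = Yv = None
    opt = _Adam(model.params, tc.learning_rate)
    best = np.inf
    best_params = None
    bad = 0
    for epoch in range(tc.epochs):
        train_loss = _epoch_pass(model, sub_X, sub_Y, tc, opt, rng)
        rec = {"epoch": epoch, "retrain_loss": train_loss}
        if Xv is not None:
            val_loss = evaluate_loss(model, Xv, Yv, tc.batch_size)
            rec["val_loss"] = val_loss
            if val_loss < best - 1e-6:
                best = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad = 0
            else:
                bad += 1
        model.history.append(rec)
        if Xv is not None and bad > tc.patience:
            break
    if best_params is not None:
        model.params = best_params
    return model
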