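"""Stacked-LSTM activity classifier, implemented directly in NumPy.

The network mirrors the study architecture: a window of 150 x/y/z samples
feeds two stacked LSTM layers of 64 units; the final hidden state passes
through a rectified fully connected layer of 64 units and a linear layer of
4 class scores, softmax-normalised to probabilities.  Training minimises
categorical cross-entropy plus an L2 (ridge) penalty of
``0.5 * l2_lambda * sum(W**2)`` over all weight matrices (biases excluded),
by seeded minibatch gradient descent — Adam by default, plain SGD as an
option.  Both forward and backward passes (backpropagation through time)
are written here; everything is deterministic for a fixed seed on a single
thread.

Gate order inside each concatenated LSTM weight matrix is (input, forget,
cell, output); the forget-gate bias is initialised to 1 so early gradients
survive the 150-step unroll.
"""

from __future__ import annotations

import copy
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, TrainingError
from .sensor_io import CLASS_ORDER

ARTIFACT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    Defaults are the study configuration: 150-sample windows, 2 stacked
    LSTM layers and 2 dense layers of 64 units, learning rate 0.0025,
    batch 1024, 150 epochs.  The L2 coefficient, optimiser and dense
    activation are not pinned down by the study; defaults here are
    conventional choices (1e-4, Adam, ReLU) and all are exposed.
    """

    window_size: int = 150
    input_channels: int = 3
    lstm_layers: int = 2
    lstm_units: int = 64
    dense_units: int = 64
    classes: int = 4
    learning_rate: float = 0.0025
    batch_size: int = 1024
    epochs: int = 150
    l2_lambda: float = 1e-4
    optimizer: str = "adam"
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.window_size, self.input_channels, self.lstm_layers,
                  self.lstm_units, self.dense_units, self.classes,
                  self.batch_size, self.epochs)
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all size/count parameters must be positive")
        if self.learning_rate <= 0 or self.l2_lambda < 0:
            raise ConfigurationError("need learning_rate > 0 and l2_lambda >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError("optimizer must be 'adam' or 'sgd'")
        if self.clip_norm < 0:
            raise ConfigurationError("clip_norm must be >= 0 (0 disables)")


@dataclass
class TrainingHistory:
    """Per-epoch accuracy and loss on both partitions."""

    train_accuracy: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)
    train_error: list = field(default_factory=list)
    test_error: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_accuracy) + 1),
                "train_acc": self.train_accuracy,
                "test_acc": self.test_accuracy,
                "train_err": self.train_error,
                "test_err": self.test_error,
            }
        )


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def init_params(config: ModelConfig) -> dict:
    """Seeded Glorot-uniform initial parameters for the full network."""
    rng = np.random.default_rng(config.seed)
    H, D = config.lstm_units, config.input_channels
    params = {}
    d_in = D
    for l in range(config.lstm_layers):
        params[f"Wx{l}"] = _glorot(rng, (d_in, 4 * H))
        params[f"Wh{l}"] = _glorot(rng, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget gate
        params[f"b{l}"] = b
        d_in = H
    params["W_fc"] = _glorot(rng, (H, config.dense_units))
    params["b_fc"] = np.zeros(config.dense_units)
    params["W_out"] = _glorot(rng, (config.dense_units, config.classes))
    params["b_out"] = np.zeros(config.classes)
    return params


def _lstm_forward(X, Wx, Wh, b):
    """Run one LSTM layer over a batch of sequences.

    X: (B, T, D) -> outputs (B, T, H) plus the per-step cache needed for
    backpropagation through time.  State starts at zero for every window
    (windows are treated as independent sequences).
    """
    B, T, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        x_t = X[:, t]
        z = x_t @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_prev = c
        c = f * c + i * g
        tanh_c = np.tanh(c)
        h = o * tanh_c
        Hs[:, t] = h
        cache.append((x_t, i, f, g, o, c_prev, tanh_c))
    return Hs, cache


def _lstm_backward(dH, cache, Wx, Wh, prev_h):
    """BPTT for one layer.  dH: (B, T, H) gradient w.r.t. the outputs.

    Returns (dX, dWx, dWh, db).  ``prev_h`` gives h_{t-1} per step (zeros at
    t=0), reconstructed by the caller from the forward outputs.
    """
    B, T, H = dH.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.empty((B, T, Wx.shape[0]))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x_t, i, f, g, o, c_prev, tanh_c = cache[t]
        dh = dH[:, t] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        di, df, dg = dc * g, dc * c_prev, dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += prev_h[t].T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dX, dWx, dWh, db


def forward(params: dict, X: np.ndarray, config: ModelConfig, with_cache=False):
    """Class probabilities for a batch of windows (B, T, 3)."""
    if X.ndim != 3 or X.shape[1] != config.window_size or X.shape[2] != config.input_channels:
        raise ConfigurationError(
            f"expected windows of shape (n, {config.window_size}, "
            f"{config.input_channels}); got {X.shape}"
        )
    caches, seq = [], X
    for l in range(config.lstm_layers):
        seq, cache = _lstm_forward(seq, params[f"Wx{l}"], params[f"Wh{l}"], params[f"b{l}"])
        caches.append((cache, seq))
    h_last = seq[:, -1]
    a_fc = h_last @ params["W_fc"] + params["b_fc"]
    r = np.maximum(a_fc, 0.0)
    scores = r @ params["W_out"] + params["b_out"]
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    probs = e / e.sum(axis=1, keepdims=True)
    if with_cache:
        return probs, (caches, h_last, a_fc, r)
    return probs


def loss_and_grads(params, X, Y, config: ModelConfig):
    """Cross-entropy + L2 loss and gradients for one minibatch."""
    B = len(X)
    probs, (caches, h_last, a_fc, r) = forward(params, X, config, with_cache=True)
    lam = config.l2_lambda
    ce = -np.mean(np.sum(Y * np.log(probs + 1e-12), axis=1))
    l2 = 0.5 * lam * sum(
        np.sum(params[k] ** 2) for k in params if k.startswith("W")
    )
    grads = {}
    dscores = (probs - Y) / B
    grads["W_out"] = r.T @ dscores + lam * params["W_out"]
    grads["b_out"] = dscores.sum(axis=0)
    dr = dscores @ params["W_out"].T
    da = dr * (a_fc > 0)
    grads["W_fc"] = h_last.T @ da + lam * params["W_fc"]
    grads["b_fc"] = da.sum(axis=0)
    dh_top = da @ params["W_fc"].T

    T, H = config.window_size, config.lstm_units
    dH = np.zeros((B, T, H))
    dH[:, -1] = dh_top
    for l in range(config.lstm_layers - 1, -1, -1):
        cache, Hs = caches[l]
        prev_h = [np.zeros((B, H))] + [Hs[:, t] for t in range(T - 1)]
        dX, dWx, dWh, db = _lstm_backward(dH, cache, params[f"Wx{l}"], params[f"Wh{l}"], prev_h)
        grads[f"Wx{l}"] = dWx + lam * params[f"Wx{l}"]
        grads[f"Wh{l}"] = dWh + lam * params[f"Wh{l}"]
        grads[f"b{l}"] = db
        dH = dX
    return ce + l2, grads


class Optimizer:
    """Adam (default) or plain SGD on the parameter dict."""

    def __init__(self, params, lr, kind="adam", beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.kind = lr, kind
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        if kind == "adam":
            self.m = {k: np.zeros_like(v) for k, v in params.items()}
            self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        if self.kind == "sgd":
            for k in params:
                params[k] -= self.lr * grads[k]
            return
        b1, b2 = self.beta1, self.beta2
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainedModel:
    """Fitted parameters plus the config and class order that produced them."""

    params: dict
    config: ModelConfig
    class_order: tuple = CLASS_ORDER
    history: TrainingHistory | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return forward(self.params, np.asarray(X, dtype=np.float64), self.config)

    def predict(self, X: np.ndarray):
        """(label, probability vector) per window; argmax ties break to the
        earliest class in class_order (argmax returns the first maximum)."""
        probs = self.predict_proba(X)
        labels = [self.class_order[i] for i in np.argmax(probs, axis=1)]
        return list(zip(labels, probs))

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return np.array([lab for lab, _ in self.predict(X)])


def _clip_global_norm(grads: dict, max_norm: float) -> None:
    """Rescale all gradients in place so their global L2 norm <= max_norm.

    Long unrolls (150 steps) occasionally produce exploding gradients that
    a single Adam step cannot absorb; clipping keeps optimisation stable
    without changing the descent direction.
    """
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] *= scale


def _accuracy_and_loss(params, X, Y, config, batch=4096):
    correct, ce_sum = 0, 0.0
    for s in range(0, len(X), batch):
        p = forward(params, X[s : s + batch], config)
        y = Y[s : s + batch]
        correct += int(np.sum(np.argmax(p, axis=1) == np.argmax(y, axis=1)))
        ce_sum += float(-np.sum(y * np.log(p + 1e-12)))
    return correct / len(X), ce_sum / len(X)


def train(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    config: ModelConfig,
    class_order=CLASS_ORDER,
) -> tuple[TrainedModel, TrainedModel, TrainingHistory]:
    """Fit the classifier; returns (best-by-test-accuracy, final, history).

    Minibatch order reshuffles every epoch from a generator seeded with
    ``config.seed``; with a single BLAS thread the whole run is
    bit-reproducible.  A non-finite loss aborts with the offending epoch.
    """
    if len(X_train) == 0:
        raise ConfigurationError("empty training set")
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    params = init_params(config)
    opt = Optimizer(params, config.learning_rate, config.optimizer)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory()
    best = (-1.0, None)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(X_train))
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            loss, grads = loss_and_grads(params, X_train[idx], Y_train[idx], config)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            if config.clip_norm > 0:
                _clip_global_norm(grads, config.clip_norm)
            opt.step(params, grads)
        tr_acc, tr_err = _accuracy_and_loss(params, X_train, Y_train, config)
        te_acc, te_err = _accuracy_and_loss(params, X_test, Y_test, config)
        history.train_accuracy.append(tr_acc)
        history.test_accuracy.append(te_acc)
        history.train_error.append(tr_err)
        history.test_error.append(te_err)
        if te_acc > best[0]:
            best = (te_acc, copy.deepcopy(params))
    best_params = best[1] if best[1] is not None else params
    final = TrainedModel(params, config, tuple(class_order), history)
    best_model = TrainedModel(best_params, config, tuple(class_order), history)
    return best_model, final, history


def save_model(model: TrainedModel, out_dir) -> None:
    """Persist as a directory: weights.npz + config.yaml + history.csv."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **model.params)
    meta = {
        "artifact_version": ARTIFACT_VERSION,
        "class_order": list(model.class_order),
        "config": asdict(model.config),
    }
    (out / "config.yaml").write_text(yaml.safe_dump(meta))
    if model.history is not None:
        model.history.to_frame().to_csv(out / "history.csv", index=False)


def load_model(in_dir) -> TrainedModel:
    p = pathlib.Path(in_dir)
    if not (p / "config.yaml").exists():
        raise FileNotFoundError(f"no model artifact at {in_dir}")
    meta = yaml.safe_load((p / "config.yaml").read_text())
    if meta.get("artifact_version") != ARTIFACT_VERSION:
        raise ConfigurationError(
            f"model artifact version {meta.get('artifact_version')} "
            f"!= supported {ARTIFACT_VERSION}"
        )
    with np.load(p / "weights.npz") as z:
        params = {k: z[k] for k in z.files}
    history = None
    if (p / "history.csv").exists():
        frame = pd.read_csv(p / "history.csv")
        history = TrainingHistory(
            train_accuracy=frame["train_acc"].tolist(),
            test_accuracy=frame["test_acc"].tolist(),
            train_error=frame["train_err"].tolist(),
            test_error=frame["test_err"].tolist(),
        )
    return TrainedModel(
        params=params,
        config=ModelConfig(**meta["config"]),
        class_order=tuple(meta["class_order"]),
        history=history,
    )
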