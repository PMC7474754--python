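"""A small convolutional network for 64x64x3 spectrogram tensors.

Architecture (shape chain for the default input):

    (64,64,3) -conv 3x3, 8 maps, same padding, ReLU-> (64,64,8)
    -max pool 2x2-> (32,32,8)
    -conv 3x3, 8 maps, same padding, ReLU-> (32,32,8)
    -max pool 2x2-> (16,16,8)
    -flatten-> 2048 -dense, ReLU, dropout-> 10 -dense-> 2 -softmax

Training minimises per-sample-weighted cross-entropy

    L = (1/n) * sum_i w_i * CE(y_i, p_i)

with stochastic gradient descent with momentum (SGDM); the learning rate
decays per update as lr / (1 + decay * step).  Input images live in [0, 1];
the model centres them by subtracting the training-set mean (stored with
the model), without which the all-positive inputs leave gradient descent
stalled on this small network.  Everything is plain NumPy:
forward, backward and the optimizer are implemented here, fully
deterministic given the seed and input order.  The implementation is
verified against finite-difference gradients in the test suite.

The activation is the standard rectifier max(0, a) by default; a
``softplus`` option (ln(1 + e^a)) is provided as a smooth alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CnnConfig", "CnnModel", "build_model", "train", "predict"]


@dataclass(frozen=True)
class CnnConfig:
    input_shape: tuple[int, int, int] = (64, 64, 3)
    n_filters: int = 8
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: int = 10
    n_classes: int = 2
    activation: str = "relu"  # relu | softplus
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    momentum: float = 0.9
    decay: float = 1e-6
    batch_size: int = 50
    max_epochs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        h, w, _ = self.input_shape
        p2 = self.pool_size**2
        if h % p2 or w % p2:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by "
                f"pool_size^2={p2} for the two pool stages"
            )
        if self.activation not in ("relu", "softplus"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")

    @property
    def flat_dim(self) -> int:
        h, w, _ = self.input_shape
        return (h // self.pool_size**2) * (w // self.pool_size**2) * self.n_filters

    @property
    def n_parameters(self) -> int:
        k, f, c = self.kernel_size, self.n_filters, self.input_shape[2]
        conv1 = k * k * c * f + f
        conv2 = k * k * f * f + f
        dense1 = self.flat_dim * self.dense_units + self.dense_units
        dense2 = self.dense_units * self.n_classes + self.n_classes
        return conv1 + conv2 + dense1 + dense2


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _activate(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(a, 0.0)
    return np.log1p(np.exp(-np.abs(a))) + np.maximum(a, 0.0)  # stable softplus


def _activate_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (a > 0.0).astype(a.dtype)
    return 1.0 / (1.0 + np.exp(-a))


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shape-preserving (same-padding) stride-1 convolution, NHWC layout.

    Implemented as k*k shifted matrix products, which is fast in NumPy for
    small kernels."""
    n, h, wd, _ = x.shape
    k = w.shape[0]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    out = np.broadcast_to(b, (n, h, wd, w.shape[3])).copy()
    for di in range(k):
        for dj in range(k):
            out += xp[:, di : di + h, dj : dj + wd, :] @ w[di, dj]
    return out


def _conv_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    n, h, wd, _ = x.shape
    k = w.shape[0]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for di in range(k):
        for dj in range(k):
            patch = xp[:, di : di + h, dj : dj + wd, :]
            dw[di, dj] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, di : di + h, dj : dj + wd, :] += dout @ w[di, dj].T
    db = dout.sum(axis=(0, 1, 2))
    dx = dxp[:, pad : pad + h, pad : pad + wd, :]
    return dx, dw, db


def _pool_forward(x: np.ndarray, s: int):
    n, h, w, f = x.shape
    r = (
        x.reshape(n, h // s, s, w // s, s, f)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h // s, w // s, s * s, f)
    )
    idx = r.argmax(axis=3)
    out = np.take_along_axis(r, idx[..., None, :], axis=3).squeeze(3)
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, in_shape, s: int):
    n, h, w, f = in_shape
    dr = np.zeros((n, h // s, w // s, s * s, f), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None, :], dout[..., None, :], axis=3)
    return (
        dr.reshape(n, h // s, w // s, s, s, f)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h, w, f)
    )


class CnnModel:
    """The network with its parameters, optimizer state and history.

    Parameters are kept in ``dtype`` (float32 by default, which halves the
    memory traffic of the convolution loops); pass float64 when bitwise
    agreement with high-precision references matters, e.g. for
    finite-difference gradient checks."""

    PARAM_NAMES = ("w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4")

    def __init__(self, config: CnnConfig, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        k, f = config.kernel_size, config.n_filters
        c = config.input_shape[2]
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {
            "w1": _glorot(rng, (k, k, c, f), k * k * c, k * k * f),
            "b1": np.zeros(f),
            "w2": _glorot(rng, (k, k, f, f), k * k * f, k * k * f),
            "b2": np.zeros(f),
            "w3": _glorot(rng, (config.flat_dim, config.dense_units),
                          config.flat_dim, config.dense_units),
            "b3": np.zeros(config.dense_units),
            "w4": _glorot(rng, (config.dense_units, config.n_classes),
                          config.dense_units, config.n_classes),
            "b4": np.zeros(config.n_classes),
        }
        self.params = {k_: v.astype(self.dtype) for k_, v in self.params.items()}
        self.velocity = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self.step = 0
        self.history: list[dict] = []
        self.input_offset = 0.5  # replaced by the training-set mean in train()
        self._rng = rng

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(self, x: np.ndarray, train_mode: bool = False,
                rng: np.random.Generator | None = None):
        """Forward pass; returns (probabilities, cache for backprop)."""
        cfg = self.config
        p = self.params
        x = np.asarray(x, dtype=self.dtype) - self.dtype.type(self.input_offset)
        a1 = _conv_forward(x, p["w1"], p["b1"])
        h1 = _activate(a1, cfg.activation)
        p1, idx1 = _pool_forward(h1, cfg.pool_size)
        a2 = _conv_forward(p1, p["w2"], p["b2"])
        h2 = _activate(a2, cfg.activation)
        p2, idx2 = _pool_forward(h2, cfg.pool_size)
        flat = p2.reshape(x.shape[0], -1)
        a3 = flat @ p["w3"] + p["b3"]
        h3 = _activate(a3, cfg.activation)
        if train_mode and cfg.dropout_rate > 0.0:
            keep = 1.0 - cfg.dropout_rate
            mask = (rng.random(h3.shape) < keep) / keep  # inverted dropout
            h3d = h3 * mask
        else:
            mask = None
            h3d = h3
        logits = h3d @ p["w4"] + p["b4"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache = (x, a1, h1, p1, idx1, a2, h2, p2, idx2, flat, a3, h3d, mask, probs)
        return probs, cache

    def loss_and_grads(self, x, y, sample_weights, rng=None, train_mode=True):
        """Weighted cross-entropy and parameter gradients for one batch."""
        cfg = self.config
        n = x.shape[0]
        probs, cache = self.forward(x, train_mode=train_mode, rng=rng)
        (x0, a1, h1, p1, idx1, a2, h2, p2, idx2, flat, a3, h3d, mask, _) = cache
        w = np.asarray(sample_weights, dtype=float)
        eps = 1e-12
        ce = -np.log(probs[np.arange(n), y] + eps)
        loss = float((w * ce).sum() / n)

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (w / n)[:, None]

        p = self.params
        g: dict[str, np.ndarray] = {}
        g["w4"] = h3d.T @ dlogits
        g["b4"] = dlogits.sum(axis=0)
        dh3d = dlogits @ p["w4"].T
        if mask is not None:
            dh3d = dh3d * mask
        da3 = dh3d * _activate_grad(a3, cfg.activation)
        g["w3"] = flat.T @ da3
        g["b3"] = da3.sum(axis=0)
        dflat = da3 @ p["w3"].T
        dp2 = dflat.reshape(p2.shape)
        dh2 = _pool_backward(dp2, idx2, h2.shape, cfg.pool_size)
        da2 = dh2 * _activate_grad(a2, cfg.activation)
        dp1, g["w2"], g["b2"] = _conv_backward(p1, p["w2"], da2)
        dh1 = _pool_backward(dp1, idx1, h1.shape, cfg.pool_size)
        da1 = dh1 * _activate_grad(a1, cfg.activation)
        _, g["w1"], g["b1"] = _conv_backward(x0, p["w1"], da1)
        return loss, g

    def sgd_momentum_update(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        lr = cfg.learning_rate / (1.0 + cfg.decay * self.step)
        for name in self.params:
            v = self.velocity[name]
            v *= cfg.momentum
            v -= lr * grads[name]
            self.params[name] += v
        self.step += 1


def build_model(config: CnnConfig = CnnConfig(), dtype=np.float32) -> CnnModel:
    """Allocate a seeded, untrained model; two builds with the same seed are
    bit-identical."""
    return CnnModel(config, dtype=dtype)


def train(
    model: CnnModel,
    X: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray | None = None,
    epochs: int | None = None,
    shuffle: bool = True,
) -> CnnModel:
    """Train in place with weighted cross-entropy + SGDM; returns the model.

    Deterministic given (config.seed, X order).  Raises on a single-class
    training set or if the loss turns non-finite.
    """
    cfg = model.config
    X = np.asarray(X, dtype=model.dtype)
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    if sample_weights is None:
        sample_weights = np.ones(len(y))
    sample_weights = np.asarray(sample_weights, dtype=float)
    if np.any(sample_weights <= 0) or np.any(sample_weights > 1):
        raise ValueError("sample weights must lie in (0, 1]")
    epochs = cfg.max_epochs if epochs is None else epochs
    model.input_offset = float(X.mean())
    n = len(y)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    for epoch in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            loss, grads = model.loss_and_grads(
                X[sel], y[sel], sample_weights[sel], rng=rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            model.sgd_momentum_update(grads)
            losses.append(loss * len(sel))
        probs, _ = model.forward(X)
        acc = float((probs.argmax(axis=1) == y).mean())
        model.history.append(
            dict(epoch=epoch, loss=float(np.sum(losses) / n), train_accuracy=acc)
        )
    return model


def predict(model: CnnModel, X: np.ndarray):
    """Class labels and softmax probabilities; ties go to the lower index."""
    X = np.asarray(X, dtype=model.dtype)
    if X.ndim == 3:
        X = X[None]
    if X.shape[1:] != model.config.input_shape:
        raise ValueError(
            f"expected input shape {model.config.input_shape}, got {X.shape[1:]}"
        )
    probs, _ = model.forward(X)
    return probs.argmax(axis=1), probs
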