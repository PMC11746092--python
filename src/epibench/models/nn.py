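"""Minimal NumPy neural-network layer library with manual backprop.

Provides exactly the building blocks the genotype classifiers need —
dense, 1-D convolution, LSTM, batch normalization, dropout, ReLU — plus
an Adam optimizer, a cosine-annealed learning-rate schedule and a
binary-cross-entropy training loop with early stopping and
best-on-validation checkpointing. Gradients are hand-derived and are
verified against numerical differentiation in the test suite.

All layers operate on float arrays of shape (batch, features) except the
sequence layers, which use (batch, channels, length). Randomness
(initialization, dropout masks, batch shuffling) comes from a single
``numpy.random.Generator`` supplied by the caller, so training is
reproducible on one thread.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "BatchNorm",
    "Dropout",
    "Conv1d",
    "LSTM",
    "Flatten",
    "Reshape3d",
    "Network",
    "Adam",
    "cosine_lr",
    "TrainingProtocol",
    "train_network",
    "consecutive_increases",
]


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        scale = math.sqrt(2.0 / n_in)  # He init, ReLU-friendly
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        self.dgamma[...] = (grad * self._xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        gx = grad * self.gamma
        return (gx - gx.mean(axis=0)
                - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape3d(Layer):
    """(batch, length * channels) -> (batch, channels, length).

    Input columns are position-major (all channels of position 0, then
    position 1, ...), matching the (snp, genotype-level) one-hot layout.
    """

    def __init__(self, channels: int, length: int):
        self.channels = channels
        self.length = length

    def forward(self, x, training):
        return x.reshape(x.shape[0], self.length, self.channels).transpose(0, 2, 1)

    def backward(self, grad):
        return np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(grad.shape[0], -1)


class Conv1d(Layer):
    """1-D convolution via im2col, valid padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator, dtype=np.float64):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        scale = math.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, scale,
                            size=(out_channels, in_channels, kernel)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.stride = stride

    def out_length(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def _im2col(self, x):
        n, c, length = x.shape
        t_out = self.out_length(length)
        idx = (np.arange(t_out)[:, None] * self.stride + np.arange(self.kernel))
        # (n, c, t_out, kernel) -> (n, t_out, c * kernel)
        cols = x[:, :, idx]
        return cols.transpose(0, 2, 1, 3).reshape(n, t_out, -1), idx

    def forward(self, x, training):
        self._x_shape = x.shape
        cols, self._idx = self._im2col(x)
        self._cols = cols
        w2 = self.W.reshape(self.W.shape[0], -1)
        out = cols @ w2.T + self.b  # (n, t_out, out_channels)
        return out.transpose(0, 2, 1)

    def backward(self, grad):
        n, _, t_out = grad.shape
        g = grad.transpose(0, 2, 1)  # (n, t_out, out_channels)
        w2 = self.W.reshape(self.W.shape[0], -1)
        self.dW[...] = np.einsum("nto,ntk->ok", g, self._cols).reshape(self.W.shape)
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ w2  # (n, t_out, c*kernel)
        _, c, length = self._x_shape
        dcols = dcols.reshape(n, t_out, c, self.kernel).transpose(0, 2, 1, 3)
        dx = np.zeros(self._x_shape, dtype=grad.dtype)
        np.add.at(dx, (slice(None), slice(None), self._idx), dcols)
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class LSTM(Layer):
    """Single-layer LSTM over (batch, channels, length) sequences.

    ``return_sequence=False`` emits the final hidden state (batch, hidden);
    otherwise the full hidden sequence (batch, hidden, length).
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator, return_sequence: bool = False,
                 dtype=np.float64):
        scale = math.sqrt(1.0 / hidden_size)
        self.W = rng.uniform(-scale, scale,
                             size=(input_size + hidden_size, 4 * hidden_size)
                             ).astype(dtype)
        self.b = np.zeros(4 * hidden_size, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.hidden_size = hidden_size
        self.return_sequence = return_sequence

    @staticmethod
    def _sigmoid(z):
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        e = np.exp(z[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    def forward(self, x, training):
        n, c, length = x.shape
        h_dim = self.hidden_size
        h = np.zeros((n, h_dim), dtype=x.dtype)
        cell = np.zeros((n, h_dim), dtype=x.dtype)
        self._cache = []
        hs = np.empty((n, h_dim, length), dtype=x.dtype)
        for t in range(length):
            xt = x[:, :, t]
            z = np.concatenate([xt, h], axis=1) @ self.W + self.b
            i = self._sigmoid(z[:, :h_dim])
            f = self._sigmoid(z[:, h_dim:2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
            o = self._sigmoid(z[:, 3 * h_dim:])
            cell_new = f * cell + i * g
            tc = np.tanh(cell_new)
            h_new = o * tc
            self._cache.append((xt, h, cell, i, f, g, o, tc))
            h, cell = h_new, cell_new
            hs[:, :, t] = h
        self._x_shape = x.shape
        self._hs = hs
        return hs if self.return_sequence else h

    def backward(self, grad):
        n, c, length = self._x_shape
        h_dim = self.hidden_size
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.zeros(self._x_shape, dtype=self.W.dtype)
        dh_next = np.zeros((n, h_dim), dtype=self.W.dtype)
        dc_next = np.zeros((n, h_dim), dtype=self.W.dtype)
        for t in reversed(range(length)):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dh_next + (grad[:, :, t] if self.return_sequence
                            else (grad if t == length - 1 else 0.0))
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1)
            concat = np.concatenate([xt, h_prev], axis=1)
            dW += concat.T @ dz
            db += dz.sum(axis=0)
            dconcat = dz @ self.W.T
            dx[:, :, t] = dconcat[:, :c]
            dh_next = dconcat[:, c:]
            dc_next = dc * f
        self.dW[...] = dW
        self.db[...] = db
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Network:
    """A sequential stack ending in a single-logit dense layer."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x.reshape(-1)

    def backward(self, grad: np.ndarray) -> None:
        g = grad[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start:start + batch_size], training=False)
            out[start:start + batch_size] = LSTM._sigmoid(logits)
        return out

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def state_dict(self):
        state = [p.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def load_state_dict(self, state):
        state = list(state)
        for p in self.params():
            p[...] = state.pop(0)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state.pop(0)
                layer.running_var[...] = state.pop(0)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(epoch: int, lr_max: float = 1e-3, lr_min: float = 1e-4,
              period: int = 10) -> float:
    """Cosine-annealed learning rate cycling lr_max -> lr_min every period."""
    phase = (epoch % period) / period
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * phase))


def consecutive_increases(losses: list[float]) -> int:
    """Length of the strictly-increasing run ending the loss history."""
    run = 0
    for prev, cur in zip(losses, losses[1:]):
        run = run + 1 if cur > prev else 0
    return run


@dataclass
class TrainingProtocol:
    """Neural training configuration.

    ``patience`` is the number of consecutive epochs of rising validation
    loss beyond which training stops (the run stops once the count
    exceeds it).
    """

    epochs: int = 100
    batch_size: int = 256
    lr_max: float = 1e-3
    lr_min: float = 1e-4
    lr_period: int = 10
    patience: int = 5


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None
    best_epoch: int | None = None


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_network(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    protocol: TrainingProtocol,
    rng: np.random.Generator,
) -> TrainingHistory:
    """Adam + binary cross-entropy training loop.

    Each epoch the learning rate follows the cosine cycle, training data
    is reshuffled, and validation loss and AUC-ROC are recorded. Training
    stops early once validation loss has increased for more than
    ``protocol.patience`` consecutive epochs; the parameters giving the
    best validation AUC-ROC are restored before returning.
    """
    from sklearn.metrics import roc_auc_score

    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    history = TrainingHistory()
    optimizer = Adam(net.params())
    best_auc, best_state = -np.inf, net.state_dict()
    n = x_train.shape[0]
    for epoch in range(protocol.epochs):
        optimizer.lr = cosine_lr(epoch, protocol.lr_max, protocol.lr_min,
                                 protocol.lr_period)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, protocol.batch_size):
            idx = order[start:start + protocol.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = net.forward(xb, training=True)
            p = LSTM._sigmoid(logits)
            loss = _bce(yb, p)
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            epoch_loss += loss * len(idx)
            net.backward((p - yb) / len(idx))
            optimizer.step(net.grads())
        history.train_loss.append(epoch_loss / n)
        p_val = net.predict_proba(x_val)
        history.val_loss.append(_bce(y_val, p_val))
        auc = (roc_auc_score(y_val, p_val)
               if y_val.min() != y_val.max() else 0.5)
        history.val_auc.append(auc)
        if auc > best_auc:
            best_auc = auc
            best_state = net.state_dict()
            history.best_epoch = epoch
        if consecutive_increases(history.val_loss) > protocol.patience:
            history.stopped_epoch = epoch
            break
    net.load_state_dict(best_state)
    return history
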