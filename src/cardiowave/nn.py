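"""Minimal numpy neural-network engine for scalogram-image training.

Implements exactly the layer set the custom scalogram CNN needs —
valid-padding stride-1 convolution, ReLU, non-overlapping max pooling,
flatten, dense — plus Adam and sigmoid binary cross-entropy with
logits.  Forward/backward use im2col-style vectorization; everything is
float64 and deterministic given a seed.  This is a training backend for
small smoke-scale networks, not a general deep-learning framework.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidArgumentError


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:      # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _sliding_patches(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H2, W2, kh*kw*C) patches of an NHWC tensor (stride 1, valid)."""
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # view: (N, H2, W2, C, kh, kw) -> (N, H2, W2, kh, kw, C)
    view = view.transpose(0, 1, 2, 4, 5, 3)
    n, h2, w2 = view.shape[:3]
    return view.reshape(n, h2, w2, kh * kw * x.shape[3])


class Conv2D(Layer):
    """Valid-padding stride-1 convolution, NHWC layout."""

    def __init__(self, in_channels: int, filters: int, kernel_hw: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel_hw
        fan_in = kh * kw * in_channels
        self.kh, self.kw = kh, kw
        self.w = rng.standard_normal((fan_in, filters)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(filters)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = _sliding_patches(x, self.kh, self.kw)
        return self._cols @ self.w + self.b

    def backward(self, dout):
        n, h2, w2, f = dout.shape
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        dflat = dout.reshape(-1, f)
        self.grads[0][...] = cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.w.T).reshape(n, h2, w2, self.kh, self.kw, -1)
        dx = np.zeros(self._x_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i:i + h2, j:j + w2, :] += dcols[:, :, :, i, j, :]
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(Layer):
    """Non-overlapping pooling (stride == kernel), valid semantics."""

    def __init__(self, kernel_hw: tuple[int, int]):
        super().__init__()
        self.kh, self.kw = kernel_hw

    def forward(self, x):
        n, h, w, c = x.shape
        h2 = (h - self.kh) // self.kh + 1
        w2 = (w - self.kw) // self.kw + 1
        self._x_shape = x.shape
        cropped = x[:, : h2 * self.kh, : w2 * self.kw, :]
        blocks = cropped.reshape(n, h2, self.kh, w2, self.kw, c)
        out = blocks.max(axis=(2, 4))
        # argmax mask; ties split the gradient evenly
        expanded = out[:, :, None, :, None, :]
        mask = (blocks == expanded).astype(float)
        self._mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1.0)
        self._pool_dims = (h2, w2)
        return out

    def backward(self, dout):
        n, h2, w2, c = dout.shape
        d = self._mask * dout[:, :, None, :, None, :]
        dx = np.zeros(self._x_shape)
        dx[:, : h2 * self.kh, : w2 * self.kw, :] = d.reshape(
            n, h2 * self.kh, w2 * self.kw, c)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.standard_normal((in_dim, units)) * np.sqrt(2.0 / in_dim)
        self.b = np.zeros(units)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size]).ravel()
            out.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(out) if out else np.zeros(0)


class Adam:
    def __init__(self, network: Network, lr: float = 8e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = network
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for l in network.layers for p in l.params]
        self.v = [np.zeros_like(p) for l in network.layers for p in l.params]

    def step(self):
        self.t += 1
        k = 0
        for layer in self.net.layers:
            for p, g in zip(layer.params, layer.grads):
                self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
                self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
                mhat = self.m[k] / (1 - self.b1**self.t)
                vhat = self.v[k] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                k += 1


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean sigmoid binary cross-entropy and its gradient w.r.t. logits."""
    z = logits.ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / z.size).reshape(logits.shape)
    return loss, grad


def train_binary(
    network: Network,
    x: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int = 30,
    batch_size: int = 16,
    learning_rate: float = 8e-4,
    seed: int = 0,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    patience: int = 5,
) -> dict:
    """Adam + BCE minibatch training; early stop on validation loss.

    Without a validation set, training stops early once the training
    epoch loss drops below 1e-3 (the separable-data regime).
    """
    if x.shape[0] != y.shape[0] or x.shape[0] == 0:
        raise InvalidArgumentError("images and labels must align and be non-empty")
    rng = np.random.default_rng(seed)
    opt = Adam(network, lr=learning_rate)
    history = {"loss": [], "val_loss": []}
    best_val, stall = np.inf, 0
    best_state = None
    for _ in range(epochs):
        order = rng.permutation(x.shape[0])
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            logits = network.forward(x[idx])
            loss, grad = bce_with_logits(logits, y[idx])
            network.backward(grad)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history["loss"].append(epoch_loss)
        if x_val is not None and len(x_val):
            p = np.clip(network.predict_proba(x_val), 1e-12, 1 - 1e-12)
            val_loss = float(np.mean(-(y_val * np.log(p) + (1 - y_val) * np.log(1 - p))))
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-4:
                best_val, stall = val_loss, 0
                best_state = [[p_.copy() for p_ in l.params] for l in network.layers]
            else:
                stall += 1
                if stall >= patience:
                    break
        elif epoch_loss < 1e-3:
            break
    if best_state is not None:
        for layer, saved in zip(network.layers, best_state):
            for p_, s in zip(layer.params, saved):
                p_[...] = s
    return history
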