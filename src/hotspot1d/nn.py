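"""Minimal 1-D convolutional network in numpy.

Layers operate on arrays of shape (N, L, C): batch, window axis, channels.
Convolution kernels span the full channel depth and slide only along the
window axis ("same" padding, stride 1), which for residue windows means the
kernel always sees complete per-residue feature vectors.  Gradients are
exact; optimization is RMSprop on mini-batches.

Kept deliberately small: just the pieces the hot-spot classifier needs
(conv + relu/tanh + maxpool blocks, dropout, dense head, weighted binary
cross-entropy), each with a hand-derived backward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1DSame",
    "Activation",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "RMSprop",
    "sigmoid",
    "weighted_bce_and_grad",
]

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
}


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1DSame(Layer):
    """1-D convolution along the window axis, odd kernel, stride 1, zero
    "same" padding; weights (k, C_in, C_out)."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for symmetric same padding")
        self.kernel, self.c_in, self.c_out = kernel, c_in, c_out
        w = glorot_uniform(rng, (kernel, c_in, c_out), kernel * c_in, kernel * c_out)
        self.params = [w, np.zeros(c_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _patches(self, x: np.ndarray) -> np.ndarray:
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # (N, L, k, C): window view along the length axis
        return sliding_window_view(xp, self.kernel, axis=1).transpose(0, 1, 3, 2)

    def forward(self, x, train, rng):
        n, length, _ = x.shape
        patches = self._patches(x).reshape(n, length, self.kernel * self.c_in)
        self._cache = (patches, x.shape)
        w, b = self.params
        return patches @ w.reshape(self.kernel * self.c_in, self.c_out) + b

    def backward(self, dout):
        patches, x_shape = self._cache
        n, length, _ = x_shape
        w, _ = self.params
        self.grads[0][...] = (
            patches.reshape(-1, self.kernel * self.c_in).T @ dout.reshape(-1, self.c_out)
        ).reshape(w.shape)
        self.grads[1][...] = dout.sum(axis=(0, 1))
        # dx: correlate dout with the kernel flipped along the window axis
        w_flip = w[::-1].transpose(0, 2, 1)  # (k, C_out, C_in)
        pad = self.kernel // 2
        dp = np.pad(dout, ((0, 0), (pad, pad), (0, 0)))
        dpatch = sliding_window_view(dp, self.kernel, axis=1).transpose(0, 1, 3, 2)
        return dpatch.reshape(n, length, self.kernel * self.c_out) @ w_flip.reshape(
            self.kernel * self.c_out, self.c_in
        )


class Activation(Layer):
    def __init__(self, name: str):
        super().__init__()
        if name not in _ACTIVATIONS:
            raise ValueError(f"unsupported activation {name!r}; choose from {sorted(_ACTIVATIONS)}")
        self.name = name

    def forward(self, x, train, rng):
        fn, _ = _ACTIVATIONS[self.name]
        out = fn(x)
        self._cache = (x, out)
        return out

    def backward(self, dout):
        _, dfn = _ACTIVATIONS[self.name]
        z, a = self._cache
        return dout * dfn(z, a)


class MaxPool1D(Layer):
    """Max pooling along the window axis; length L -> floor(L/size), any
    remainder truncated."""

    def __init__(self, size: int = 2):
        super().__init__()
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size

    def forward(self, x, train, rng):
        n, length, c = x.shape
        out_len = length // self.size
        xt = x[:, : out_len * self.size].reshape(n, out_len, self.size, c)
        argmax = xt.argmax(axis=2)
        self._cache = (x.shape, argmax)
        return np.take_along_axis(xt, argmax[:, :, None, :], axis=2).squeeze(2)

    def backward(self, dout):
        x_shape, argmax = self._cache
        n, length, c = x_shape
        out_len = length // self.size
        dx = np.zeros((n, out_len, self.size, c), dtype=dout.dtype)
        np.put_along_axis(dx, argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        full = np.zeros(x_shape, dtype=dout.dtype)
        full[:, : out_len * self.size] = dx.reshape(n, out_len * self.size, c)
        return full


class Dropout(Layer):
    """Inverted dropout: active only in training; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training forward pass needs an RNG"
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.params = [w, np.zeros(n_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        self._cache = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout):
        x = self._cache
        w, _ = self.params
        self.grads[0][...] = x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


class Network:
    """A plain layer stack ending in a single logit; sigmoid applied by the
    probability helpers, not stored as a layer."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x[:, 0]  # logits

    def backward(self, dlogit: np.ndarray) -> None:
        dout = dlogit[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        chunks = [
            sigmoid(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks) if chunks else np.zeros(0)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class RMSprop:
    """Root-mean-square propagation: cache = rho*cache + (1-rho)*g^2,
    step = lr * g / (sqrt(cache) + eps)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


def weighted_bce_and_grad(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits plus its gradient d(loss)/d(logit).

    Stable log-sum-exp form; optional per-sample weights implement the
    class-weight balancing mode.
    """
    y = np.asarray(y, dtype=np.float64)
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    # log(1 + e^z) computed stably
    softplus = np.maximum(logits, 0.0) + np.log1p(np.exp(-np.abs(logits)))
    loss = float(np.mean(w * (softplus - y * logits)))
    grad = w * (sigmoid(logits) - y) / len(y)
    return loss, grad
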