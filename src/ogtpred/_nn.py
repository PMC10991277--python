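"""Minimal numpy neural-network primitives for the 1-D convolutional
regressor: layers with explicit forward/backward passes and an Adam
optimiser with the AMSGRAD correction.

Everything is float32 and CPU-sized.  All stochasticity (weight
initialisation, dropout masks) flows through generators handed in by the
caller, so a fixed seed reproduces training bit-for-bit in a fixed
environment.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameter-free identity."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution over (N, L, C_in) → (N, L-k+1, C_out).

    He-normal initialisation; weights stored as (k * C_in, C_out) so both
    passes are single matmuls over an im2col view.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        self.k = int(kernel_size)
        self.c_in = int(c_in)
        self.c_out = int(c_out)
        scale = np.sqrt(2.0 / (self.k * self.c_in))
        self.w = (rng.standard_normal((self.k * self.c_in, self.c_out)) * scale).astype(np.float32)
        self.b = np.zeros(self.c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, length, _ = x.shape
        if length < self.k:
            raise ValueError(f"input length {length} < kernel size {self.k}")
        # (N, P, C_in, k) -> (N, P, k, C_in) -> (N*P, k*C_in)
        win = sliding_window_view(x, self.k, axis=1)
        p = length - self.k + 1
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n * p, self.k * self.c_in)
        self._cols = cols if train else None
        self._in_len = length
        y = cols @ self.w + self.b
        return y.reshape(n, p, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, p, _ = grad.shape
        gmat = grad.reshape(n * p, self.c_out)
        assert self._cols is not None, "backward before training forward"
        self.dw = (self._cols.T @ gmat) / n
        self.db = gmat.sum(axis=0) / n
        dcols = (gmat @ self.w.T).reshape(n, p, self.k, self.c_in)
        dx = np.zeros((n, self._in_len, self.c_in), dtype=np.float32)
        for j in range(self.k):
            dx[:, j : j + p, :] += dcols[:, :, j, :]
        return dx

    def params(self) -> list[dict]:
        return [
            {"value": self.w, "grad": lambda: self.dw, "name": "conv_w"},
            {"value": self.b, "grad": lambda: self.db, "name": "conv_b"},
        ]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis; a trailing
    remainder shorter than the window is dropped."""

    def __init__(self, pool_size: int = 2):
        self.pool = int(pool_size)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, length, c = x.shape
        p = length // self.pool
        if p == 0:
            raise ValueError(f"input length {length} < pool size {self.pool}")
        trimmed = x[:, : p * self.pool, :].reshape(n, p, self.pool, c)
        self._argmax = trimmed.argmax(axis=2)
        self._in_shape = x.shape
        return trimmed.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, p, c = grad.shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        view = dx[:, : p * self.pool, :].reshape(n, p, self.pool, c)
        ni, pi, ci = np.ogrid[:n, :p, :c]
        view[ni, pi, self._argmax, ci] = grad
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        self.dw = self._x.T @ grad / n
        self.db = grad.sum(axis=0) / n
        return grad @ self.w.T

    def params(self) -> list[dict]:
        return [
            {"value": self.w, "grad": lambda: self.dw, "name": "dense_w"},
            {"value": self.b, "grad": lambda: self.db, "name": "dense_b"},
        ]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p["value"].size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError(
                f"expected {len(params)} weight arrays, got {len(weights)}"
            )
        for p, w in zip(params, weights):
            if p["value"].shape != w.shape:
                raise ValueError(
                    f"shape mismatch for {p['name']}: {p['value'].shape} vs {w.shape}"
                )
            p["value"][...] = w


class Adam:
    """Adam with the optional AMSGRAD max-of-second-moment correction."""

    def __init__(
        self,
        params: list[dict],
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        amsgrad: bool = True,
    ):
        self.params = params
        self.lr = float(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.vhat = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            g = p["grad"]()
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / b1t
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                v_hat = self.vhat[i] / b2t
            else:
                v_hat = self.v[i] / b2t
            p["value"] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred`` (summed over the
    batch inside the layers, so the gradient here is per-sample)."""
    diff = (pred - target).astype(np.float32)
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff
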