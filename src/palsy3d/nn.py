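"""Minimal NumPy neural-network core: dense/batch-norm/ReLU layers, max
pooling over points, and an Adam optimizer, with hand-written backprop.

Only what the dual-branch point-cloud regressor needs is implemented.  All
layers operate on 2-D ``(rows, channels)`` float32 arrays; a shared per-point
MLP is realised by flattening ``(batch, points, channels)`` to rows, so the
same weights are applied to every point identically.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Dense:
    """Affine layer ``y = x W + b`` with He-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ dy
        self.gb = dy.sum(axis=0)
        return dy @ self.W.T

    def params_and_grads(self):
        yield self.W, self.gW
        yield self.b, self.gb


class BatchNorm:
    """Batch normalisation over rows, with running statistics for inference."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_channels, dtype=DTYPE)
        self.beta = np.zeros(n_channels, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dy.shape[0]
        self.ggamma = (dy * xhat).sum(axis=0)
        self.gbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )

    def params_and_grads(self):
        yield self.gamma, self.ggamma
        yield self.beta, self.gbeta


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params_and_grads(self):
        return iter(())


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params_and_grads(self):
        for layer in self.layers:
            yield from layer.params_and_grads()


def max_pool_points(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric max aggregation over the point axis of ``(B, N, F)``.

    Returns the pooled ``(B, F)`` features and the argmax indices needed to
    route gradients back to the supporting points.  Invariant to any
    permutation of the points by construction.
    """
    arg = features.argmax(axis=1)
    pooled = np.take_along_axis(features, arg[:, None, :], axis=1)[:, 0, :]
    return pooled, arg


def max_pool_backward(
    d_pooled: np.ndarray, arg: np.ndarray, n_points: int
) -> np.ndarray:
    d = np.zeros((d_pooled.shape[0], n_points, d_pooled.shape[1]), dtype=d_pooled.dtype)
    np.put_along_axis(d, arg[:, None, :], d_pooled[:, None, :], axis=1)
    return d


class Adam:
    """Adaptive moment estimation over a fixed list of (param, grad) pairs."""

    def __init__(self, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params_and_grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in params_and_grads]
            self._v = [np.zeros_like(p) for p, _ in params_and_grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for (p, g), m, v in zip(params_and_grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
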