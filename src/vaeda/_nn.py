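"""Minimal feed-forward neural-network primitives on numpy.

Implements exactly the building blocks the doublet-annotation networks need:
dense layers, batch normalization, inverted dropout, softplus-parameterized
Gaussian heads, softmax, and the Adamax optimizer.  Every layer exposes
``forward(x, training)`` and ``backward(grad)``; parameters and their
gradients live in plain dicts so the optimizer can walk them generically.

All randomness flows through an explicit ``numpy.random.Generator`` so runs
are bit-reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "BatchNorm",
    "Dropout",
    "ReLU",
    "Adamax",
    "softplus",
    "sigmoid",
]


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(x))."""
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameterized layers fill ``params`` and ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map x @ W + b with Glorot-uniform init (or zeros)."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        zero_init: bool = False,
        dtype=np.float64,
    ) -> None:
        super().__init__()
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            limit = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(n_out, dtype=dtype)}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class BatchNorm(Layer):
    """Batch normalization with running statistics for inference.

    Uses batch statistics while training and exponential running averages
    (momentum 0.99, eps 1e-3) at inference, matching common deep-learning
    framework defaults.
    """

    def __init__(self, n: int, momentum: float = 0.99, eps: float = 1e-3, dtype=np.float64) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(n, dtype=dtype), "beta": np.zeros(n, dtype=dtype)}
        self.running_mean = np.zeros(n, dtype=dtype)
        self.running_var = np.ones(n, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.grads["gamma"] = (grad * xhat).sum(axis=0)
        self.grads["beta"] = grad.sum(axis=0)
        gx = grad * self.params["gamma"]
        if not self._training:
            return gx * inv_std
        m = xhat.shape[0]
        return (inv_std / m) * (m * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Adamax:
    """Adamax optimizer (Adam with the infinity norm), framework defaults.

    update: m <- b1*m + (1-b1)*g ; u <- max(b2*u, |g|)
            theta <- theta - lr/(1-b1^t) * m / (u + eps)
    """

    def __init__(self, layers, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._u = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        corr = 1.0 - self.beta1**self.t
        for layer, m, u in zip(self.layers, self._m, self._u):
            for k, g in layer.grads.items():
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                u[k] = np.maximum(self.beta2 * u[k], np.abs(g))
                layer.params[k] -= (self.lr / corr) * m[k] / (u[k] + self.eps)
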