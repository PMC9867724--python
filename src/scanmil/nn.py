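"""Minimal numpy neural-network utilities shared by the MIL models.

The trainable heads in this package are small (of order 1M parameters), so
forward and backward passes are written directly in numpy with hand-derived
gradients; tests verify them against finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "sigmoid", "bce_loss", "bce_grad", "init_normal", "softmax"]


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x)))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over a 1-D logit vector (max subtraction)."""
    z = logits - np.max(logits)
    e = np.exp(z)
    return e / e.sum()


_EPS = 1e-12


def bce_loss(p: float, y: float) -> float:
    p = float(np.clip(p, _EPS, 1.0 - _EPS))
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def bce_grad(p: float, y: float) -> float:
    """d(BCE)/d(logit) for p = sigmoid(logit): simply p - y."""
    return float(p - y)


def init_normal(rng: np.random.Generator, shape, std: float | None = None,
                fan_in: int | None = None) -> np.ndarray:
    """Normal-distribution initialization for learned parameters.

    With ``std=None`` the scale defaults to 1/sqrt(fan_in) (fan_in inferred
    from the shape when not given): a fixed small std would shrink
    activations by a factor ~std*sqrt(fan_in) per 512-wide layer and stall
    learning at the 1e-4 learning rate.
    """
    if std is None:
        if fan_in is None:
            fan_in = shape[0] if isinstance(shape, tuple) and len(shape) >= 2 else 1
        std = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.normal(0.0, std, size=shape)


class Adam:
    """Adam optimizer over a dict of named parameter arrays.

    Defaults follow the training recipe used throughout this package:
    beta1 = 0.9, beta2 = 0.99, initial learning rate 1e-4.

    All moment state lives in flat buffers so the update is a handful of
    vectorized in-place passes regardless of how many parameter tensors the
    model has; parameter arrays are updated in place through slice views.
    """

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._keys = list(params)
        self._slices = {}
        total, offset = sum(int(v.size) for v in params.values()), 0
        dtype = np.result_type(*[v.dtype for v in params.values()])
        for k in self._keys:
            n = int(params[k].size)
            self._slices[k] = slice(offset, offset + n)
            offset += n
        self.m = np.zeros(total, dtype=dtype)
        self.v = np.zeros(total, dtype=dtype)
        self._g = np.zeros(total, dtype=dtype)

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        g = self._g
        for k in self._keys:
            g[self._slices[k]] = np.ravel(grads[k])
        self.m *= b1
        self.m += (1 - b1) * g
        np.multiply(g, g, out=g)
        self.v *= b2
        self.v += (1 - b2) * g
        denom = np.sqrt(self.v)
        denom /= np.sqrt(1 - b2**self.t)
        denom += self.eps
        update = self.m / denom
        update *= self.lr / (1 - b1**self.t)
        for k in self._keys:
            p = self.params[k]
            p -= update[self._slices[k]].reshape(p.shape).astype(p.dtype, copy=False)
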