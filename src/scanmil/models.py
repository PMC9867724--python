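"""MIL heads and the noisy-2D baseline.

The MIL head composes three stages: a trainable instance tail (two fully
connected layers with ReLU and dropout 0.5 applied to the frozen extractor
features), a permutation-invariant pooling operator P (attention, mean or
max), and a bag classifier g (affine map to a sigmoid probability). The
attention pooling follows the gated-free formulation

    a_n = softmax_n( w^T tanh(V x_n) ),    z = sum_n a_n x_n

with embedding dimension 512 and attention hidden dimension 128 by default.
Attention weights are non-negative, sum to one per bag, and expose which
slices drove the scan-level decision.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .nn import Adam, bce_grad, bce_loss, init_normal, sigmoid, softmax

__all__ = [
    "attention_pool",
    "mean_pool",
    "max_pool",
    "MILHead",
    "Noisy2DClassifier",
    "BagPrediction",
]

POOLING_MODES = ("attention", "mean", "max")


def _check_instances(instances: np.ndarray) -> np.ndarray:
    x = np.asarray(instances, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValidationError(f"instances must be (N>=1, D), got shape {x.shape}")
    return x


def attention_pool(instances: np.ndarray, w: np.ndarray, V: np.ndarray):
    """Attention-weighted average of instance vectors.

    Returns ``(z, a)`` with ``a_n = softmax(w^T tanh(V x_n))`` and
    ``z = sum_n a_n x_n``. The softmax subtracts the max logit for stability.
    """
    x = _check_instances(instances)
    w = np.asarray(w, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2 or w.ndim != 1 or V.shape[0] != w.shape[0]:
        raise ValidationError(
            f"attention params mismatched: w {w.shape}, V {V.shape}"
        )
    if V.shape[1] != x.shape[1]:
        raise ValidationError(
            f"V maps dim {V.shape[1]} but instances have dim {x.shape[1]}"
        )
    logits = np.tanh(x @ V.T) @ w
    a = softmax(logits)
    return a @ x, a


def mean_pool(instances: np.ndarray) -> np.ndarray:
    """Element-wise mean across instances."""
    return _check_instances(instances).mean(axis=0)


def max_pool(instances: np.ndarray) -> np.ndarray:
    """Element-wise max across instances."""
    return _check_instances(instances).max(axis=0)


class BagPrediction:
    """Scan-level prediction: probability plus attention weights if available."""

    __slots__ = ("scan_id", "probability", "attention")

    def __init__(self, scan_id, probability, attention=None):
        self.scan_id = scan_id
        self.probability = float(probability)
        self.attention = None if attention is None else np.asarray(attention)

    def __repr__(self):
        return f"BagPrediction({self.scan_id!r}, p={self.probability:.4f})"


class MILHead:
    """Trainable MIL head over frozen instance features.

    Parameters
    ----------
    d_raw : int
        Dimension of the frozen extractor features.
    pooling : {'attention', 'mean', 'max'}
        Pooling operator P.
    hidden, embed : int
        Widths of the two fully connected layers (d_raw -> hidden -> embed);
        the pooling operates on the embed-dimensional instance vectors.
    attn_hidden : int
        Attention hidden dimension (w in R^attn_hidden, V in R^{attn_hidden x embed}).
    dropout : float
        Dropout rate after each FC ReLU, active in training mode only.
    init_std : float or None
        All parameters are initialized from N(0, std^2); None (default)
        scales each tensor's std as 1/sqrt(fan_in).
    dtype : numpy dtype
        Parameter/compute dtype; float32 by default for speed, use float64
        for high-precision checks.
    """

    def __init__(
        self,
        d_raw: int,
        pooling: str = "attention",
        hidden: int = 512,
        embed: int = 512,
        attn_hidden: int = 128,
        dropout: float = 0.5,
        init_std: float | None = None,
        lr: float = 1e-4,
        seed: int = 0,
        dtype=np.float32,
    ):
        if pooling not in POOLING_MODES:
            raise ValidationError(f"pooling must be one of {POOLING_MODES}")
        self.d_raw = d_raw
        self.pooling = pooling
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        bias_std = init_std if init_std is not None else 0.01
        p = {
            "W1": init_normal(rng, (d_raw, hidden), init_std),
            "b1": init_normal(rng, hidden, bias_std),
            "W2": init_normal(rng, (hidden, embed), init_std),
            "b2": init_normal(rng, embed, bias_std),
            "u": init_normal(rng, embed, init_std, fan_in=embed),
            "c": init_normal(rng, (), bias_std),
        }
        if pooling == "attention":
            p["V"] = init_normal(rng, (attn_hidden, embed), init_std, fan_in=embed)
            p["w"] = init_normal(rng, attn_hidden, init_std, fan_in=attn_hidden)
        self.dtype = dtype
        self.params = {k: np.asarray(v, dtype=dtype) for k, v in p.items()}
        self.opt = Adam(self.params, lr=lr)

    # -- parameter bookkeeping -------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k][...] = state[k]

    # -- forward / backward ----------------------------------------------
    def _forward(self, X: np.ndarray, training: bool, rng=None):
        X = _check_instances(X)
        if X.shape[1] != self.d_raw:
            raise ValidationError(
                f"expected features of dim {self.d_raw}, got {X.shape[1]}"
            )
        X = X.astype(self.dtype, copy=False)
        p = self.params
        cache = {"X": X}
        H1p = X @ p["W1"] + p["b1"]
        H1 = np.maximum(H1p, 0.0)
        if training and self.dropout > 0:
            keep = self.dtype(1.0 - self.dropout)
            m1 = (rng.random(H1.shape) < keep).astype(self.dtype) / keep
            H1 = H1 * m1
            cache["m1"] = m1
        H2p = H1 @ p["W2"] + p["b2"]
        H2 = np.maximum(H2p, 0.0)
        if training and self.dropout > 0:
            keep = self.dtype(1.0 - self.dropout)
            m2 = (rng.random(H2.shape) < keep).astype(self.dtype) / keep
            H2 = H2 * m2
            cache["m2"] = m2
        cache.update(H1p=H1p, H1=H1, H2p=H2p, H=H2)
        a = None
        if self.pooling == "attention":
            t = np.tanh(H2 @ p["V"].T)
            a = softmax(t @ p["w"])
            z = a @ H2
            cache.update(t=t, a=a)
        elif self.pooling == "mean":
            z = H2.mean(axis=0)
        else:
            amax = np.argmax(H2, axis=0)
            z = H2[amax, np.arange(H2.shape[1])]
            cache["amax"] = amax
        logit = float(z @ p["u"] + p["c"])
        cache["z"] = z
        return sigmoid(logit), a, cache

    def predict_bag(self, X: np.ndarray, scan_id: str = "") -> BagPrediction:
        """Bag probability in eval mode (dropout off); attention if applicable."""
        prob, a, _ = self._forward(X, training=False)
        return BagPrediction(scan_id, prob, a)

    def loss(self, X: np.ndarray, y: int) -> float:
        prob, _, _ = self._forward(X, training=False)
        return bce_loss(prob, y)

    def _backward(self, cache, dlogit: float) -> dict:
        p = self.params
        H, z = cache["H"], cache["z"]
        g = {"u": dlogit * z, "c": np.asarray(dlogit)}
        dz = dlogit * p["u"]
        if self.pooling == "attention":
            a, t = cache["a"], cache["t"]
            dH = a[:, None] * dz[None, :]
            da = H @ dz
            ds = a * (da - a @ da)
            g["w"] = t.T @ ds
            dpre = (ds[:, None] * p["w"][None, :]) * (1.0 - t**2)
            g["V"] = dpre.T @ H
            dH = dH + dpre @ p["V"]
        elif self.pooling == "mean":
            dH = np.repeat(dz[None, :], H.shape[0], axis=0) / H.shape[0]
        else:
            dH = np.zeros_like(H)
            dH[cache["amax"], np.arange(H.shape[1])] = dz
        if "m2" in cache:
            dH = dH * cache["m2"]
        dH2p = dH * (cache["H2p"] > 0)
        g["W2"] = cache["H1"].T @ dH2p
        g["b2"] = dH2p.sum(axis=0)
        dH1 = dH2p @ p["W2"].T
        if "m1" in cache:
            dH1 = dH1 * cache["m1"]
        dH1p = dH1 * (cache["H1p"] > 0)
        g["W1"] = cache["X"].T @ dH1p
        g["b1"] = dH1p.sum(axis=0)
        return g

    def train_step(self, X: np.ndarray, y: int, rng: np.random.Generator) -> float:
        """One bag-level SGD step (bags vary in size, so batch size is one bag)."""
        prob, _, cache = self._forward(X, training=True, rng=rng)
        loss = bce_loss(prob, y)
        grads = self._backward(cache, bce_grad(prob, y))
        self.opt.step(grads)
        return loss


class Noisy2DClassifier:
    """Slice-level classifier trained with the scan label broadcast to slices.

    Every slice inherits the scan's label during training — a deliberately
    noisy supervision scheme (a positive scan's clean slices become false
    positive training slices). At inference the per-slice probabilities are
    aggregated to a scan score by their mean (or max, configurable).
    """

    def __init__(
        self,
        d_raw: int,
        hidden: int = 512,
        embed: int = 512,
        dropout: float = 0.5,
        aggregate: str = "mean",
        init_std: float | None = None,
        lr: float = 1e-4,
        seed: int = 0,
        dtype=np.float32,
    ):
        if aggregate not in ("mean", "max"):
            raise ValidationError("aggregate must be 'mean' or 'max'")
        self.d_raw = d_raw
        self.dropout = dropout
        self.aggregate = aggregate
        rng = np.random.default_rng(seed)
        bias_std = init_std if init_std is not None else 0.01
        self.params = {
            "W1": init_normal(rng, (d_raw, hidden), init_std),
            "b1": init_normal(rng, hidden, bias_std),
            "W2": init_normal(rng, (hidden, embed), init_std),
            "b2": init_normal(rng, embed, bias_std),
            "u": init_normal(rng, embed, init_std, fan_in=embed),
            "c": init_normal(rng, (), bias_std),
        }
        self.dtype = dtype
        self.params = {k: np.asarray(v, dtype=dtype) for k, v in self.params.items()}
        self.opt = Adam(self.params, lr=lr)

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k][...] = state[k]

    def _forward(self, X, training=False, rng=None):
        X = _check_instances(X).astype(self.dtype, copy=False)
        p = self.params
        cache = {"X": X}
        H1p = X @ p["W1"] + p["b1"]
        H1 = np.maximum(H1p, 0.0)
        if training and self.dropout > 0:
            keep = self.dtype(1.0 - self.dropout)
            m1 = (rng.random(H1.shape) < keep).astype(self.dtype) / keep
            H1 = H1 * m1
            cache["m1"] = m1
        H2p = H1 @ p["W2"] + p["b2"]
        H2 = np.maximum(H2p, 0.0)
        if training and self.dropout > 0:
            keep = self.dtype(1.0 - self.dropout)
            m2 = (rng.random(H2.shape) < keep).astype(self.dtype) / keep
            H2 = H2 * m2
            cache["m2"] = m2
        logits = H2 @ p["u"] + p["c"]
        cache.update(H1p=H1p, H1=H1, H2p=H2p, H=H2, probs=sigmoid(logits))
        return cache

    def slice_probabilities(self, X) -> np.ndarray:
        return self._forward(X)["probs"]

    def predict_bag(self, X, scan_id: str = "") -> BagPrediction:
        probs = self.slice_probabilities(X)
        score = probs.mean() if self.aggregate == "mean" else probs.max()
        return BagPrediction(scan_id, score)

    def loss(self, X, y: int) -> float:
        probs = np.clip(self.slice_probabilities(X), 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(probs) + (1 - y) * np.log(1 - probs)))

    def train_step(self, X, y: int, rng: np.random.Generator) -> float:
        cache = self._forward(X, training=True, rng=rng)
        probs = np.clip(cache["probs"], 1e-12, 1 - 1e-12)
        n = probs.size
        loss = float(-np.mean(y * np.log(probs) + (1 - y) * np.log(1 - probs)))
        dlogits = (probs - y) / n
        p, g = self.params, {}
        g["u"] = cache["H"].T @ dlogits
        g["c"] = np.asarray(dlogits.sum())
        dH = dlogits[:, None] * p["u"][None, :]
        if "m2" in cache:
            dH = dH * cache["m2"]
        dH2p = dH * (cache["H2p"] > 0)
        g["W2"] = cache["H1"].T @ dH2p
        g["b2"] = dH2p.sum(axis=0)
        dH1 = dH2p @ p["W2"].T
        if "m1" in cache:
            dH1 = dH1 * cache["m1"]
        dH1p = dH1 * (cache["H1p"] > 0)
        g["W1"] = cache["X"].T @ dH1p
        g["b1"] = dH1p.sum(axis=0)
        self.opt.step(g)
        return loss
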