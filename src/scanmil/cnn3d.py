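"""Fully 3D baseline: axial interpolation to a fixed slice count + small 3D CNN.

The scan-level baseline that ignores the MIL structure entirely: every volume
is linearly interpolated along the axial axis to exactly 128 slices (and
optionally resampled in-plane), then classified by a compact 3D convolutional
network trained on the scan label. Convolutions and their gradients are
implemented with numpy sliding windows; tests check them against finite
differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bags import ScanBag
from .errors import ValidationError
from .models import BagPrediction
from .nn import Adam, bce_grad, bce_loss, init_normal, sigmoid

__all__ = ["interpolate_axial", "Volume3DCNN", "prepare_volume"]

FIXED_SLICES = 128


def interpolate_axial(slices: np.ndarray, n_out: int = FIXED_SLICES) -> np.ndarray:
    """Linearly interpolate a (N, H, W) stack to (n_out, H, W) along depth.

    Input slice j of N maps to position j/(N-1) in [0, 1]; output positions
    are i/(n_out-1). When N == n_out the operation is the identity.
    """
    x = np.asarray(slices, dtype=np.float64)
    if x.ndim != 3 or x.shape[0] < 1:
        raise ValidationError(f"expected (N, H, W) slices, got {x.shape}")
    n = x.shape[0]
    if n == n_out:
        return x.copy()
    if n == 1:
        return np.repeat(x, n_out, axis=0)
    pos = np.linspace(0.0, n - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = (pos - lo)[:, None, None]
    return (1.0 - w) * x[lo] + w * x[hi]


def prepare_volume(bag: ScanBag, in_plane: int = 40) -> np.ndarray:
    """Bag -> (1, 128, in_plane, in_plane) network input."""
    from skimage.transform import resize

    vol = interpolate_axial(bag.slices, FIXED_SLICES)
    if vol.shape[1:] != (in_plane, in_plane):
        vol = resize(vol, (FIXED_SLICES, in_plane, in_plane), order=1,
                     anti_aliasing=True)
    return vol[None, ...]


def _conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 3x3x3 convolution; x (Cin,D,H,W), w (Cout,Cin,3,3,3) -> (Cout,...)."""
    view = sliding_window_view(x, (3, 3, 3), axis=(1, 2, 3))
    return np.einsum("cdhwxyz,ocxyz->odhw", view, w, optimize=True) + b[:, None, None, None]


def _conv3d_backward(x, w, dy):
    view = sliding_window_view(x, (3, 3, 3), axis=(1, 2, 3))
    dw = np.einsum("cdhwxyz,odhw->ocxyz", view, dy, optimize=True)
    db = dy.sum(axis=(1, 2, 3))
    pad = np.pad(dy, ((0, 0), (2, 2), (2, 2), (2, 2)))
    pview = sliding_window_view(pad, (3, 3, 3), axis=(1, 2, 3))
    wflip = w[:, :, ::-1, ::-1, ::-1]
    dx = np.einsum("odhwxyz,ocxyz->cdhw", pview, wflip, optimize=True)
    return dx, dw, db


def _avgpool2(x: np.ndarray):
    """2x2x2 average pooling; odd trailing voxels are cropped.

    An axis already of size < 2 is left unpooled so deep blocks on small
    inputs never collapse to zero extent.
    """
    c, d, h, w = x.shape
    fd, fh, fw = (2 if d >= 2 else 1), (2 if h >= 2 else 1), (2 if w >= 2 else 1)
    d2, h2, w2 = d // fd * fd, h // fh * fh, w // fw * fw
    xt = x[:, :d2, :h2, :w2].reshape(c, d2 // fd, fd, h2 // fh, fh, w2 // fw, fw)
    return xt.mean(axis=(2, 4, 6)), (x.shape, (fd, fh, fw))


def _avgpool2_backward(dy: np.ndarray, pool_info):
    in_shape, (fd, fh, fw) = pool_info
    dx = np.zeros(in_shape)
    up = np.repeat(np.repeat(np.repeat(dy, fd, 1), fh, 2), fw, 3) / (fd * fh * fw)
    dx[:, : up.shape[1], : up.shape[2], : up.shape[3]] = up
    return dx


class Volume3DCNN:
    """Four-block 3D CNN scan classifier.

    Each block is a valid 3x3x3 convolution, ReLU and 2x2x2 average pooling;
    channel widths default to (4, 8, 16, 16). The final representation is the
    global average per channel, classified by an affine map with sigmoid.
    """

    def __init__(
        self,
        in_plane: int = 40,
        channels: tuple = (4, 8, 16, 16),
        init_std: float | None = None,
        lr: float = 1e-4,
        seed: int = 0,
    ):
        self.in_plane = in_plane
        self.channels = channels
        rng = np.random.default_rng(seed)
        bias_std = init_std if init_std is not None else 0.01
        p = {}
        cin = 1
        for i, cout in enumerate(channels):
            p[f"w{i}"] = init_normal(rng, (cout, cin, 3, 3, 3), init_std,
                                     fan_in=cin * 27)
            p[f"b{i}"] = init_normal(rng, cout, bias_std)
            cin = cout
        p["u"] = init_normal(rng, channels[-1], init_std, fan_in=channels[-1])
        p["c"] = init_normal(rng, (), bias_std)
        self.params = p
        self.opt = Adam(self.params, lr=lr)

    def state_dict(self):
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state):
        for k in self.params:
            self.params[k][...] = state[k]

    def _forward(self, vol: np.ndarray):
        if vol.ndim != 4 or vol.shape[1] != FIXED_SLICES:
            raise ValidationError(
                f"expected (1, {FIXED_SLICES}, H, W) input, got {vol.shape}"
            )
        cache = {"inputs": [vol]}
        x = vol
        cache["relu"] = []
        cache["pool_shapes"] = []
        for i in range(len(self.channels)):
            if min(x.shape[1:]) < 3:
                raise ValidationError(
                    f"block {i}: spatial extent {x.shape[1:]} too small for a "
                    "3x3x3 convolution; use a larger in_plane size or fewer blocks"
                )
            pre = _conv3d(x, self.params[f"w{i}"], self.params[f"b{i}"])
            mask = pre > 0
            x = pre * mask
            cache["relu"].append(mask)
            x, shp = _avgpool2(x)
            cache["pool_shapes"].append(shp)
            cache["inputs"].append(x)
        feat = x.mean(axis=(1, 2, 3))
        cache["feat"] = feat
        cache["spatial"] = x.shape[1:]
        logit = float(feat @ self.params["u"] + self.params["c"])
        return sigmoid(logit), cache

    def predict_bag(self, vol: np.ndarray, scan_id: str = "") -> BagPrediction:
        prob, _ = self._forward(vol)
        return BagPrediction(scan_id, prob)

    def loss(self, vol: np.ndarray, y: int) -> float:
        prob, _ = self._forward(vol)
        return bce_loss(prob, y)

    def train_step(self, vol: np.ndarray, y: int, rng=None) -> float:
        prob, cache = self._forward(vol)
        loss = bce_loss(prob, y)
        dlogit = bce_grad(prob, y)
        g = {"u": dlogit * cache["feat"], "c": np.asarray(dlogit)}
        d, h, w = cache["spatial"]
        dx = (dlogit * self.params["u"])[:, None, None, None] * np.ones(
            (len(self.params["u"]), d, h, w)
        ) / (d * h * w)
        for i in reversed(range(len(self.channels))):
            dx = _avgpool2_backward(dx, cache["pool_shapes"][i])
            dx = dx * cache["relu"][i]
            dx, dw, db = _conv3d_backward(cache["inputs"][i], self.params[f"w{i}"], dx)
            g[f"w{i}"], g[f"b{i}"] = dw, db
        self.opt.step(g)
        return loss
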