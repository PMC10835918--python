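"""Minimal NumPy CNN: a small 2-level U-Net with manual backprop.

Implemented from scratch (im2col convolutions, explicit gradients) so the
pipeline trains on CPU without a deep-learning framework, stays deterministic
under a fixed seed, and makes the freeze/unfreeze transfer-learning contracts
bit-exact: a parameter tensor changes iff its name is in the trainable set.

Parameters live in a flat ``{name: float32 array}`` dict.  The final 1x1
pixel-wise classification layer is named ``head`` (``c2.head`` when the
cascaded second stage is enabled).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# ---------------------------------------------------------------- primitives

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) column matrix (stride 1, same size)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)


def conv_forward(x, W, b):
    """Same-size convolution; kernel (Cout, Cin, k, k), pad = k // 2."""
    n, _, h, w = x.shape
    cout, cin, k, _ = W.shape
    cols = _im2col(x, k, k // 2)
    out = cols @ W.reshape(cout, -1).T + b
    return out.transpose(0, 2, 1).reshape(n, cout, h, w), cols


def conv_backward(dout, cols, x_shape, W):
    cout, cin, k, _ = W.shape
    n, _, h, w = x_shape
    dmat = dout.reshape(n, cout, h * w).transpose(0, 2, 1)  # (N, HW, Cout)
    dW = np.einsum("npo,npk->ok", dmat, cols).reshape(W.shape)
    db = dout.sum(axis=(0, 2, 3))
    Wt = np.ascontiguousarray(W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx, _ = conv_forward(dout, Wt, np.zeros(cin, dtype=F32))
    return dx.astype(F32), dW.astype(F32), db.astype(F32)


def relu_forward(x):
    return np.maximum(x, 0), x > 0


def maxpool2_forward(x):
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    return r.max(axis=-1), (idx, x.shape)


def maxpool2_backward(dout, cache):
    idx, (n, c, h, w) = cache
    dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    return dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
        0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def upsample2_forward(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pixel-wise CE; returns (loss, dlogits)."""
    n, c, h, w = logits.shape
    probs = softmax(logits.astype(np.float64))
    flat = probs.transpose(0, 2, 3, 1).reshape(-1, c)
    lab = labels.reshape(-1)
    npix = lab.size
    loss = -np.log(np.clip(flat[np.arange(npix), lab], 1e-12, None)).mean()
    dflat = flat
    dflat[np.arange(npix), lab] -= 1.0
    dlogits = (dflat / npix).reshape(n, h, w, c).transpose(0, 3, 1, 2)
    return float(loss), dlogits.astype(F32)


# ------------------------------------------------------------------- U-Net

_CONVS = ("enc1a", "enc1b", "enc2a", "enc2b", "bota", "botb",
          "dec2a", "dec2b", "dec1a", "dec1b", "head")


def init_unet_params(
    in_ch: int, base: int, n_classes: int, rng: np.random.Generator,
    prefix: str = "",
) -> dict[str, np.ndarray]:
    """He-normal initialization of the small U-Net parameter dict."""
    shapes = {
        "enc1a": (base, in_ch, 3, 3),
        "enc1b": (base, base, 3, 3),
        "enc2a": (2 * base, base, 3, 3),
        "enc2b": (2 * base, 2 * base, 3, 3),
        "bota": (4 * base, 2 * base, 3, 3),
        "botb": (4 * base, 4 * base, 3, 3),
        "dec2a": (2 * base, 4 * base + 2 * base, 3, 3),
        "dec2b": (2 * base, 2 * base, 3, 3),
        "dec1a": (base, 2 * base + base, 3, 3),
        "dec1b": (base, base, 3, 3),
        "head": (n_classes, base, 1, 1),
    }
    params: dict[str, np.ndarray] = {}
    for name, shape in shapes.items():
        fan_in = shape[1] * shape[2] * shape[3]
        params[f"{prefix}{name}.W"] = (
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)
        )
        params[f"{prefix}{name}.b"] = np.zeros(shape[0], dtype=F32)
    return params


def unet_forward(params: dict, x: np.ndarray, prefix: str = ""):
    """Forward pass; returns (logits, cache)."""
    cache: dict = {"x_shape": {}}

    def conv_relu(name, inp):
        out, cols = conv_forward(inp, params[f"{prefix}{name}.W"], params[f"{prefix}{name}.b"])
        act, mask = relu_forward(out)
        cache[name] = (cols, inp.shape, mask)
        return act

    e1 = conv_relu("enc1a", x)
    e1 = conv_relu("enc1b", e1)
    p1, cache["pool1"] = maxpool2_forward(e1)
    e2 = conv_relu("enc2a", p1)
    e2 = conv_relu("enc2b", e2)
    p2, cache["pool2"] = maxpool2_forward(e2)
    bt = conv_relu("bota", p2)
    bt = conv_relu("botb", bt)
    u2 = upsample2_forward(bt)
    c2 = np.concatenate([u2, e2], axis=1)
    cache["split2"] = u2.shape[1]
    d2 = conv_relu("dec2a", c2)
    d2 = conv_relu("dec2b", d2)
    u1 = upsample2_forward(d2)
    c1 = np.concatenate([u1, e1], axis=1)
    cache["split1"] = u1.shape[1]
    d1 = conv_relu("dec1a", c1)
    d1 = conv_relu("dec1b", d1)
    logits, cols = conv_forward(d1, params[f"{prefix}head.W"], params[f"{prefix}head.b"])
    cache["head"] = (cols, d1.shape, None)
    return logits, cache


def unet_backward(params: dict, cache: dict, dlogits: np.ndarray, prefix: str = "") -> dict:
    """Gradients w.r.t. every parameter of one U-Net."""
    grads: dict[str, np.ndarray] = {}

    def conv_relu_back(name, dout, through_relu=True):
        cols, x_shape, mask = cache[name]
        if through_relu and mask is not None:
            dout = dout * mask
        dx, dW, db = conv_backward(dout, cols, x_shape, params[f"{prefix}{name}.W"])
        grads[f"{prefix}{name}.W"] = dW
        grads[f"{prefix}{name}.b"] = db
        return dx

    cols, d1_shape, _ = cache["head"]
    dd1, dWh, dbh = conv_backward(dlogits, cols, d1_shape, params[f"{prefix}head.W"])
    grads[f"{prefix}head.W"] = dWh
    grads[f"{prefix}head.b"] = dbh

    dd1 = dd1 * cache["dec1b"][2]
    dd1 = conv_relu_back("dec1b", dd1, through_relu=False)
    dc1 = conv_relu_back("dec1a", dd1)
    s1 = cache["split1"]
    du1, de1_skip = dc1[:, :s1], dc1[:, s1:]
    dd2 = upsample2_backward(du1)
    dd2 = conv_relu_back("dec2b", dd2)
    dc2 = conv_relu_back("dec2a", dd2)
    s2 = cache["split2"]
    du2, de2_skip = dc2[:, :s2], dc2[:, s2:]
    dbt = upsample2_backward(du2)
    dbt = conv_relu_back("botb", dbt)
    dp2 = conv_relu_back("bota", dbt)
    de2 = maxpool2_backward(dp2, cache["pool2"]) + de2_skip
    de2 = conv_relu_back("enc2b", de2)
    dp1 = conv_relu_back("enc2a", de2)
    de1 = maxpool2_backward(dp1, cache["pool1"]) + de1_skip
    de1 = conv_relu_back("enc1b", de1)
    conv_relu_back("enc1a", de1)
    return grads


class Adam:
    """Adam optimizer over a parameter dict; updates only trainable names."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict, grads: dict, trainable: set[str]) -> None:
        self.t += 1
        for name in sorted(trainable):
            g = grads[name].astype(np.float64)
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1 ** self.t)
            vhat = self.v[name] / (1 - self.beta2 ** self.t)
            params[name] = (
                params[name].astype(np.float64)
                - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(F32)
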