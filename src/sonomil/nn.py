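"""Minimal CPU neural-network primitives with explicit reverse-mode gradients.

Functional layers (convolution via im2col, ReLU, sigmoid, spatial max
pooling) return ``(output, cache)`` pairs; the matching ``*_backward``
consumes the upstream gradient and the cache. Parameters live in plain
dictionaries of float arrays, which keeps the optimizer and checkpointing
trivial and makes every gradient directly checkable against finite
differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv2d_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1, pad: int = 0
):
    """2-D cross-correlation. x: (H, W, Cin); w: (Cout, kh, kw, Cin); b: (Cout,)."""
    kh, kw = w.shape[1], w.shape[2]
    if x.shape[2] != w.shape[3]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[2]}, kernel expects {w.shape[3]}"
        )
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0))) if pad else x
    win = sliding_window_view(xp, (kh, kw), axis=(0, 1))[::stride, ::stride]
    # win: (Ho, Wo, Cin, kh, kw) -> cols (Ho*Wo, kh*kw*Cin)
    ho, wo = win.shape[0], win.shape[1]
    cols = win.transpose(0, 1, 3, 4, 2).reshape(ho * wo, kh * kw * x.shape[2])
    wmat = w.transpose(0, 1, 2, 3).reshape(w.shape[0], kh * kw * x.shape[2])
    out = cols @ wmat.T + b
    cache = (cols, x.shape, xp.shape, w.shape, stride, pad, ho, wo)
    return out.reshape(ho, wo, w.shape[0]), cache


def conv2d_backward(dout: np.ndarray, cache, w: np.ndarray):
    """Returns (dx, dw, db)."""
    cols, x_shape, xp_shape, w_shape, stride, pad, ho, wo = cache
    cout, kh, kw, cin = w_shape
    d2 = dout.reshape(ho * wo, cout)
    wmat = w.reshape(cout, kh * kw * cin)
    db = d2.sum(axis=0)
    dw = (d2.T @ cols).reshape(w_shape)
    dcols = (d2 @ wmat).reshape(ho, wo, kh, kw, cin)
    dxp = np.zeros(xp_shape, dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[i : i + ho * stride : stride, j : j + wo * stride : stride] += dcols[
                :, :, i, j, :
            ]
    if pad:
        dx = dxp[pad:-pad, pad:-pad, :]
    else:
        dx = dxp
    return dx, dw, db


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def global_max_pool_forward(h: np.ndarray):
    """h: (h, w, C) -> (C,) channelwise spatial max; cache holds argmax."""
    hh, ww, c = h.shape
    flat = h.reshape(hh * ww, c)
    idx = flat.argmax(axis=0)
    return flat[idx, np.arange(c)], (idx, h.shape)


def global_max_pool_backward(dv: np.ndarray, cache) -> np.ndarray:
    idx, shape = cache
    hh, ww, c = shape
    dflat = np.zeros((hh * ww, c), dtype=dv.dtype)
    dflat[idx, np.arange(c)] = dv
    return dflat.reshape(shape)


def softmax_columns(e: np.ndarray) -> np.ndarray:
    """Column-wise softmax with max subtraction. e: (K, n_cols)."""
    z = e - e.max(axis=0, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=0, keepdims=True)


def softmax_columns_backward(dalpha: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of the column softmax."""
    inner = (dalpha * alpha).sum(axis=0, keepdims=True)
    return alpha * (dalpha - inner)


def instance_norm_forward(x: np.ndarray, gain: np.ndarray, bias: np.ndarray, eps: float = 1e-5):
    """Per-channel spatial standardization with learnable gain/bias.

    x: (H, W, C); statistics are taken over the spatial positions of each
    channel, so the layer is deterministic per image (no running state).
    """
    n = x.shape[0] * x.shape[1]
    mu = x.mean(axis=(0, 1), keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=(0, 1), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gain * xhat + bias
    return out, (xhat, inv, gain, n)


def instance_norm_backward(dout: np.ndarray, cache):
    xhat, inv, gain, n = cache
    dgain = (dout * xhat).sum(axis=(0, 1))
    dbias = dout.sum(axis=(0, 1))
    dxhat = dout * gain
    m1 = dxhat.mean(axis=(0, 1), keepdims=True)
    m2 = (dxhat * xhat).mean(axis=(0, 1), keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dgain, dbias


def he_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class AdamW:
    """Adam with decoupled weight decay over a parameter dict."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p
            p -= self.lr * update
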