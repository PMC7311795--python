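"""Minimal numpy neural-network primitives (dense + dilated conv + Adam).

The learned components of this package are deliberately tiny, so they are
implemented directly on numpy with explicit backprop: dense layers for the
crop classifiers and im2col-based 2-D convolutions (with dilation) for the
coarse inpainting network. Everything is deterministic given the seed in
single-threaded BLAS conditions.
"""

from __future__ import annotations

import hashlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(x))."""
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean NLL of ``labels`` under softmax(logits) and its gradient."""
    n = logits.shape[0]
    logp = log_softmax(logits)
    loss = -float(logp[np.arange(n), labels].mean())
    grad = softmax(logits)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a named parameter dict (in-place updates)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / b1t
            vh = self.v[k] / b2t
            self.params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def im2col(x: np.ndarray, k: int, dilation: int = 1) -> np.ndarray:
    """Unfold (N, C, H, W) into (N, H*W, C*k*k) columns with same-padding."""
    n, c, h, w = x.shape
    eff = dilation * (k - 1) + 1
    pad = eff // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (eff, eff), axis=(2, 3))  # N,C,H,W,eff,eff
    win = win[..., ::dilation, ::dilation]                   # N,C,H,W,k,k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
    return np.ascontiguousarray(cols)


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                   dilation: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Same-size 2-D convolution; returns (output, cols cache).

    x: (N, Cin, H, W); weight: (Cout, Cin, k, k); bias: (Cout,).
    """
    n, _, h, w = x.shape
    cout, cin, k, _ = weight.shape
    cols = im2col(x, k, dilation)
    wmat = weight.reshape(cout, cin * k * k)
    out = cols @ wmat.T + bias
    return out.transpose(0, 2, 1).reshape(n, cout, h, w), cols


def conv2d_backward(dout: np.ndarray, cols: np.ndarray, weight: np.ndarray,
                    x_shape: tuple[int, ...], dilation: int = 1
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dweight, dbias) of :func:`conv2d_forward`."""
    n, cin, h, w = x_shape
    cout, _, k, _ = weight.shape
    dflat = dout.reshape(n, cout, h * w).transpose(0, 2, 1)  # N, HW, Cout
    wmat = weight.reshape(cout, cin * k * k)
    dw = np.einsum("npo,npk->ok", dflat, cols).reshape(weight.shape)
    db = dflat.sum(axis=(0, 1))
    dcols = dflat @ wmat  # N, HW, Cin*k*k
    dcols = dcols.reshape(n, h, w, cin, k, k)
    eff = dilation * (k - 1) + 1
    pad = eff // 2
    dxp = np.zeros((n, cin, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i * dilation:i * dilation + h, j * dilation:j * dilation + w] += \
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, pad:pad + h, pad:pad + w], dw, db


def weights_checksum(params: dict[str, np.ndarray]) -> str:
    """Stable hex digest of a parameter dict (for determinism checks)."""
    h = hashlib.sha256()
    for k in sorted(params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params[k], dtype=np.float64).tobytes())
    return h.hexdigest()
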