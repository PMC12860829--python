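"""Minimal CPU neural-network primitives (numpy, explicit backprop).

Shared by the local dilated-convolution channel and the global Transformer
channel: stride-1 "same" 3-D convolution via im2col (chunked for large
volumes), dense layers, layer normalization, softmax cross-entropy and an
Adam optimizer.  Everything is float32 and deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Adam", "conv3d_same", "conv3d_backward", "im2col",
           "relu", "relu_grad", "softmax", "softmax_ce", "he_normal"]


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1.0 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(Cin, D, H, W) -> (D*H*W, Cin*k^3) with 'same' zero padding."""
    cin = x.shape[0]
    p = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    K = dilation * (k - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (K, K, K), axis=(1, 2, 3))
    win = win[..., ::dilation, ::dilation, ::dilation]
    return win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, cin * k ** 3)


def conv3d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int, dilation: int,
                max_chunk_elems: int = 40_000_000) -> np.ndarray:
    """Stride-1 dilated convolution preserving spatial shape.

    ``w`` has shape (Cout, Cin*k^3).  Large inputs are processed in slabs
    along the first spatial axis to bound the im2col buffer.
    """
    cin, d, h, wd = x.shape
    cout = w.shape[0]
    taps = cin * k ** 3
    p = dilation * (k - 1) // 2
    K = dilation * (k - 1) + 1
    per_slab = h * wd * taps
    dchunk = max(1, int(max_chunk_elems // max(per_slab, 1)))
    if dchunk >= d:
        cols = im2col(x, k, dilation)
        out = cols @ w.T.astype(x.dtype) + b.astype(x.dtype)
        return out.reshape(d, h, wd, cout).transpose(3, 0, 1, 2)
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    out = np.empty((cout, d, h, wd), dtype=x.dtype)
    for d0 in range(0, d, dchunk):
        d1 = min(d, d0 + dchunk)
        sub = xp[:, d0:d1 - 1 + K, :, :]
        win = np.lib.stride_tricks.sliding_window_view(sub, (K, K, K), axis=(1, 2, 3))
        win = win[..., ::dilation, ::dilation, ::dilation]
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, taps)
        blk = cols @ w.T.astype(x.dtype) + b.astype(x.dtype)
        out[:, d0:d1] = blk.reshape(d1 - d0, h, wd, cout).transpose(3, 0, 1, 2)
    return out


def _flip_weights(w: np.ndarray, cin: int, k: int) -> np.ndarray:
    """(Cout, Cin*k^3) -> (Cin, Cout*k^3) with spatially reversed taps."""
    cout = w.shape[0]
    w3 = w.reshape(cout, cin, k ** 3)[:, :, ::-1]
    return np.ascontiguousarray(w3.transpose(1, 0, 2)).reshape(cin, cout * k ** 3)


def conv3d_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray, k: int,
                    dilation: int, cols: np.ndarray | None = None):
    """Gradients of a stride-1 same convolution.

    Returns ``(dx, dw, db)``.  ``cols`` may pass the cached im2col matrix of
    the forward pass; otherwise it is recomputed.
    """
    cin = x.shape[0]
    cout = dout.shape[0]
    if cols is None:
        cols = im2col(x, k, dilation)
    dmat = dout.transpose(1, 2, 3, 0).reshape(-1, cout)
    dw = dmat.T @ cols
    db = dmat.sum(axis=0)
    wf = _flip_weights(w, cin, k)
    dx = conv3d_same(dout, wf, np.zeros(cin, dtype=w.dtype), k, dilation)
    return dx, dw.astype(np.float32), db.astype(np.float32)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(dout: np.ndarray, out: np.ndarray) -> np.ndarray:
    return dout * (out > 0)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_ce(logits: np.ndarray, label: int):
    """Cross-entropy loss and gradient for a single sample."""
    p = softmax(logits.astype(np.float64))
    loss = -np.log(max(p[label], 1e-12))
    dlogits = p.copy()
    dlogits[label] -= 1.0
    return float(loss), dlogits.astype(np.float32)
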