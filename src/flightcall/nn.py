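"""Minimal neural-network primitives with explicit gradients.

Only what the detector architecture needs: valid 2-D convolution,
non-overlapping strided max pooling, dense layers, ReLU, sigmoid, softmax,
binary cross-entropy, Glorot initialization, and an Adam optimizer. Forward
functions return caches consumed by the matching backward functions; there
is no autodiff graph.

Feature maps are laid out NHWC (batch, time, frequency, channels).
Convolution and pooling inner loops are numba-compiled; dense layers go
through BLAS.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out,
                   dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# Convolution kernels (valid, stride 1). W layout: (kh, kw, C, O).

@njit(cache=True, fastmath=True)
def _conv_fwd(x, W, b):
    B, H, Wd, C = x.shape
    kh, kw, _, O = W.shape
    Ho, Wo = H - kh + 1, Wd - kw + 1
    out = np.empty((B, Ho, Wo, O), dtype=x.dtype)
    acc = np.empty(O, dtype=x.dtype)
    for bb in range(B):
        for i in range(Ho):
            for j in range(Wo):
                for o in range(O):
                    acc[o] = b[o]
                for di in range(kh):
                    for dj in range(kw):
                        for c in range(C):
                            v = x[bb, i + di, j + dj, c]
                            for o in range(O):
                                acc[o] += v * W[di, dj, c, o]
                for o in range(O):
                    out[bb, i, j, o] = acc[o]
    return out


@njit(cache=True, fastmath=True)
def _conv_fwd_c1(x, W, b):
    # single-input-channel specialization: vectorize along the width axis
    B, H, Wd, _ = x.shape
    kh, kw, _, O = W.shape
    Ho, Wo = H - kh + 1, Wd - kw + 1
    out = np.empty((B, Ho, Wo, O), dtype=x.dtype)
    tmp = np.empty(Wo, dtype=x.dtype)
    for bb in range(B):
        for i in range(Ho):
            for o in range(O):
                for j in range(Wo):
                    tmp[j] = b[o]
                for di in range(kh):
                    for dj in range(kw):
                        w = W[di, dj, 0, o]
                        for j in range(Wo):
                            tmp[j] += w * x[bb, i + di, j + dj, 0]
                for j in range(Wo):
                    out[bb, i, j, o] = tmp[j]
    return out


@njit(cache=True, fastmath=True)
def _conv_bwd_dw(x, dout, kh, kw):
    B, H, Wd, C = x.shape
    _, Ho, Wo, O = dout.shape
    dW = np.zeros((kh, kw, C, O), dtype=x.dtype)
    db = np.zeros(O, dtype=x.dtype)
    for bb in range(B):
        for i in range(Ho):
            for j in range(Wo):
                for o in range(O):
                    db[o] += dout[bb, i, j, o]
                for di in range(kh):
                    for dj in range(kw):
                        for c in range(C):
                            v = x[bb, i + di, j + dj, c]
                            for o in range(O):
                                dW[di, dj, c, o] += v * dout[bb, i, j, o]
    return dW, db


@njit(cache=True, fastmath=True)
def _conv_bwd_dx(dout, W, H, Wd):
    B, Ho, Wo, O = dout.shape
    kh, kw, C, _ = W.shape
    dx = np.zeros((B, H, Wd, C), dtype=dout.dtype)
    for bb in range(B):
        for i in range(Ho):
            for j in range(Wo):
                for di in range(kh):
                    for dj in range(kw):
                        for c in range(C):
                            acc = dout.dtype.type(0.0)
                            for o in range(O):
                                acc += dout[bb, i, j, o] * W[di, dj, c, o]
                            dx[bb, i + di, j + dj, c] += acc
    return dx


def conv2d_forward(x, W, b):
    """Valid convolution. x: (B,H,W,C) NHWC, W: (kh,kw,C,O), b: (O,)."""
    if x.shape[3] == 1:
        out = _conv_fwd_c1(x, W, b)
    else:
        out = _conv_fwd(x, W, b)
    return out, x


def conv2d_backward(dout, W, x, need_dx: bool = True):
    dout = np.ascontiguousarray(dout)
    dW, db = _conv_bwd_dw(x, dout, W.shape[0], W.shape[1])
    dx = _conv_bwd_dx(dout, W, x.shape[1], x.shape[2]) if need_dx else None
    return dx, dW, db


# ---------------------------------------------------------------------------
# Max pooling (non-overlapping, trailing remainder truncated)

@njit(cache=True, fastmath=True)
def _pool_fwd(x, ph, pw):
    B, H, Wd, C = x.shape
    Ho, Wo = H // ph, Wd // pw
    out = np.empty((B, Ho, Wo, C), dtype=x.dtype)
    idx = np.empty((B, Ho, Wo, C), dtype=np.int32)
    for bb in range(B):
        for i in range(Ho):
            for j in range(Wo):
                for c in range(C):
                    best = x[bb, i * ph, j * pw, c]
                    bestk = 0
                    for di in range(ph):
                        for dj in range(pw):
                            v = x[bb, i * ph + di, j * pw + dj, c]
                            if v > best:
                                best = v
                                bestk = di * pw + dj
                    out[bb, i, j, c] = best
                    idx[bb, i, j, c] = bestk
    return out, idx


@njit(cache=True, fastmath=True)
def _pool_bwd(dout, idx, H, Wd, ph, pw):
    B, Ho, Wo, C = dout.shape
    dx = np.zeros((B, H, Wd, C), dtype=dout.dtype)
    for bb in range(B):
        for i in range(Ho):
            for j in range(Wo):
                for c in range(C):
                    k = idx[bb, i, j, c]
                    dx[bb, i * ph + k // pw, j * pw + k % pw, c] = dout[bb, i, j, c]
    return dx


def maxpool_forward(x, ph, pw):
    out, idx = _pool_fwd(x, ph, pw)
    return out, (x.shape, ph, pw, idx)


def maxpool_backward(dout, cache):
    x_shape, ph, pw, idx = cache
    return _pool_bwd(np.ascontiguousarray(dout), idx, x_shape[1], x_shape[2],
                     ph, pw)


def relu_pool_forward(x, ph, pw):
    """Fused ReLU followed by non-overlapping max pooling.

    ReLU and windowed max commute, so the pooled output is
    max(window max, 0); the backward pass routes gradient to the argmax
    position only when the pooled activation is strictly positive, which
    avoids materializing a full-size ReLU mask.
    """
    m, idx = _pool_fwd(x, ph, pw)
    out = np.maximum(m, 0)
    return out, (x.shape, ph, pw, idx, m > 0)


def relu_pool_backward(dout, cache):
    x_shape, ph, pw, idx, pos = cache
    dout = np.ascontiguousarray(dout * pos)
    return _pool_bwd(dout, idx, x_shape[1], x_shape[2], ph, pw)


# ---------------------------------------------------------------------------
# Dense / activations / loss

def dense_forward(x, W, b):
    return x @ W + b, x


def dense_backward(dout, W, x):
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


def relu_forward(x):
    out = np.maximum(x, 0)
    return out, (x > 0)


def relu_backward(dout, mask):
    return dout * mask


def sigmoid(a):
    return 0.5 * (1.0 + np.tanh(0.5 * a))


def softmax(a, axis=-1):
    e = np.exp(a - a.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def bce_loss(y, t, eps=1e-12):
    """Mean binary cross-entropy and its gradient w.r.t. the pre-sigmoid
    activation (which is simply (y - t) / B)."""
    y = np.clip(y.astype(np.float64), eps, 1 - eps)
    loss = -np.mean(t * np.log(y) + (1 - t) * np.log(1 - y))
    da = (y - t) / y.shape[0]
    return float(loss), da


# ---------------------------------------------------------------------------
# Optimizer

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(params[k].dtype)
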