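"""Minimal NumPy neural-network primitives with explicit backprop.

Implements exactly what the double-stream architecture needs: valid
(no-padding) 3-D convolution over single-channel volumes, 3-D max pooling
with stride equal to the pool size, dense layers, ReLU, inverted dropout,
softmax / sigmoid heads and the gradient-reversal contract.

All operations are batched.  Volumes are (B, H, W, T) arrays; convolution
and pooling activations are kept channels-last, (B, H', W', T', C), which
lets every intermediate be produced by a single GEMM or strided reduction
without layout copies (the published channels-first shape arithmetic is
exposed through :func:`conv_output_shape`).  Each forward function returns
``(output, cache)``; the matching backward consumes the cache and the
upstream gradient.  Convolutions sit at the network input, so their
backward pass skips the input gradient unless ``need_dx`` is set.

Max-pool gradients are split equally among tied maxima; ties between
positive activations have measure zero for continuous inputs, and ties at
zero are annihilated by the preceding ReLU's gradient mask.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np


def conv_output_shape(in_shape, kernel, stride) -> Tuple[int, ...]:
    """Valid-convolution/pooling arithmetic: floor((in - k) / s) + 1 per axis."""
    out = []
    for n, k, s in zip(in_shape, kernel, stride):
        if k > n:
            raise ValueError(f"kernel {kernel} larger than input {in_shape}")
        out.append((n - k) // s + 1)
    return tuple(out)


def _im2col(x: np.ndarray, kernel, stride, out_shape) -> np.ndarray:
    """x: (B, H, W, T) -> patch matrix (K, B * prod(out_shape)).

    Row j holds the j-th kernel offset (in (kh, kw, kt) C-order, matching
    ``weight.reshape(C, -1)``); each row is written contiguously.
    """
    b = x.shape[0]
    kh, kw, kt = kernel
    sh, sw, st = stride
    ho, wo, to = out_shape
    patches = np.empty((kh * kw * kt, b * ho * wo * to), dtype=x.dtype)
    j = 0
    for a in range(kh):
        for c in range(kw):
            for d in range(kt):
                np.copyto(patches[j].reshape(b, ho, wo, to),
                          x[:, a:a + ho * sh:sh, c:c + wo * sw:sw,
                            d:d + to * st:st])
                j += 1
    return patches


def conv3d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                   stride) -> Tuple[np.ndarray, tuple]:
    """x: (B, H, W, T); weight: (C, kh, kw, kt) -> (B, Ho, Wo, To, C)."""
    b = x.shape[0]
    c = weight.shape[0]
    kernel = weight.shape[1:]
    out_shape = conv_output_shape(x.shape[1:], kernel, stride)
    patches = _im2col(x, kernel, stride, out_shape)
    out = patches.T @ weight.reshape(c, -1).T + bias
    out = out.reshape(b, *out_shape, c)
    cache = (x.shape, patches, weight, stride, out_shape)
    return out, cache


def conv3d_backward(dout: np.ndarray, cache, need_dx: bool = False):
    """Returns (dx_or_None, dweight, dbias); dout: (B, Ho, Wo, To, C)."""
    x_shape, patches, weight, stride, out_shape = cache
    b = x_shape[0]
    c = weight.shape[0]
    dflat = dout.reshape(-1, c)
    dweight = (patches @ dflat).T.reshape(weight.shape)
    dbias = dflat.sum(axis=0)
    if not need_dx:
        return None, dweight, dbias
    sh, sw, st = stride
    ho, wo, to = out_shape
    dpatches = weight.reshape(c, -1).T @ dflat.T          # (K, B*n)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    j = 0
    for a in range(weight.shape[1]):
        for cc in range(weight.shape[2]):
            for d in range(weight.shape[3]):
                dx[:, a:a + ho * sh:sh, cc:cc + wo * sw:sw,
                   d:d + to * st:st] += dpatches[j].reshape(b, ho, wo, to)
                j += 1
    return dx, dweight, dbias


def maxpool3d_forward(x: np.ndarray, pool) -> Tuple[np.ndarray, tuple]:
    """x: (B, H, W, T, C); non-overlapping valid pooling, stride = pool."""
    b, h, w, t, c = x.shape
    ph, pw, pt = pool
    ho, wo, to = h // ph, w // pw, t // pt
    win = x[:, :ho * ph, :wo * pw, :to * pt].reshape(
        b, ho, ph, wo, pw, to, pt, c)
    out = win.max(axis=(2, 4, 6))
    cache = (x, pool, (ho, wo, to), out)
    return out, cache


def maxpool3d_backward(dout: np.ndarray, cache) -> np.ndarray:
    x, pool, (ho, wo, to), out = cache
    ph, pw, pt = pool

    def offset_view(arr, a, b, c):
        return arr[:, a:ho * ph:ph, b:wo * pw:pw, c:to * pt:pt]

    counts = np.zeros_like(out)
    for a in range(ph):
        for b in range(pw):
            for c in range(pt):
                counts += offset_view(x, a, b, c) == out
    scale = dout / counts
    dx = np.zeros_like(x)
    for a in range(ph):
        for b in range(pw):
            for c in range(pt):
                view = offset_view(x, a, b, c)
                offset_view(dx, a, b, c)[...] = (view == out) * scale
    return dx


def dense_forward(x: np.ndarray, weight: np.ndarray,
                  bias: np.ndarray) -> Tuple[np.ndarray, tuple]:
    """x: (B, in); weight: (out, in) -> (B, out)."""
    return x @ weight.T + bias, (x, weight)


def dense_backward(dout: np.ndarray, cache):
    x, weight = cache
    return dout @ weight, dout.T @ x, dout.sum(axis=0)


def relu_forward(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def dropout_forward(x: np.ndarray, rate: float, train: bool,
                    rng: np.random.Generator | None):
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate <= 0:
        return x, None
    mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * mask, mask


def dropout_backward(dout: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return dout
    return dout * mask


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clamp so exp never overflows float32
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def grl_backward(grad: np.ndarray, grl_lambda: float) -> np.ndarray:
    """Gradient-reversal contract: identity forward, -lambda * grad backward."""
    return -grl_lambda * grad


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
                   dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)
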