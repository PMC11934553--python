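"""Minimal NumPy neural-network layers with explicit backpropagation.

Everything the boundary classifier needs — 2-D convolution, max pooling,
CBAM-style channel and spatial attention gates, layer normalisation,
multi-head self-attention, dense layers, dropout and Adam — implemented on
plain ndarrays.  Each layer caches what its backward pass needs during
``forward`` and accumulates parameter gradients in ``.grads`` (aligned with
``.params``).  All layers are float64 and single-threaded-deterministic;
every stochastic element (init, dropout) draws from an explicit
``numpy.random.Generator``.

The backward passes are verified against central finite differences in the
test suite; keep any change here covered by that check.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameters and aligned gradient buffers."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def _register(self, *arrays: np.ndarray) -> None:
        for a in arrays:
            self.params.append(a)
            self.grads.append(np.zeros_like(a))

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B, H*W, C*k*k) patches for stride-1 'same' convolution."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, k, k, H, W), strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False,
    )
    return windows.transpose(0, 4, 5, 1, 2, 3).reshape(B, H * W, C * k * k)


def _col2im(dcols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    B, C, H, W = x_shape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    d6 = dcols.reshape(B, H, W, C, k, k)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + H, dj:dj + W] += d6[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2DSame(Layer):
    """Stride-1 convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for 'same' padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        self.W = _he_init(rng, (out_ch, in_ch * kernel * kernel), in_ch * kernel * kernel)
        self.b = np.zeros(out_ch)
        self._register(self.W, self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        cols = _im2col(x, self.k, self.pad)
        out = cols @ self.W.T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(B, H, Wd, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        B, _, H, Wd = x_shape
        d2 = dout.transpose(0, 2, 3, 1).reshape(B, H * Wd, self.out_ch)
        k_dim = self.W.shape[1]
        self.grads[0] += d2.reshape(-1, self.out_ch).T @ cols.reshape(-1, k_dim)
        self.grads[1] += d2.sum(axis=(0, 1))
        dcols = d2 @ self.W
        return _col2im(dcols, x_shape, self.k, self.pad)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(B, C, H // 2, W // 2, 4)
        self._argmax = r.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._x_shape
        dr = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(dr, self._argmax[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(B, C, H, W)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self._register(self.W, self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self.W.shape[0])
        d2 = dout.reshape(-1, self.W.shape[1])
        self.grads[0] += x2.T @ d2
        self.grads[1] += d2.sum(axis=0)
        return dout @ self.W.T


class ChannelAttention(Layer):
    """CBAM channel gate: shared two-layer MLP over global average- and
    max-pooled channel descriptors, summed, squashed by a sigmoid."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ({reduction})"
            )
        hidden = channels // reduction
        self.W1 = _he_init(rng, (channels, hidden), channels)
        self.W2 = _he_init(rng, (hidden, channels), hidden)
        self._register(self.W1, self.W2)

    def _mlp(self, v: np.ndarray):
        h = v @ self.W1
        hr = np.maximum(h, 0.0)
        return hr @ self.W2, (v, h > 0, hr)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        avg = x.mean(axis=(2, 3))
        flat = x.reshape(B, C, H * W)
        arg = flat.argmax(axis=-1)
        mx = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        a_avg, cache_avg = self._mlp(avg)
        a_max, cache_max = self._mlp(mx)
        gate = sigmoid(a_avg + a_max)
        self._cache = (x, gate, cache_avg, cache_max, arg)
        return x * gate[:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, gate, cache_avg, cache_max, arg = self._cache
        B, C, H, W = x.shape
        dx = dout * gate[:, :, None, None]
        dgate = (dout * x).sum(axis=(2, 3))
        da = dgate * gate * (1.0 - gate)
        dvs = []
        for v, relu_mask, hr in (cache_avg, cache_max):
            self.grads[1] += hr.T @ da
            dh = (da @ self.W2.T) * relu_mask
            self.grads[0] += v.T @ dh
            dvs.append(dh @ self.W1.T)
        davg, dmax = dvs
        dx += davg[:, :, None, None] / (H * W)
        dflat = np.zeros((B, C, H * W))
        np.put_along_axis(dflat, arg[..., None], dmax[..., None], axis=-1)
        return dx + dflat.reshape(B, C, H, W)


class SpatialAttention(Layer):
    """CBAM spatial gate: 7x7 convolution over the channel-wise average and
    maximum maps, squashed by a sigmoid and broadcast over channels."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        self.conv = Conv2DSame(2, 1, kernel, rng)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        avg = x.mean(axis=1, keepdims=True)
        arg = x.argmax(axis=1)
        mx = np.take_along_axis(x, arg[:, None], axis=1)
        gate = sigmoid(self.conv.forward(np.concatenate([avg, mx], axis=1)))
        self._cache = (x, gate, arg)
        return x * gate

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, gate, arg = self._cache
        B, C, H, W = x.shape
        dx = dout * gate
        dgate = (dout * x).sum(axis=1, keepdims=True)
        dpre = dgate * gate * (1.0 - gate)
        dmaps = self.conv.backward(dpre)
        dx += dmaps[:, :1] / C
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, arg[:, None], dmaps[:, 1:2], axis=1)
        return dx + dmax


class LayerNorm(Layer):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.eps = eps
        self._register(self.gamma, self.beta)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.grads[0] += (dout * xhat).reshape(-1, d).sum(axis=0)
        self.grads[1] += dout.reshape(-1, d).sum(axis=0)
        dxhat = dout * self.gamma
        return inv / d * (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )


class MultiHeadSelfAttention(Layer):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"heads ({heads}) must divide model dim ({dim})")
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.o = Linear(dim, dim, rng)
        for lay in (self.q, self.k, self.v, self.o):
            self.params.extend(lay.params)
            self.grads.extend(lay.grads)

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        q = self._split(self.q.forward(x))
        k = self._split(self.k.forward(x))
        v = self._split(self.v.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        p = np.exp(scores)
        p /= p.sum(axis=-1, keepdims=True)
        ctx = p @ v
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, self.dim)
        self._cache = (q, k, v, p)
        return self.o.forward(merged)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, p = self._cache
        B, h, T, dh = q.shape
        dmerged = self.o.backward(dout)
        dctx = dmerged.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        dp = dctx @ v.transpose(0, 1, 3, 2)
        dv = p.transpose(0, 1, 3, 2) @ dctx
        dscores = p * (dp - (dp * p).sum(axis=-1, keepdims=True)) / np.sqrt(dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        def merge(a):
            return a.transpose(0, 2, 1, 3).reshape(B, T, self.dim)
        return (self.q.backward(merge(dq)) + self.k.backward(merge(dk))
                + self.v.backward(merge(dv)))


class TransformerEncoderLayer(Layer):
    """Post-norm encoder block: LN(x + MHSA(x)), then LN(x + FFN(x))."""

    def __init__(self, dim: int, heads: int, ff_dim: int, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.relu = ReLU()
        self.ff2 = Linear(ff_dim, dim, rng)
        self.ln2 = LayerNorm(dim)
        for lay in (self.attn, self.ln1, self.ff1, self.ff2, self.ln2):
            self.params.extend(lay.params)
            self.grads.extend(lay.grads)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.ln1.forward(x + self.attn.forward(x))
        return self.ln2.forward(h + self.ff2.forward(self.relu.forward(self.ff1.forward(h))))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.ln2.backward(dout)
        dh = dh + self.ff1.backward(self.relu.backward(self.ff2.backward(dh)))
        dx = self.ln1.backward(dh)
        return dx + self.attn.backward(dx)


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
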