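"""A small, self-contained CNN engine on numpy.

Implements exactly the layer inventory the intelligibility classifier
needs — same-padding 2-D convolution (im2col + BLAS matmul), leaky ReLU,
2 × 2 max pooling with configurable stride, batch normalization, a dense
layer, softmax cross-entropy and the Adam optimizer — with full backward
passes.  Layers carry an analytic ``out_shape`` so a network's layer-by-layer
shape table can be audited without allocating activations.

Convention: activations are (batch, height, width, channels), float32 by
default; float64 is available for numerical gradient checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    name = "layer"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, d: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, shape: tuple) -> tuple:
        return shape

    def params(self) -> list:
        """[(param_array, grad_array), ...]; arrays are updated in place."""
        return []


class Conv2D(Layer):
    """Same-padding convolution, stride 1, evaluated in the frequency domain.

    Even kernels pad asymmetrically (left/top gets the smaller half), which
    preserves the spatial size exactly as a same-padded convolution must.
    The forward pass, the input gradient and the weight gradient are all
    rfft2 products; with an FFT size of ``padded + kernel − 1`` the circular
    weight-gradient correlation is alias-free over the kernel support.
    """

    def __init__(self, in_ch: int, filters: int, kernel: tuple, rng, dtype=np.float32):
        kh, kw = kernel
        self.kh, self.kw, self.in_ch, self.filters = kh, kw, in_ch, filters
        self.pad = ((kh - 1) // 2, kh - 1 - (kh - 1) // 2,
                    (kw - 1) // 2, kw - 1 - (kw - 1) // 2)
        fan_in = kh * kw * in_ch
        # weights kept as (kh, kw, in_ch, filters)
        self.W = (rng.standard_normal((kh, kw, in_ch, filters))
                  * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.name = f"Conv2D({filters}, {kh}x{kw})"

    def out_shape(self, shape):
        h, w, c = shape
        if c != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} input channels, got {c}")
        return (h, w, self.filters)

    def _fft_shape(self, H, W):
        from scipy.fft import next_fast_len

        # linear sizes: forward needs Hp + kh - 1; dW correlation is
        # alias-free for shifts < kh at this size as well
        return (next_fast_len(H + 2 * (self.kh - 1)),
                next_fast_len(W + 2 * (self.kw - 1)))

    @staticmethod
    def _irfft2_last(Zf, fh, fw):
        """Inverse rfft2 over the trailing two axes of a contiguous stack."""
        from scipy import fft as sp_fft

        return sp_fft.irfft2(np.ascontiguousarray(Zf), s=(fh, fw), axes=(-2, -1))

    def forward(self, x, train):
        from scipy import fft as sp_fft

        B, H, W, _ = x.shape
        pt, pb, pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        fh, fw = self._fft_shape(H, W)
        Xf = sp_fft.rfft2(xp, s=(fh, fw), axes=(1, 2))  # (B, fh, fwr, C)
        Wf = sp_fft.rfft2(self.W[::-1, ::-1].astype(x.dtype), s=(fh, fw), axes=(0, 1))
        Yf = (Xf.transpose(1, 2, 0, 3) @ Wf).transpose(2, 3, 0, 1)  # (B, F, fh, fwr)
        y = self._irfft2_last(Yf, fh, fw)
        y = y[:, :, self.kh - 1 : self.kh - 1 + H, self.kw - 1 : self.kw - 1 + W]
        if train:
            self._Xf, self._dims = Xf, (B, H, W, fh, fw)
        return np.ascontiguousarray(y.transpose(0, 2, 3, 1).astype(x.dtype)) \
            + self.b.astype(x.dtype)

    def backward(self, d):
        from scipy import fft as sp_fft

        B, H, W, fh, fw = self._dims
        pt, pb, pl, pr = self.pad
        Hp, Wp = H + self.kh - 1, W + self.kw - 1
        self.db[...] = d.sum(axis=(0, 1, 2))

        Df = sp_fft.rfft2(d, s=(fh, fw), axes=(1, 2))  # (B, fh, fwr, F)
        # weight gradient: alias-free circular correlation of xp with d
        Gf = self._Xf.transpose(1, 2, 3, 0) @ np.conj(Df).transpose(1, 2, 0, 3)
        g = self._irfft2_last(Gf.transpose(2, 3, 0, 1), fh, fw)  # (C, F, fh, fw)
        self.dW[...] = g.transpose(2, 3, 0, 1)[: self.kh, : self.kw].astype(self.dW.dtype)
        # input gradient: full convolution of d with the (unflipped) kernel
        Wf = sp_fft.rfft2(self.W.astype(d.dtype), s=(fh, fw), axes=(0, 1))
        Xg = (Df.transpose(1, 2, 0, 3) @ Wf.transpose(0, 1, 3, 2)).transpose(2, 3, 0, 1)
        dxp = self._irfft2_last(Xg, fh, fw)[:, :, :Hp, :Wp]  # (B, C, Hp, Wp)
        del self._Xf
        return np.ascontiguousarray(
            dxp[:, :, pt : pt + H, pl : pl + W].transpose(0, 2, 3, 1).astype(d.dtype))

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self.name = f"LeakyReLU({slope})"

    def forward(self, x, train):
        if train:
            self._neg = x < 0
        return np.where(x < 0, x * np.asarray(self.slope, x.dtype), x)

    def backward(self, d):
        return np.where(self._neg, d * np.asarray(self.slope, d.dtype), d)


class MaxPool2D(Layer):
    """k × k max pooling without padding; stride may differ from k."""

    def __init__(self, pool: int = 2, stride: int = 2):
        self.k, self.s = pool, stride
        self.name = f"MaxPool2D({pool}x{pool}, stride {stride})"

    def out_shape(self, shape):
        h, w, c = shape
        return ((h - self.k) // self.s + 1, (w - self.k) // self.s + 1, c)

    def forward(self, x, train):
        k, s = self.k, self.s
        v = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        vv = v.reshape(*v.shape[:4], k * k)
        arg = vv.argmax(axis=-1)
        y = np.take_along_axis(vv, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._in_shape = arg, x.shape
        return np.ascontiguousarray(y)

    def backward(self, d):
        k, s = self.k, self.s
        arg = self._arg
        B, Ho, Wo, C = arg.shape
        dx = np.zeros(self._in_shape, dtype=d.dtype)
        rows = (np.arange(Ho) * s)[None, :, None, None] + arg // k
        cols = (np.arange(Wo) * s)[None, None, :, None] + arg % k
        bidx = np.arange(B)[:, None, None, None]
        cidx = np.arange(C)[None, None, None, :]
        np.add.at(dx, (bidx, rows, cols, cidx), d)
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps
        self.name = f"BatchNorm2D({channels})"

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mu.astype(np.float64) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float64) - self.running_var)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._xhat, self._inv = xhat, inv.astype(x.dtype)
        return self.gamma * xhat + self.beta

    def backward(self, d):
        xhat, inv = self._xhat, self._inv
        m = d.shape[0] * d.shape[1] * d.shape[2]
        self.dgamma[...] = (d * xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = d.sum(axis=(0, 1, 2))
        dxhat = d * self.gamma
        dx = (inv / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )
        return dx.astype(d.dtype)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Flatten(Layer):
    name = "Flatten"

    def out_shape(self, shape):
        return (int(np.prod(shape)),)

    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng, dtype=np.float32):
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = rng.uniform(-limit, limit, (in_dim, out_dim)).astype(dtype)
        self.b = np.zeros(out_dim, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.name = f"Dense({out_dim})"

    def out_shape(self, shape):
        return (self.W.shape[1],)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, d):
        self.dW[...] = self._x.T @ d
        self.db[...] = d.sum(axis=0)
        return d @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def params(self) -> list:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def shape_trace(self, input_shape: tuple) -> list:
        """[(layer name, output shape), ...] computed analytically."""
        shape = tuple(input_shape)
        trace = [("Input", shape)]
        for layer in self.layers:
            shape = layer.out_shape(shape)
            trace.append((layer.name, shape))
        return trace

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``targets`` are integer class indices.  Returns (loss, dlogits, probs).
    """
    probs = softmax(logits.astype(np.float64))
    n = len(targets)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), targets] + eps))
    d = probs.copy()
    d[np.arange(n), targets] -= 1.0
    return loss, (d / n).astype(logits.dtype), probs


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
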