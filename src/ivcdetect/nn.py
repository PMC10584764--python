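"""Minimal neural-network engine in numpy.

Provides exactly the layers the classifiers need — 3x3 convolutions, 2x2 max
pooling, dense layers, inverted dropout, and a gated recurrent unit with
per-timestep masking — together with manual backpropagation and an Adam
optimizer. Forward passes cache what the backward pass needs; ``train=False``
disables dropout and caching side effects are irrelevant at inference.

Design notes
------------
* Convolutions use im2col (``sliding_window_view`` + one matmul) so the heavy
  lifting is BLAS; col2im in the backward pass is a 9-term shifted add.
* The GRU follows the Keras gate convention
  ``h_t = z_t * h_{t-1} + (1 - z_t) * htilde_t``; with a 0/1 mask, masked
  timesteps copy the previous hidden state so the output is independent of
  the padding values fed at those steps.
* All randomness (init, dropout) flows through an explicit
  ``numpy.random.Generator`` for bit-reproducible training.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Dropout",
    "GRU",
    "Sequential",
    "Adam",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer: parameters are (name, value, grad) triples."""

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2D(Layer):
    """3x3 (by default) same-padding convolution, stride 1, NCHW layout."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, *, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.W = _glorot(rng, (out_ch, fan_in), fan_in, out_ch)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # B,C,H,W,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * self.k * self.k)
        out = cols @ self.W.T + self.b  # B, HW, F
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(B, self.out_ch, H, W)

    def backward(self, grad):
        cols, xshape = self._cache
        B, C, H, W = xshape
        g = grad.reshape(B, self.out_ch, H * W).transpose(0, 2, 1)  # B, HW, F
        self.dW[...] = g.reshape(-1, self.out_ch).T @ cols.reshape(-1, cols.shape[-1])
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ self.W  # B, HW, C*k*k
        dcols = dcols.reshape(B, H, W, C, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + H, p : p + W]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling; odd trailing rows/columns are dropped."""

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xt = x[:, :, : Ho * 2, : Wo * 2]
        win = xt.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, Ho, Wo, 4
        )
        idx = win.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, xshape = self._cache
        B, C, H, W = xshape
        Ho, Wo = H // 2, W // 2
        dwin = np.zeros((B, C, Ho, Wo, 4), dtype=DTYPE)
        np.put_along_axis(dwin, idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros(xshape, dtype=DTYPE)
        dx[:, :, : Ho * 2, : Wo * 2] = dwin.reshape(B, C, Ho, Wo, 2, 2).transpose(
            0, 1, 2, 4, 3, 5
        ).reshape(B, C, Ho * 2, Wo * 2)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.reshape(-1, self._x.shape[-1]).T @ grad.reshape(
            -1, grad.shape[-1]
        )
        self.db[...] = grad.reshape(-1, grad.shape[-1]).sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, *, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (
            (self.rng.random(x.shape) >= self.rate).astype(DTYPE) / DTYPE(1.0 - self.rate)
        )
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class GRU(Layer):
    """Gated recurrent unit over (B, T, F) sequences with optional 0/1 mask.

    Gates (Keras convention):
        z_t = sigma(x_t Wz + h_{t-1} Uz + bz)        update
        r_t = sigma(x_t Wr + h_{t-1} Ur + br)        reset
        htilde_t = tanh(x_t Wh + (r_t * h_{t-1}) Uh + bh)
        h_t = z_t * h_{t-1} + (1 - z_t) * htilde_t
    Masked steps (mask == 0) carry h_{t-1} forward unchanged.
    """

    def __init__(self, n_in: int, units: int, *, return_sequences: bool,
                 rng: np.random.Generator):
        self.units = units
        self.return_sequences = return_sequences
        self.W = _glorot(rng, (n_in, 3 * units), n_in, units)
        self.U = _glorot(rng, (units, 3 * units), units, units)
        self.b = np.zeros(3 * units, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("U", self.U, self.dU), ("b", self.b, self.db)]

    def forward(self, x, train=False, mask=None):
        B, T, _ = x.shape
        n = self.units
        h = np.zeros((B, n), dtype=DTYPE)
        hs, cache = [], []
        for t in range(T):
            xt = x[:, t, :]
            gx = xt @ self.W + self.b
            gh = h @ self.U
            z = _sigmoid(gx[:, :n] + gh[:, :n])
            r = _sigmoid(gx[:, n : 2 * n] + gh[:, n : 2 * n])
            hcand = np.tanh(gx[:, 2 * n :] + (r * h) @ self.U[:, 2 * n :])
            hnew = z * h + (1.0 - z) * hcand
            m = None if mask is None else mask[:, t : t + 1]
            hout = hnew if m is None else m * hnew + (1.0 - m) * h
            cache.append((xt, h, z, r, hcand, m))
            h = hout
            hs.append(h)
        self._cache = cache
        self._x_shape = x.shape
        out = np.stack(hs, axis=1)
        self._out = out
        return out if self.return_sequences else h

    def backward(self, grad):
        B, T, _ = self._x_shape
        n = self.units
        self.dW[...] = 0.0
        self.dU[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros(self._x_shape, dtype=DTYPE)
        dh_next = np.zeros((B, n), dtype=DTYPE)
        for t in reversed(range(T)):
            xt, hprev, z, r, hcand, m = self._cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += grad[:, t, :]
            elif t == T - 1:
                dh += grad
            if m is not None:
                dh_prev_mask = dh * (1.0 - m)
                dh = dh * m
            else:
                dh_prev_mask = 0.0
            # h_t = z*h_prev + (1-z)*hcand
            dz = dh * (hprev - hcand)
            dhcand = dh * (1.0 - z)
            dhprev = dh * z
            da_c = dhcand * (1.0 - hcand**2)  # pre-tanh
            da_z = dz * z * (1.0 - z)
            # hcand pre-act = x Wh + (r*hprev) Uh
            drh = da_c @ self.U[:, 2 * n :].T
            dr = drh * hprev
            dhprev += drh * r
            da_r = dr * r * (1.0 - r)
            da = np.concatenate([da_z, da_r, da_c], axis=1)
            self.dW += xt.T @ da
            self.db += da.sum(axis=0)
            self.dU[:, : 2 * n] += hprev.T @ da[:, : 2 * n]
            self.dU[:, 2 * n :] += (r * hprev).T @ da_c
            dx[:, t, :] = da @ self.W.T
            dhprev += da[:, : 2 * n] @ self.U[:, : 2 * n].T
            dh_next = dhprev + dh_prev_mask
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{name}", v, g) for name, v, g in layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (name, value, grad)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (_, val, grad), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * grad
            v *= self.b2
            v += (1.0 - self.b2) * grad**2
            val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
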