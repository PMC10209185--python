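"""Compact CPU neural-network core: layers, backward passes, Adam.

Everything runs on numpy with a channels-last ``(N, H, W, C)`` layout so
convolutions reduce to one matrix product per kernel offset — the fastest
pure-numpy formulation for the small models this package trains.  Each
layer stores what its backward pass needs; gradients accumulate in
``Param.grad`` and an :class:`Adam` instance updates the parameters.

Only the operations the U-Net needs exist here: same-padded convolution,
batch normalization, ReLU, 2×2 max pooling, nearest-neighbor upsampling and
channel concatenation.
"""

from __future__ import annotations

import numpy as np

#: Single precision throughout the network core: halves memory traffic and
#: speeds up the BLAS-bound convolutions without hurting segmentation.
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self):
        return []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution with 'same' padding (asymmetric for even k).

    Weights use He fan-in initialization (std = sqrt(2 / (k·k·C_in))),
    the scheme designed for rectifier networks.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 name: str = "conv"):
        fan_in = k * k * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, in_ch, out_ch))
        self.w = Param(w.astype(DTYPE), f"{name}.w")
        self.b = Param(np.zeros(out_ch, dtype=DTYPE), f"{name}.b")
        self.k = k
        self.in_ch, self.out_ch = in_ch, out_ch
        pt = (k - 1) // 2
        self.pad = (pt, k - 1 - pt)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool):
        if x.shape[-1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[-1]}")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        N, H, W, _ = x.shape
        pt, pb = self.pad
        xp = np.pad(x, ((0, 0), (pt, pb), (pt, pb), (0, 0)))
        self._xp, self._shape = xp, (N, H, W)
        y = np.empty((N, H, W, self.out_ch), dtype=DTYPE)
        y[:] = self.b.value
        wv = self.w.value
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, di:di + H, dj:dj + W, :].reshape(-1, self.in_ch)
                y += (patch @ wv[di, dj]).reshape(N, H, W, self.out_ch)
        return y

    def backward(self, dy):
        N, H, W = self._shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        dyf = dy.reshape(-1, self.out_ch)
        wv = self.w.value
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, di:di + H, dj:dj + W, :].reshape(-1, self.in_ch)
                self.w.grad[di, dj] += patch.T @ dyf
                dxp[:, di:di + H, dj:dj + W, :] += (
                    dyf @ wv[di, dj].T).reshape(N, H, W, self.in_ch)
        self.b.grad += dyf.sum(axis=0)
        pt, pb = self.pad
        Hp, Wp = xp.shape[1], xp.shape[2]
        self._xp = None
        return dxp[:, pt:Hp - pb, pt:Wp - pb, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(ch, dtype=DTYPE), f"{name}.gamma")
        self.beta = Param(np.zeros(ch, dtype=DTYPE), f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv, self._n = xhat, inv, x[..., 0].size
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dy):
        xhat, inv, n = self._xhat, self._inv, self._n
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        dx = (inv / n) * (n * dxhat
                          - dxhat.sum(axis=(0, 1, 2))
                          - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train: bool):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0.0)

    def backward(self, dy):
        dy = np.where(self._mask, dy, 0.0)
        self._mask = None
        return dy


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; ties route gradient to the first maximum."""

    def forward(self, x, train: bool):
        N, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C)
        flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._shape = arg, (N, H, W, C)
        return y

    def backward(self, dy):
        N, H, W, C = self._shape
        flat = np.zeros((N, H // 2, W // 2, C, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        dx = flat.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._arg = None
        return dx.reshape(N, H, W, C)


class UpsampleNearest2(Layer):
    def forward(self, x, train: bool):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy):
        N, H, W, C = dy.shape
        return dy.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train: bool):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam with the standard exponential-decay defaults."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
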