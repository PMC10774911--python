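"""Minimal CNN building blocks with explicit forward/backward passes.

Everything operates on float32 arrays of shape ``(N, C, H, W)``.  Each
layer caches what its backward pass needs; ``backward`` consumes the
gradient w.r.t. the output and returns the gradient w.r.t. the input,
accumulating parameter gradients in ``layer.G``.

Convolutions are sums of per-offset channel contractions on shifted
views, so the heavy lifting runs in BLAS without materializing patch
matrices; the framework is small but complete enough for the residual
super-resolution localizers in this package.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: parameter dict ``P`` and matching gradient dict ``G``."""

    def __init__(self) -> None:
        self.P: dict[str, np.ndarray] = {}
        self.G: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.G.values():
            g[...] = 0.0


class Conv2d(Layer):
    """Same-padding 2D convolution (odd kernel, stride 1).

    Implemented as a sum of per-offset 1x1 convolutions (tensordot over
    channels on shifted views), which keeps memory flat and lets BLAS do
    the channel contractions.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.k, self.c_in, self.c_out = kernel, c_in, c_out
        fan_in = c_in * kernel * kernel
        # He initialization, appropriate for the leaky-rectified blocks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.P = {"W": w.astype(DTYPE), "b": np.zeros(c_out, dtype=DTYPE)}
        self.G = {k2: np.zeros_like(v) for k2, v in self.P.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        self._xshape = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        if train:
            self._xp = xp
        Wk = self.P["W"]
        out = np.empty((N, self.c_out, H, W), dtype=DTYPE)
        out[...] = self.P["b"][None, :, None, None]
        for a in range(self.k):
            for b in range(self.k):
                sl = xp[:, :, a : a + H, b : b + W]
                out += np.einsum("nchw,oc->nohw", sl, Wk[:, :, a, b], optimize=True)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, _, H, W = dy.shape
        p = self.k // 2
        self.G["b"] += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(self._xp)
        Wk = self.P["W"]
        for a in range(self.k):
            for b in range(self.k):
                sl = self._xp[:, :, a : a + H, b : b + W]
                self.G["W"][:, :, a, b] += np.einsum(
                    "nohw,nchw->oc", dy, sl, optimize=True
                )
                dxp[:, :, a : a + H, b : b + W] += np.einsum(
                    "nohw,oc->nchw", dy, Wk[:, :, a, b], optimize=True
                )
        return dxp[:, :, p : p + H, p : p + W]


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel size equal to the stride.

    Each input pixel expands to a learned ``s x s`` block, tripling (for
    s=3) the spatial resolution without overlap artifacts.
    """

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.s, self.c_in, self.c_out = stride, c_in, c_out
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, stride, stride))
        self.P = {"W": w.astype(DTYPE), "b": np.zeros(c_out, dtype=DTYPE)}
        self.G = {k: np.zeros_like(v) for k, v in self.P.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        N, C, H, W = x.shape
        out = np.einsum("ncij,cdab->ndiajb", x, self.P["W"], optimize=True)
        out = out.reshape(N, self.c_out, H * self.s, W * self.s)
        out += self.P["b"][None, :, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, _, Ho, Wo = dy.shape
        s = self.s
        blocks = dy.reshape(N, self.c_out, Ho // s, s, Wo // s, s)
        self.G["b"] += dy.sum(axis=(0, 2, 3))
        self.G["W"] += np.einsum("ncij,ndiajb->cdab", self._x, blocks, optimize=True)
        return np.einsum("ndiajb,cdab->ncij", blocks, self.P["W"], optimize=True)


class InstanceNorm(Layer):
    """Per-instance, per-channel normalization with affine parameters."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.P = {
            "gamma": np.ones(channels, dtype=DTYPE),
            "beta": np.zeros(channels, dtype=DTYPE),
        }
        self.G = {k: np.zeros_like(v) for k, v in self.P.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        return self.P["gamma"][None, :, None, None] * xhat + self.P["beta"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.G["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.G["beta"] += dy.sum(axis=(0, 2, 3))
        g = dy * self.P["gamma"][None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        gm = g.mean(axis=(2, 3), keepdims=True)
        gx = (g * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (g - gm - xhat * gx)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._neg = x < 0
        return np.where(x < 0, self.slope * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.slope * dy, dy)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def param_items(self, prefix: str = "") -> list[tuple[str, np.ndarray, np.ndarray]]:
        items = []
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "param_items"):
                items.extend(layer.param_items(f"{prefix}{i}."))
            else:
                for name, p in layer.P.items():
                    items.append((f"{prefix}{i}.{name}", p, layer.G[name]))
        return items


class ResBlock(Layer):
    """conv -> IN -> LeakyReLU -> conv -> IN, plus identity skip."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, slope: float = 0.2):
        super().__init__()
        self.body = Sequential(
            Conv2d(channels, channels, kernel, rng),
            InstanceNorm(channels),
            LeakyReLU(slope),
            Conv2d(channels, channels, kernel, rng),
            InstanceNorm(channels),
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x + self.body.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.body.backward(dy)

    def zero_grad(self) -> None:
        self.body.zero_grad()

    def param_items(self, prefix: str = "") -> list[tuple[str, np.ndarray, np.ndarray]]:
        return self.body.param_items(prefix + "body.")
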