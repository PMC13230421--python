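"""Minimal convolutional-network layers with explicit forward/backward passes.

All layers operate on arrays of shape ``(N, C, H, W)``; parameters are
float32 (``DTYPE``) and computations follow the input dtype.  ``forward``
returns ``(output, cache)``; ``backward`` consumes the cache and the upstream
gradient, accumulates parameter gradients into ``layer.grads`` (unless the
layer is frozen via ``trainable = False``) and returns the gradient with
respect to the layer input.  Caches are explicit so one layer instance can be
driven through several forward passes per iteration (the cycle-consistent
training step needs exactly that).
"""

from __future__ import annotations

import numpy as np

#: working precision of the layer stack; float32 keeps the im2col
#: buffers small and BLAS fast at desk scale.
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sequential",
    "ResidualBlock",
]


class Layer:
    """Base class: a parameterised, differentiable array transform."""

    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    # -- (de)serialisation ------------------------------------------------
    def named_layers(self, prefix: str = ""):
        yield prefix, self

    def state_items(self, prefix: str = ""):
        for name, layer in self.named_layers(prefix):
            for k, p in layer.params.items():
                yield f"{name}{k}", p


def _reflect_pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")


def _reflect_pad_backward(dxp: np.ndarray, p: int) -> np.ndarray:
    """Fold gradients of a reflect-padded array back onto the source."""
    if p == 0:
        return dxp
    # width axis first, then height; reflect (no edge repeat): padded index
    # j < p holds source column p - j; right pad t = 1..p holds column W-1-t.
    g = dxp[:, :, :, p:-p].copy()
    W = g.shape[3]
    for j in range(p):
        g[:, :, :, p - j] += dxp[:, :, :, j]
    for t in range(1, p + 1):
        g[:, :, :, W - 1 - t] += dxp[:, :, :, p + W - 1 + t]
    out = g[:, :, p:-p, :].copy()
    H = out.shape[2]
    for j in range(p):
        out[:, :, p - j, :] += g[:, :, j, :]
    for t in range(1, p + 1):
        out[:, :, H - 1 - t, :] += g[:, :, p + H - 1 + t, :]
    return out


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col + BLAS matmul."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, pad_mode="zeros", rng: np.random.Generator | None = None,
                 init_sd=0.02):
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.pad, self.pad_mode = stride, padding, pad_mode
        rng = rng or np.random.default_rng(0)
        self.params["weight"] = rng.normal(
            0.0, init_sd, size=(out_channels, in_channels, kernel_size, kernel_size)
        ).astype(DTYPE)
        self.params["bias"] = np.zeros(out_channels, dtype=DTYPE)
        self.zero_grad()

    def _pad(self, x):
        if self.pad == 0:
            return x
        if self.pad_mode == "reflect":
            return _reflect_pad(x, self.pad)
        return np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))

    def forward(self, x):
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        xp = self._pad(x)
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        N, C, Ho, Wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
        wmat = self.params["weight"].reshape(self.cout, C * k * k)
        y = cols @ wmat.T + self.params["bias"]
        y = y.reshape(N, Ho, Wo, self.cout).transpose(0, 3, 1, 2)
        return y, (x.shape, xp.shape, cols)

    def backward(self, cache, dy):
        x_shape, xp_shape, cols = cache
        N, Co, Ho, Wo = dy.shape
        k, s = self.k, self.stride
        dyf = dy.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Co)
        if self.trainable:
            self.grads["weight"] += (dyf.T @ cols).reshape(self.params["weight"].shape)
            self.grads["bias"] += dyf.sum(axis=0)
        wmat = self.params["weight"].reshape(Co, -1)
        dcols = (dyf @ wmat).reshape(N, Ho, Wo, self.cin, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, Ho, Wo, k, k)
        dxp = np.zeros(xp_shape, dtype=dcols.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u:u + s * Ho:s, v:v + s * Wo:s] += dcols[:, :, :, :, u, v]
        if self.pad == 0:
            return dxp
        if self.pad_mode == "reflect":
            return _reflect_pad_backward(dxp, self.pad)
        p = self.pad
        return dxp[:, :, p:-p, p:-p]


class ConvTranspose2d(Layer):
    """Transposed convolution (fractionally strided), torch weight layout
    ``(C_in, C_out, k, k)``; with k=3, stride=2, padding=1, output_padding=1
    it exactly doubles the spatial size."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=2,
                 padding=1, output_padding=1, rng=None, init_sd=0.02):
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.pad, self.opad = stride, padding, output_padding
        rng = rng or np.random.default_rng(0)
        self.params["weight"] = rng.normal(
            0.0, init_sd, size=(in_channels, out_channels, kernel_size, kernel_size)
        ).astype(DTYPE)
        self.params["bias"] = np.zeros(out_channels, dtype=DTYPE)
        self.zero_grad()

    def out_size(self, n: int) -> int:
        return self.stride * (n - 1) + self.k - 2 * self.pad + self.opad

    def forward(self, x):
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        Hf, Wf = s * (H - 1) + k, s * (W - 1) + k
        Ho, Wo = self.out_size(H), self.out_size(W)
        w = self.params["weight"]
        yf = np.zeros((N, self.cout, Hf, Wf), dtype=np.result_type(x, w))
        for u in range(k):
            for v in range(k):
                contrib = np.einsum("ncij,co->noij", x, w[:, :, u, v], optimize=True)
                yf[:, :, u:u + s * H:s, v:v + s * W:s] += contrib
        y = yf[:, :, p:p + Ho, p:p + Wo] + self.params["bias"][None, :, None, None]
        return y, (x, (Hf, Wf))

    def backward(self, cache, dy):
        x, (Hf, Wf) = cache
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        dyf = np.zeros((N, self.cout, Hf, Wf), dtype=dy.dtype)
        dyf[:, :, p:p + dy.shape[2], p:p + dy.shape[3]] = dy
        w = self.params["weight"]
        dx = np.zeros_like(x)
        for u in range(k):
            for v in range(k):
                sl = dyf[:, :, u:u + s * H:s, v:v + s * W:s]
                dx += np.einsum("noij,co->ncij", sl, w[:, :, u, v], optimize=True)
                if self.trainable:
                    self.grads["weight"][:, :, u, v] += np.einsum(
                        "ncij,noij->co", x, sl, optimize=True
                    )
        if self.trainable:
            self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        return dx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel spatial normalisation (no learned affine)."""

    trainable = False

    def __init__(self, eps=1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = (x - mu) * inv
        return y, (y, inv)

    def backward(self, cache, dy):
        y, inv = cache
        m1 = dy.mean(axis=(2, 3), keepdims=True)
        m2 = (dy * y).mean(axis=(2, 3), keepdims=True)
        return inv * (dy - m1 - y * m2)


class ReLU(Layer):
    trainable = False

    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy):
        return dy * cache


class LeakyReLU(Layer):
    trainable = False

    def __init__(self, alpha=0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.alpha * x), mask

    def backward(self, cache, dy):
        return np.where(cache, dy, self.alpha * dy)


class Tanh(Layer):
    trainable = False

    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, cache, dy):
        return dy * (1.0 - cache * cache)


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(c, dy)
        return dy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def named_layers(self, prefix=""):
        for i, layer in enumerate(self.layers):
            yield from layer.named_layers(f"{prefix}{i}.")


class ResidualBlock(Layer):
    """Two reflect-padded 3x3 convs with instance norm; identity skip."""

    def __init__(self, channels, rng=None):
        super().__init__()
        self.body = Sequential([
            Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng),
            InstanceNorm2d(),
            ReLU(),
            Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng),
            InstanceNorm2d(),
        ])

    def forward(self, x):
        y, c = self.body.forward(x)
        return x + y, c

    def backward(self, cache, dy):
        return dy + self.body.backward(cache, dy)

    def zero_grad(self):
        self.body.zero_grad()

    def named_layers(self, prefix=""):
        yield from self.body.named_layers(f"{prefix}body.")
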