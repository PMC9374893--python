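"""Minimal 3D convolutional-network layers on numpy with hand-written
backpropagation.

No deep-learning framework is assumed at runtime; the networks needed here are
small U-shaped models run at batch size 1, which a plain im2col/matmul
implementation handles comfortably on a single CPU. Every layer implements

    forward(x) -> y        caching whatever backward needs
    backward(gy) -> gx     accumulating parameter gradients in ``Param.grad``

Tensors are ``(channels, D, H, W)`` float32 arrays. Gradient correctness is
established by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "ReLU",
    "Sigmoid",
    "ChannelSoftmax",
    "InstanceNorm",
    "MaxPool",
    "MaxUnpool",
    "Adam",
]


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel size 1 or 3, stride 1, 'same' zero padding.

    The k=3 case runs as 27 GEMMs over *flat offset views* of the
    zero-padded input: for crop-region voxels a flat shift equals the 3D
    shift (the one-voxel pad absorbs row/plane wrap), so no patch gather is
    ever materialized.
    """

    _OFFSETS = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)]

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, rng=None, name=""):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel counts must be >= 1")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.weight = Param(w, f"{name}.weight")
        # small positive bias: keeps ReLU branches alive at very small widths
        self.bias = Param(np.full(out_ch, 0.01), f"{name}.bias")
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        c, d, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        if self.kernel == 1:
            xf = x.reshape(c, -1)
            out = self.weight.value @ xf + self.bias.value[:, None]
            self._cache = (xf, (d, h, w))
            return out.reshape(self.out_ch, d, h, w)
        xp = np.zeros((c, d + 2, h + 2, w + 2), dtype=np.float32)
        xp[:, 1:-1, 1:-1, 1:-1] = x
        xpf = xp.reshape(c, -1)
        length = xpf.shape[1]
        wk = self.weight.value.reshape(self.out_ch, c, 27)
        out = np.zeros((self.out_ch, length), dtype=np.float32)
        for t, o in enumerate(self._flat_offsets(d, h, w)):
            lo, hi = max(0, -o), length - max(0, o)
            out[:, lo:hi] += wk[:, :, t] @ xpf[:, lo + o : hi + o]
        out += self.bias.value[:, None]
        self._cache = (xpf, (d, h, w))
        return np.ascontiguousarray(
            out.reshape(self.out_ch, d + 2, h + 2, w + 2)[:, 1:-1, 1:-1, 1:-1]
        )

    def _flat_offsets(self, d, h, w):
        return [
            a * (h + 2) * (w + 2) + b * (w + 2) + c for a, b, c in self._OFFSETS
        ]

    def backward(self, gy):
        xf, (d, h, w) = self._cache
        if self.kernel == 1:
            g = gy.reshape(self.out_ch, -1).astype(np.float32)
            self.weight.grad += g @ xf.T
            self.bias.grad += g.sum(axis=1)
            return (self.weight.value.T @ g).reshape(self.in_ch, d, h, w)
        # pad the output gradient: border stays zero, so offset-view GEMMs
        # see no wrap contamination
        gp = np.zeros((self.out_ch, d + 2, h + 2, w + 2), dtype=np.float32)
        gp[:, 1:-1, 1:-1, 1:-1] = gy
        gpf = gp.reshape(self.out_ch, -1)
        length = gpf.shape[1]
        wk = self.weight.value.reshape(self.out_ch, self.in_ch, 27)
        wg = self.weight.grad.reshape(self.out_ch, self.in_ch, 27)
        gxf = np.zeros((self.in_ch, length), dtype=np.float32)
        for t, o in enumerate(self._flat_offsets(d, h, w)):
            lo, hi = max(0, -o), length - max(0, o)
            src = xf[:, lo + o : hi + o]
            dst = gpf[:, lo:hi]
            wg[:, :, t] += dst @ src.T
            gxf[:, lo + o : hi + o] += wk[:, :, t].T @ dst
        self.bias.grad += gy.reshape(self.out_ch, -1).sum(axis=1)
        return np.ascontiguousarray(
            gxf.reshape(self.in_ch, d + 2, h + 2, w + 2)[:, 1:-1, 1:-1, 1:-1]
        )


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        return self._y.astype(np.float32)

    def backward(self, gy):
        return (gy * self._y * (1.0 - self._y)).astype(np.float32)


class ChannelSoftmax(Layer):
    """Per-voxel softmax across the channel axis."""

    def forward(self, x):
        z = x - x.max(axis=0, keepdims=True)
        e = np.exp(z.astype(np.float64))
        self._y = e / e.sum(axis=0, keepdims=True)
        return self._y.astype(np.float32)

    def backward(self, gy):
        dot = (gy * self._y).sum(axis=0, keepdims=True)
        return (self._y * (gy - dot)).astype(np.float32)


class InstanceNorm(Layer):
    """Per-channel normalization over spatial dims with a learned affine."""

    EPS = 1e-5

    def __init__(self, channels: int, affine: bool = True, name=""):
        self.channels = channels
        self.affine = affine
        self.gamma = Param(np.ones(channels), f"{name}.gamma") if affine else None
        self.beta = Param(np.zeros(channels), f"{name}.beta") if affine else None

    def params(self):
        return [self.gamma, self.beta] if self.affine else []

    def forward(self, x):
        x = x.astype(np.float32)
        # a single-voxel feature map cannot be variance-normalized (the
        # statistic is the voxel itself); pass through so the deep branch
        # keeps a gradient at very small input sizes
        self._passthrough = np.prod(x.shape[1:]) == 1
        if self._passthrough:
            self._xhat = x
            self._inv = np.ones((x.shape[0], 1, 1, 1), dtype=np.float32)
        else:
            mu = x.mean(axis=(1, 2, 3), keepdims=True)
            var = x.var(axis=(1, 2, 3), keepdims=True)
            self._inv = 1.0 / np.sqrt(var + self.EPS)
            self._xhat = (x - mu) * self._inv
        if self.affine:
            g = self.gamma.value.reshape(-1, 1, 1, 1)
            b = self.beta.value.reshape(-1, 1, 1, 1)
            return (self._xhat * g + b).astype(np.float32)
        return self._xhat.astype(np.float32)

    def backward(self, gy):
        xhat, inv = self._xhat, self._inv
        n = float(np.prod(gy.shape[1:]))
        if self.affine:
            self.gamma.grad += (gy * xhat).sum(axis=(1, 2, 3))
            self.beta.grad += gy.sum(axis=(1, 2, 3))
            gy = gy * self.gamma.value.reshape(-1, 1, 1, 1)
        if self._passthrough:
            return gy.astype(np.float32)
        mean_g = gy.mean(axis=(1, 2, 3), keepdims=True)
        mean_gx = (gy * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return (inv * (gy - mean_g - xhat * mean_gx)).astype(np.float32)


class MaxPool(Layer):
    """Max pooling by an integer factor per axis, recording argmax positions.

    Spatial dims must be divisible by the factor (callers pad). The recorded
    one-hot mask is shared with the paired :class:`MaxUnpool`.
    """

    def __init__(self, factor=(2, 2, 2)):
        self.factor = tuple(int(f) for f in factor)
        self.mask = None  # one-hot of argmax positions, input shape

    def _blocks(self, x):
        c, d, h, w = x.shape
        fd, fh, fw = self.factor
        v = x.reshape(c, d // fd, fd, h // fh, fh, w // fw, fw)
        return v.transpose(0, 1, 3, 5, 2, 4, 6).reshape(
            c, d // fd, h // fh, w // fw, fd * fh * fw
        )

    def forward(self, x):
        c, d, h, w = x.shape
        fd, fh, fw = self.factor
        if d % fd or h % fh or w % fw:
            raise ValueError(f"shape {x.shape[1:]} not divisible by factor {self.factor}")
        blocks = self._blocks(x)
        arg = blocks.argmax(axis=-1)
        onehot = np.zeros(blocks.shape, dtype=bool)
        np.put_along_axis(onehot, arg[..., None], True, axis=-1)
        self.mask = (
            onehot.reshape(c, d // fd, h // fh, w // fw, fd, fh, fw)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )
        self._in_shape = x.shape
        return np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        return (self._upsample(gy) * self.mask).astype(np.float32)

    def _upsample(self, y):
        fd, fh, fw = self.factor
        return np.repeat(np.repeat(np.repeat(y, fd, 1), fh, 2), fw, 3)


class MaxUnpool(Layer):
    """Places values back at the argmax positions recorded by its MaxPool."""

    def __init__(self, pool: MaxPool):
        self.pool = pool

    def forward(self, x):
        return (self.pool._upsample(x) * self.pool.mask).astype(np.float32)

    def backward(self, gy):
        p = self.pool
        c, d, h, w = gy.shape
        fd, fh, fw = p.factor
        g = (gy * p.mask).reshape(c, d // fd, fd, h // fh, fh, w // fw, fw)
        return np.ascontiguousarray(
            g.sum(axis=(2, 4, 6)), dtype=np.float32
        )


class Adam:
    """ADAM optimizer over a flat parameter list."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
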