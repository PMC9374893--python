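"""The three U-shaped segmentation network topologies, with scalable widths.

All nets share the same construction style: an encoder of conv blocks with
max-pooling that records argmax indices, a decoder of unpooling stages that
restore those indices, and skip connections implemented as *sums* (which is
why encoder/decoder channel counts must match). Widths scale with a single
``width_scale`` factor; 1.0 reproduces the reference channel counts
(24/64/128 for the T1 lesion net, 12/16 for the ROI and FLAIR nets).

The FLAIR-space net pools the slice axis only at the first two levels, so a
thin stack of 2D slices (>= 8) survives all five levels; inputs of any
spatial size are symmetrically zero-padded to the required divisors
internally and cropped on output, so output spatial shape always equals
input spatial shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    Adam,
    ChannelSoftmax,
    Conv3d,
    InstanceNorm,
    MaxPool,
    MaxUnpool,
    ReLU,
    Sigmoid,
)

__all__ = [
    "UNetSpec",
    "Model",
    "build_t1_wmh_net",
    "build_t1_roi_net",
    "build_flair_net",
    "build_net",
    "save_model",
    "load_model",
]

MIN_SPATIAL = 8  # below this the deepest feature maps collapse to nothing


@dataclass(frozen=True)
class UNetSpec:
    kind: str  # t1_wmh | t1_roi | flair
    width_scale: float
    out_channels: int
    final_activation: str  # sigmoid | softmax
    pool_factors: tuple  # per level, 3-tuple each
    seed: int

    @property
    def divisors(self) -> tuple:
        d = np.ones(3, dtype=int)
        for f in self.pool_factors:
            d *= np.asarray(f, dtype=int)
        return tuple(int(x) for x in d)


def _scaled(base: int, width_scale: float) -> int:
    c = int(round(base * width_scale))
    if c < 1:
        raise ValueError(
            f"width_scale {width_scale} collapses a {base}-channel layer below 1"
        )
    return c


class Model:
    """An op-tape network: ordered layers, skip saves/sums and pool/unpool pairs."""

    def __init__(self, spec: UNetSpec, ops):
        self.spec = spec
        self.ops = ops

    def params(self):
        out = []
        for kind, payload in self.ops:
            if kind == "layer":
                out.extend(payload.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- raw passes on already-padded (C, D, H, W) tensors ------------------

    def _forward_tape(self, x):
        saved = {}
        for kind, payload in self.ops:
            if kind == "layer":
                x = payload.forward(x)
            elif kind == "save":
                saved[payload] = x
            elif kind == "sum":
                x = x + saved[payload]
            else:  # pragma: no cover - construction guarantees
                raise RuntimeError(kind)
        return x

    def _backward_tape(self, gy):
        skip_grads = {}
        for kind, payload in reversed(self.ops):
            if kind == "layer":
                gy = payload.backward(gy)
            elif kind == "sum":
                if payload in skip_grads:
                    skip_grads[payload] = skip_grads[payload] + gy
                else:
                    skip_grads[payload] = gy
            elif kind == "save":
                if payload in skip_grads:
                    gy = gy + skip_grads.pop(payload)
        return gy

    # -- public API on 3D volumes -------------------------------------------

    def _padding(self, shape):
        div = self.spec.divisors
        pads = []
        for s, dv in zip(shape, div):
            target = int(np.ceil(s / dv) * dv)
            lo = (target - s) // 2
            pads.append((lo, target - s - lo))
        return pads

    def forward(self, data: np.ndarray) -> np.ndarray:
        """Run on a 3D volume; returns (out_channels, *data.shape) in [0, 1]."""
        data = np.asarray(data, dtype=np.float32)
        if data.ndim != 3:
            raise ValueError("expected a 3D volume")
        if min(data.shape) < MIN_SPATIAL:
            raise ValueError(
                f"input shape {data.shape} below receptive-field minimum "
                f"({MIN_SPATIAL} voxels per axis)"
            )
        self._pads = self._padding(data.shape)
        self._shape = data.shape
        x = np.pad(data, self._pads)[None]
        y = self._forward_tape(x)
        (d0, _), (h0, _), (w0, _) = self._pads
        d, h, w = self._shape
        return y[:, d0 : d0 + d, h0 : h0 + h, w0 : w0 + w]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the (cropped) output of ``forward``."""
        c = gout.shape[0]
        full = np.zeros(
            (c,) + tuple(s + a + b for s, (a, b) in zip(self._shape, self._pads)),
            dtype=np.float32,
        )
        (d0, _), (h0, _), (w0, _) = self._pads
        d, h, w = self._shape
        full[:, d0 : d0 + d, h0 : h0 + h, w0 : w0 + w] = gout
        gx = self._backward_tape(full)
        return gx[0, d0 : d0 + d, h0 : h0 + h, w0 : w0 + w]

    def make_optimizer(self, lr=1e-3) -> Adam:
        return Adam(self.params(), lr=lr)


def _conv_block(ops, rng, specs):
    """Append [('conv3'|'conv1', in, out) | 'relu' | ('in', ch)] items."""
    for item in specs:
        if item == "relu":
            ops.append(("layer", ReLU()))
        elif item[0] == "in":
            ops.append(("layer", InstanceNorm(item[1])))
        else:
            k = 3 if item[0] == "conv3" else 1
            ops.append(("layer", Conv3d(item[1], item[2], kernel=k, rng=rng)))


def build_t1_wmh_net(width_scale: float = 1.0, seed: int = 0) -> Model:
    """Lesion + cortical-ribbon net on the high-res T1 working grid.

    Two sigmoid output channels: 0 = lesion probability, 1 = cortical ribbon.
    """
    rng = np.random.default_rng(seed)
    s = lambda b: _scaled(b, width_scale)
    c0, c1, cb = s(24), s(64), s(128)
    factors = ((2, 2, 2),) * 5
    ops, pools = [], []
    _conv_block(ops, rng, [("conv3", 1, c0), ("in", c0), "relu", ("conv3", c0, c1), "relu"])
    ops.append(("save", "b0"))
    for lvl in range(1, 5):
        p = MaxPool(factors[lvl - 1])
        pools.append(p)
        ops.append(("layer", p))
        _conv_block(
            ops, rng, [("conv3", c1, c1), ("in", c1), "relu", ("conv3", c1, c1), "relu"]
        )
        if lvl < 4:
            ops.append(("save", f"b{lvl}"))
    p = MaxPool(factors[4])
    pools.append(p)
    ops.append(("layer", p))
    _conv_block(ops, rng, [("conv3", c1, cb), ("in", cb), "relu", ("conv3", cb, c1), "relu"])
    # decoder: first stage has no skip (block4 is not summed)
    for skip in (None, "b3", "b2", "b1"):
        ops.append(("layer", MaxUnpool(pools.pop())))
        _conv_block(ops, rng, [("conv3", c1, c1), ("in", c1), "relu"])
        if skip:
            ops.append(("sum", skip))
        _conv_block(ops, rng, [("conv3", c1, c1), "relu"])
    ops.append(("layer", MaxUnpool(pools.pop())))
    _conv_block(ops, rng, [("conv3", c1, c1), ("in", c1), "relu"])
    ops.append(("sum", "b0"))
    _conv_block(ops, rng, [("conv3", c1, c1), "relu", ("conv3", c1, c0), "relu", ("conv1", c0, 2)])
    ops.append(("layer", Sigmoid()))
    spec = UNetSpec("t1_wmh", width_scale, 2, "sigmoid", factors, seed)
    return Model(spec, ops)


def _build_12_16_net(kind, width_scale, seed, factors, out_channels, final):
    """Shared scaffold for the ROI and FLAIR nets (12/16-channel family)."""
    rng = np.random.default_rng(seed)
    s = lambda b: _scaled(b, width_scale)
    c0, c1, c8 = s(12), s(16), s(8)
    ops, pools = [], []
    if kind == "t1_roi":
        _conv_block(ops, rng, [("conv3", 1, c0), "relu"])
    else:
        _conv_block(ops, rng, [("conv3", 1, c0), ("in", c0), "relu", ("conv1", c0, c0), "relu"])
    ops.append(("save", "b0"))
    for lvl in range(1, 5):
        p = MaxPool(factors[lvl - 1])
        pools.append(p)
        ops.append(("layer", p))
        cin = c0 if lvl == 1 else c1
        second = ("conv1", c1, c1) if kind == "t1_roi" else ("conv3", c1, c1)
        _conv_block(ops, rng, [("conv3", cin, c1), "relu", second, "relu"])
        ops.append(("save", f"b{lvl}"))
    p = MaxPool(factors[4])
    pools.append(p)
    ops.append(("layer", p))
    _conv_block(ops, rng, [("conv3", c1, c1), "relu", ("conv1", c1, c1), ("in", c1), "relu"])
    for skip in ("b4", "b3", "b2"):
        ops.append(("layer", MaxUnpool(pools.pop())))
        _conv_block(ops, rng, [("conv3", c1, c1), ("in", c1), "relu"])
        ops.append(("sum", skip))
        _conv_block(ops, rng, [("conv3", c1, c1), "relu"])
    ops.append(("layer", MaxUnpool(pools.pop())))
    _conv_block(ops, rng, [("conv3", c1, c1), ("in", c1), "relu"])
    ops.append(("sum", "b1"))
    _conv_block(ops, rng, [("conv3", c1, c0), "relu"])
    ops.append(("layer", MaxUnpool(pools.pop())))
    if kind == "t1_roi":
        _conv_block(ops, rng, [("conv3", c0, c0), "relu"])
    else:
        _conv_block(ops, rng, [("conv3", c0, c0), ("in", c0), "relu"])
    ops.append(("sum", "b0"))
    _conv_block(
        ops, rng, [("conv1", c0, c0), "relu", ("conv3", c0, c8), "relu", ("conv1", c8, out_channels)]
    )
    ops.append(("layer", ChannelSoftmax() if final == "softmax" else Sigmoid()))
    spec = UNetSpec(kind, width_scale, out_channels, final, factors, seed)
    return Model(spec, ops)


def build_t1_roi_net(width_scale: float = 1.0, seed: int = 0) -> Model:
    """Region-of-interest net: four per-voxel label maps summing to 1.

    The final "soft mask" is a per-voxel softmax over the four channels
    (0 = outside WM, 1 = periventricular, 2 = deep, 3 = juxtacortical).
    """
    return _build_12_16_net("t1_roi", width_scale, seed, ((2, 2, 2),) * 5, 4, "softmax")


def build_flair_net(width_scale: float = 1.0, seed: int = 0) -> Model:
    """Native-FLAIR-space net; three sigmoid channels, channel 0 carries the
    lesion mask (the remaining channels are free auxiliary outputs).

    Pooling halves the slice axis only at the first two levels, so slice
    stacks as thin as 8 survive five levels.
    """
    factors = ((2, 2, 2), (2, 2, 2), (2, 2, 1), (2, 2, 1), (2, 2, 1))
    return _build_12_16_net("flair", width_scale, seed, factors, 3, "sigmoid")


_BUILDERS = {
    "t1_wmh": build_t1_wmh_net,
    "t1_roi": build_t1_roi_net,
    "flair": build_flair_net,
}


def build_net(kind: str, width_scale: float = 1.0, seed: int = 0) -> Model:
    try:
        return _BUILDERS[kind](width_scale=width_scale, seed=seed)
    except KeyError:
        raise ValueError(f"unknown net kind {kind!r}") from None


def save_model(model: Model, path) -> None:
    """Serialize spec + weights into a single .npz container."""
    spec = asdict(model.spec)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, spec=json.dumps(spec), **arrays)


def load_model(path) -> Model:
    with np.load(path, allow_pickle=False) as f:
        spec = json.loads(str(f["spec"]))
        model = build_net(spec["kind"], spec["width_scale"], spec["seed"])
        params = model.params()
        for i, p in enumerate(params):
            p.value[...] = f[f"param_{i}"]
    return model
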