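"""Cross-resolution training losses.

The central object is the spatially sparse lesion loss: squared error summed
over FLAIR voxels, each compared against the *single* high-res voxel its
center maps to. High-res voxels that are not the nearest neighbour of any
FLAIR center contribute nothing and receive exactly zero gradient — the
target is never interpolated. A dense trilinear-interpolation baseline is
provided for comparison experiments.

All losses are sums (not means), matching the sigma form of the objective;
``normalize=True`` switches to per-sample means for learning-rate stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import SamplingMap, Volume, resample

__all__ = [
    "LossTerms",
    "RIBBON_WEIGHT",
    "sparse_lesion_loss",
    "sparse_lesion_loss_grad",
    "ribbon_loss",
    "joint_loss",
    "joint_loss_grad",
    "dense_interpolating_loss",
    "dense_interpolating_loss_grad",
]

RIBBON_WEIGHT = 0.001  # weight of the auxiliary cortical-ribbon term


@dataclass(frozen=True)
class LossTerms:
    sparse_lesion: float
    ribbon: float
    total: float
    n_sampled: int


def _check_map(out1: Volume, flair_wmh: Volume, smap: SamplingMap) -> None:
    if smap.n_pairs == 0:
        return
    if np.any(smap.t1_indices >= np.array(out1.grid.shape)) or np.any(
        smap.t1_indices < 0
    ):
        raise ValueError("sampling map indices exceed the T1 volume shape")
    if np.any(smap.flair_indices >= np.array(flair_wmh.grid.shape)):
        raise ValueError("sampling map indices exceed the FLAIR volume shape")


def _gather(vol: Volume, idx: np.ndarray) -> np.ndarray:
    return vol.data[idx[:, 0], idx[:, 1], idx[:, 2]]


def sparse_lesion_loss(out1: Volume, flair_wmh: Volume, smap: SamplingMap) -> float:
    """Sum over sampled pairs of squared (prediction - FLAIR target)."""
    _check_map(out1, flair_wmh, smap)
    if smap.n_pairs == 0:
        return 0.0
    diff = _gather(out1, smap.t1_indices) - _gather(flair_wmh, smap.flair_indices)
    return float(np.sum(diff.astype(np.float64) ** 2))


def sparse_lesion_loss_grad(
    out1: Volume, flair_wmh: Volume, smap: SamplingMap
) -> np.ndarray:
    """d(loss)/d(out1): exactly zero at every unsampled high-res voxel.

    A T1 voxel hit by several FLAIR centers accumulates one term per pair.
    """
    _check_map(out1, flair_wmh, smap)
    g = np.zeros(out1.grid.shape, dtype=np.float64)
    if smap.n_pairs == 0:
        return g
    diff = _gather(out1, smap.t1_indices) - _gather(flair_wmh, smap.flair_indices)
    np.add.at(
        g, (smap.t1_indices[:, 0], smap.t1_indices[:, 1], smap.t1_indices[:, 2]), 2.0 * diff
    )
    return g


def ribbon_loss(out2: Volume, ribbon: Volume) -> float:
    """Dense sum of squared differences over the full high-res grid."""
    if out2.grid.shape != ribbon.grid.shape:
        raise ValueError("ribbon volumes must share a grid shape")
    d = out2.data.astype(np.float64) - ribbon.data.astype(np.float64)
    return float(np.sum(d * d))


def ribbon_loss_grad(out2: Volume, ribbon: Volume) -> np.ndarray:
    return 2.0 * (out2.data.astype(np.float64) - ribbon.data.astype(np.float64))


def joint_loss(
    out1: Volume,
    out2: Volume,
    flair_wmh: Volume,
    ribbon: Volume,
    smap: SamplingMap,
    ribbon_weight: float = RIBBON_WEIGHT,
) -> LossTerms:
    """Weighted sum: sparse lesion term + ``ribbon_weight`` x ribbon term."""
    sl = sparse_lesion_loss(out1, flair_wmh, smap)
    rb = ribbon_loss(out2, ribbon)
    return LossTerms(
        sparse_lesion=sl,
        ribbon=rb,
        total=sl + ribbon_weight * rb,
        n_sampled=smap.n_pairs,
    )


def joint_loss_grad(
    out1: Volume,
    out2: Volume,
    flair_wmh: Volume,
    ribbon: Volume,
    smap: SamplingMap,
    ribbon_weight: float = RIBBON_WEIGHT,
):
    """Gradients of the joint loss w.r.t. both outputs."""
    g1 = sparse_lesion_loss_grad(out1, flair_wmh, smap)
    g2 = ribbon_weight * ribbon_loss_grad(out2, ribbon)
    return g1, g2


def _fov_and_target(out1: Volume, flair_wmh: Volume, rigid):
    target = resample(flair_wmh, out1.grid, transform=rigid, mode="trilinear")
    ones = Volume(np.ones(flair_wmh.grid.shape), flair_wmh.grid)
    fov = resample(ones, out1.grid, transform=rigid, mode="trilinear").data > 0
    return target, fov


def dense_interpolating_loss(out1: Volume, flair_wmh: Volume, rigid) -> float:
    """Baseline: trilinearly interpolate the FLAIR target onto the high-res
    grid and sum squared error densely over the FLAIR field of view."""
    target, fov = _fov_and_target(out1, flair_wmh, rigid)
    d = (out1.data.astype(np.float64) - target.data)[fov]
    return float(np.sum(d * d))


def dense_interpolating_loss_grad(out1: Volume, flair_wmh: Volume, rigid) -> np.ndarray:
    target, fov = _fov_and_target(out1, flair_wmh, rigid)
    g = 2.0 * (out1.data.astype(np.float64) - target.data)
    g[~fov] = 0.0
    return g
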