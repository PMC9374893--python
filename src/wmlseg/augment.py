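"""Training-time augmentations: constrained random rigid transforms, monotone
histogram warping, and simulated lacunes.

Everything here is a pure function of its parameters and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .grids import RigidTransform, Volume

__all__ = ["AugmentParams", "random_affine", "histogram_warp", "scatter_lacunes"]


@dataclass(frozen=True)
class AugmentParams:
    max_rotation_deg: tuple = (10.0, 10.0, 10.0)
    max_translation_mm: float = 5.0
    axial_only: bool = False  # rotate only about the slice axis (axis 2)
    rotation_center_mm: tuple = (0.0, 0.0, 0.0)
    histogram_knots: int = 5
    histogram_strength: float = 0.3
    lacune_count_range: tuple = (0, 0)
    lacune_radius_range_mm: tuple = (1.0, 2.5)
    lacune_intensity_drop: float = 0.8
    lacune_target_level: float = 0.15  # CSF-like T1 intensity
    seed: int = 0

    @property
    def effective_rotation_deg(self) -> tuple:
        r = self.max_rotation_deg
        if np.isscalar(r):
            r = (float(r),) * 3
        if self.axial_only:
            return (0.0, 0.0, float(r[2]))
        return tuple(float(x) for x in r)


def _rot(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(3)
    a, b = [i for i in range(3) if i != axis]
    m[a, a] = c
    m[a, b] = -s
    m[b, a] = s
    m[b, b] = c
    return m


def random_affine(params: AugmentParams, seed: int) -> RigidTransform:
    """Random rigid transform: per-axis rotations uniform within bounds
    (about ``rotation_center_mm``) followed by a uniform random translation.

    With ``axial_only`` the rotation leaves the slice axis fixed. All-zero
    strengths yield the exact identity.
    """
    rng = np.random.default_rng(seed)
    bounds = params.effective_rotation_deg
    angles = [rng.uniform(-b, b) if b > 0 else 0.0 for b in bounds]
    r = _rot(2, np.deg2rad(angles[2])) @ _rot(1, np.deg2rad(angles[1])) @ _rot(
        0, np.deg2rad(angles[0])
    )
    t_max = params.max_translation_mm
    t = rng.uniform(-t_max, t_max, size=3) if t_max > 0 else np.zeros(3)
    center = np.asarray(params.rotation_center_mm, dtype=float)
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = center - r @ center + t
    return RigidTransform(m)


def histogram_warp(vol: Volume, params: AugmentParams, seed: int) -> Volume:
    """Random monotone intensity remapping (a shape-preserved contrast change).

    A strictly increasing piecewise-cubic (PCHIP) curve through randomly
    perturbed knots on the normalized intensity range; rank order of voxel
    intensities is always preserved, and strength 0 is the exact identity.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("histogram_warp requires finite intensities")
    lo, hi = float(data.min()), float(data.max())
    s = params.histogram_strength
    if s == 0 or hi == lo:
        return Volume(data.copy(), vol.grid)
    rng = np.random.default_rng(seed)
    k = max(2, int(params.histogram_knots))
    incr = rng.uniform(max(1.0 - s, 0.05), 1.0 + s, size=k - 1)
    y = np.concatenate([[0.0], np.cumsum(incr)])
    y /= y[-1]
    x = np.linspace(0.0, 1.0, k)
    curve = PchipInterpolator(x, y)
    out = lo + (hi - lo) * curve((data - lo) / (hi - lo))
    return Volume(out, vol.grid)


def scatter_lacunes(vol: Volume, wm_mask: Volume, params: AugmentParams, seed: int):
    """Scatter small dark smooth-edged cavities into the white matter.

    Intensities inside each patch are pulled toward a CSF-like level with a
    smooth profile. Returns ``(augmented Volume, binary lacune mask Volume)``.
    """
    wm = np.asarray(wm_mask.data) > 0.5
    if not wm.any():
        raise ValueError("white-matter mask is empty")
    rng = np.random.default_rng(seed)
    lo, hi = params.lacune_count_range
    count = int(rng.integers(lo, hi + 1))
    data = np.asarray(vol.data, dtype=np.float64).copy()
    mask = np.zeros(vol.grid.shape, dtype=bool)
    if count == 0:
        return Volume(data, vol.grid), Volume(mask.astype(np.float64), vol.grid)
    wm_idx = np.argwhere(wm)
    mm = vol.grid.index_to_mm(np.indices(vol.grid.shape).reshape(3, -1).T).reshape(
        vol.grid.shape + (3,)
    )
    for _ in range(count):
        ci = wm_idx[rng.integers(len(wm_idx))]
        radius = float(rng.uniform(*params.lacune_radius_range_mm))
        center = vol.grid.index_to_mm(ci)
        r = np.linalg.norm(mm - center, axis=-1)
        g = np.exp(-((r / radius) ** 4))
        g[g < 0.01] = 0.0
        a = g * params.lacune_intensity_drop
        data = data * (1 - a) + params.lacune_target_level * a
        mask |= g >= 0.5
    return Volume(data, vol.grid), Volume(mask.astype(np.float64), vol.grid)
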