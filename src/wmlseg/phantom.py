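"""Synthetic paired-resolution phantoms.

Generates a high-resolution "T1-like" anatomy (white matter, cortical ribbon,
ventricle) with known smooth lesion blobs, renders it in two contrasts —
an isotropic T1-like volume where lesions take gray-matter-like intensity,
and a thick-slice FLAIR-like stack where lesions are hyperintense — and
derives the clean thick-slice lesion mask that stands in for an external
FLAIR segmenter's output. Target-corruption modes emulate that segmenter's
typical failures (missed small lesions, bright artifacts, motion).

The default geometry keeps a 6:1 slice-thickness ratio between the two
spaces, which is what makes the cross-resolution loss experiments meaningful
at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid, RigidTransform, Volume

__all__ = [
    "PhantomTruth",
    "AcquisitionSpec",
    "make_phantom",
    "render",
    "lesion_mask_flair",
    "corrupt_target",
    "default_acquisition",
]

LESION_CLASSES = ("periventricular", "deep", "juxtacortical")

# noise-free tissue signal levels per contrast
T1_SIGNAL = {"background": 0.02, "wm": 1.0, "ribbon": 0.62, "ventricle": 0.15}
FLAIR_SIGNAL = {"background": 0.0, "wm": 0.35, "ribbon": 0.40, "ventricle": 0.05}

BG, WM, RIBBON, VENTRICLE = 0, 1, 2, 3


@dataclass
class PhantomTruth:
    tissue_labels: np.ndarray  # int labels, BG/WM/RIBBON/VENTRICLE
    lesion_field: np.ndarray  # [0, 1], > 0 only inside WM
    grid: Grid
    lesion_components: list  # (center_mm, radius_mm, class)

    @property
    def wm_mask(self) -> np.ndarray:
        return self.tissue_labels == WM

    @property
    def ribbon_mask(self) -> np.ndarray:
        return self.tissue_labels == RIBBON

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.tissue_labels == VENTRICLE


@dataclass(frozen=True)
class AcquisitionSpec:
    in_plane_mm: float
    slice_thickness_mm: float
    n_slices: int
    contrast: str  # "t1" | "flair"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.contrast not in ("t1", "flair"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.contrast == "flair" and self.slice_thickness_mm <= self.in_plane_mm:
            raise ValueError("thick-slice contrast requires slice_thickness > in_plane")


def default_acquisition(truth: PhantomTruth, contrast: str, noise_sd: float = 0.0,
                        seed: int = 0, anisotropy: int = 6) -> AcquisitionSpec:
    """6:1-anisotropy FLAIR (or native-grid T1) acquisition for ``truth``."""
    vx = truth.grid.voxel_size
    if contrast == "t1":
        return AcquisitionSpec(vx[0], vx[2], truth.grid.shape[2], "t1", noise_sd, seed)
    thickness = anisotropy * vx[2]
    n_slices = truth.grid.shape[2] // anisotropy
    return AcquisitionSpec(vx[0], thickness, n_slices, "flair", noise_sd, seed)


def _ellipsoid(shape, center, semi_axes):
    idx = np.indices(shape).astype(float)
    q = sum(((idx[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    return q <= 1.0


def make_phantom(
    seed: int,
    shape=(64, 64, 48),
    n_lesions_by_class=(2, 2, 1),
    lesion_radius_range=(2.5, 5.0),
    voxel_size=(1.0, 1.0, 1.0),
    pv_radius_mm: float = 9.0,
    jc_radius_mm: float = 4.0,
    max_tries: int = 300,
) -> PhantomTruth:
    """Deterministic synthetic anatomy with class-placed smooth lesion blobs.

    Lesion classes are validated against the same region partition the ROI
    module computes, so a generated component re-classifies to its nominal
    class by construction.
    """
    from .rois import partition_wm  # local import: rois also imports grids

    shape = tuple(int(s) for s in shape)
    if any(s < m for s, m in zip(shape, (32, 32, 16))):
        raise ValueError(f"phantom shape must be at least (32, 32, 16), got {shape}")
    rng = np.random.default_rng(seed)
    grid = Grid.from_spacing(shape, voxel_size)
    c = np.array(shape) / 2.0 - 0.5

    brain = _ellipsoid(shape, c, np.array(shape) * 0.44)
    interior = ndimage.binary_erosion(brain, iterations=2)
    ribbon = brain & ~interior
    vent = _ellipsoid(shape, c, np.maximum(np.array(shape) * 0.10, 2.0))
    wm = interior & ~vent
    labels = np.zeros(shape, dtype=np.int16)
    labels[wm] = WM
    labels[ribbon] = RIBBON
    labels[vent] = VENTRICLE

    roi = partition_wm(
        Volume(wm.astype(float), grid),
        Volume(vent.astype(float), grid),
        Volume(ribbon.astype(float), grid),
        pv_radius_mm=pv_radius_mm,
        jc_radius_mm=jc_radius_mm,
    )
    class_label = {"periventricular": 1, "deep": 2, "juxtacortical": 3}

    mm = grid.index_to_mm(np.indices(shape).reshape(3, -1).T).reshape(shape + (3,))
    lesion_field = np.zeros(shape, dtype=np.float64)
    components = []
    for cls, count in zip(LESION_CLASSES, n_lesions_by_class):
        want = class_label[cls]
        candidates = np.argwhere(wm & (roi.labels == want))
        for _ in range(int(count)):
            placed = False
            for _try in range(max_tries):
                if len(candidates) == 0:
                    break
                ci = candidates[rng.integers(len(candidates))]
                radius = float(rng.uniform(*lesion_radius_range))
                center_mm = grid.index_to_mm(ci)
                r = np.linalg.norm(mm - center_mm, axis=-1)
                blob = np.exp(-((r / radius) ** 4))
                blob[blob < 0.01] = 0.0
                blob *= wm  # lesions live strictly inside white matter
                core = blob >= 0.5
                if core.sum() < 3:
                    continue
                votes = np.bincount(roi.labels[core], minlength=4)
                if votes.argmax() != want:
                    continue
                lesion_field = np.maximum(lesion_field, blob)
                components.append((tuple(center_mm), radius, cls))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {cls} lesion after {max_tries} tries"
                )
    return PhantomTruth(labels, lesion_field, grid, components)


def _signal(truth: PhantomTruth, contrast: str) -> np.ndarray:
    levels = T1_SIGNAL if contrast == "t1" else FLAIR_SIGNAL
    s = np.full(truth.grid.shape, levels["background"], dtype=np.float64)
    s[truth.wm_mask] = levels["wm"]
    s[truth.ribbon_mask] = levels["ribbon"]
    s[truth.ventricle_mask] = levels["ventricle"]
    f = truth.lesion_field
    if contrast == "t1":
        # lesions sink to gray-matter-like intensity: ambiguous with the ribbon
        s = s * (1 - f) + T1_SIGNAL["ribbon"] * f
    else:
        # hyperintense, strictly above WM and GM
        s = s * (1 - f) + 1.0 * f
    return s


def _slab_geometry(truth: PhantomTruth, spec: AcquisitionSpec):
    vz = truth.grid.voxel_size[2]
    ratio = spec.slice_thickness_mm / vz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            "slice thickness must be an integer multiple of the truth z spacing"
        )
    ratio = int(round(ratio))
    needed = spec.n_slices * ratio
    if needed > truth.grid.shape[2]:
        raise ValueError(
            f"{spec.n_slices} slices of {spec.slice_thickness_mm} mm do not fit "
            f"in the truth extent"
        )
    z0 = (truth.grid.shape[2] - needed) // 2
    return ratio, z0


def _flair_grid(truth: PhantomTruth, spec: AcquisitionSpec, ratio: int, z0: int) -> Grid:
    vx = truth.grid.voxel_size
    if abs(spec.in_plane_mm - vx[0]) > 1e-9:
        raise ValueError("in-plane spacing must match the truth grid in-plane spacing")
    shape = (truth.grid.shape[0], truth.grid.shape[1], spec.n_slices)
    origin_z = truth.grid.affine[2, 3] + (z0 + (ratio - 1) / 2.0) * vx[2]
    origin = (truth.grid.affine[0, 3], truth.grid.affine[1, 3], origin_z)
    return Grid.from_spacing(shape, (vx[0], vx[1], spec.slice_thickness_mm), origin)


def _slab_average(data: np.ndarray, ratio: int, z0: int, n_slices: int) -> np.ndarray:
    sl = data[:, :, z0 : z0 + n_slices * ratio]
    return sl.reshape(sl.shape[0], sl.shape[1], n_slices, ratio).mean(axis=3)


def render(truth: PhantomTruth, spec: AcquisitionSpec):
    """Render the phantom in the requested contrast.

    Returns ``(Volume, RigidTransform)`` — the rendered volume on its own
    grid and the exact rigid transform from that grid's world coordinates to
    the truth grid's (identity here: the grids share a world frame).
    """
    rng = np.random.default_rng(spec.seed)
    signal = _signal(truth, spec.contrast)
    if spec.contrast == "t1":
        data, grid = signal, truth.grid
    else:
        ratio, z0 = _slab_geometry(truth, spec)
        grid = _flair_grid(truth, spec, ratio, z0)
        data = _slab_average(signal, ratio, z0, spec.n_slices)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return Volume(data, grid), RigidTransform.identity()


def lesion_mask_flair(truth: PhantomTruth, spec: AcquisitionSpec) -> Volume:
    """Ground-truth lesion field slab-averaged onto the thick-slice grid and
    thresholded at 0.5 — the clean training target."""
    if spec.contrast != "flair":
        raise ValueError("lesion masks are defined on the thick-slice grid")
    ratio, z0 = _slab_geometry(truth, spec)
    grid = _flair_grid(truth, spec, ratio, z0)
    avg = _slab_average(truth.lesion_field, ratio, z0, spec.n_slices)
    return Volume((avg >= 0.5).astype(np.float64), grid)


def corrupt_target(
    mask: Volume,
    mode: str,
    seed: int,
    min_size: int = 12,
    n_artifacts: int = 3,
    artifact_radius_vox: float = 2.5,
) -> Volume:
    """Deterministically corrupt a binary target mask, emulating segmenter
    failure modes: missed small components, spurious bright components, or
    motion-like slice duplication/shear."""
    data = np.asarray(mask.data)
    if not np.isin(data, (0, 1)).all():
        raise ValueError("corrupt_target expects a binary mask")
    rng = np.random.default_rng(seed)
    out = data.astype(np.float64).copy()
    if mode == "miss_small":
        lab, n = ndimage.label(out > 0)
        if n:
            sizes = np.bincount(lab.ravel())
            kill = np.flatnonzero(sizes < min_size)
            out[np.isin(lab, kill[kill > 0])] = 0.0
    elif mode == "bright_artifact":
        shape = np.array(out.shape)
        added = 0
        for _ in range(200):
            if added >= n_artifacts:
                break
            c = rng.uniform(0, shape - 1)
            idx = np.indices(out.shape).astype(float)
            r = np.sqrt(sum((idx[a] - c[a]) ** 2 for a in range(3)))
            blob = r <= artifact_radius_vox
            if not blob.any() or (blob & (data > 0)).any():
                continue  # artifacts must be spurious, outside true lesions
            out[blob] = 1.0
            added += 1
        if out.sum() <= data.sum():
            raise RuntimeError("failed to place any spurious artifact")
    elif mode == "motion":
        for k in range(out.shape[2]):
            if rng.random() < 0.5:
                dx, dy = rng.integers(-3, 4, size=2)
                shifted = np.roll(np.roll(out[:, :, k], dx, axis=0), dy, axis=1)
                out[:, :, k] = np.maximum(out[:, :, k], shifted)
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return Volume(out, mask.grid)
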