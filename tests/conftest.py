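import numpy as np
import pytest

from wmlseg.grids import Grid, RigidTransform, Volume
from wmlseg.phantom import default_acquisition, make_phantom


# desk-scale phantoms need proportionally smaller ROI radii or the deep-WM
# shell between the periventricular and juxtacortical bands vanishes
SMALL_ROI = dict(pv_radius_mm=6.0, jc_radius_mm=3.0)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic phantom shared across read-only tests."""
    return make_phantom(
        seed=7, shape=(48, 48, 30), n_lesions_by_class=(1, 1, 1), **SMALL_ROI
    )


@pytest.fixture(scope="session")
def flair_spec(small_phantom):
    return default_acquisition(small_phantom, "flair", anisotropy=6)


def random_orthogonal_grid(rng, max_dim=16):
    """Random axis-orthogonal grid: anisotropic spacing, random origin and a
    random rotation (no shear, so per-axis index rounding = nearest center)."""
    shape = tuple(int(s) for s in rng.integers(3, max_dim + 1, size=3))
    spacing = rng.uniform(0.5, 3.0, size=3)
    origin = rng.uniform(-5, 5, size=3)
    theta = rng.uniform(-0.4, 0.4)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    affine = np.eye(4)
    affine[:3, :3] = rot @ np.diag(spacing)
    affine[:3, 3] = origin
    return Grid(shape, affine)


def random_rigid(rng, max_angle=0.3, max_shift=4.0):
    theta = rng.uniform(-max_angle, max_angle)
    c, s = np.cos(theta), np.sin(theta)
    m = np.eye(4)
    m[:3, :3] = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    m[:3, 3] = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(m)


def brute_force_sampling_pairs(flair_grid, t1_grid, rigid, aug=None):
    """Independent oracle: exhaustive nearest-voxel-center search."""
    m = rigid.matrix if isinstance(rigid, RigidTransform) else np.asarray(rigid)
    if aug is not None:
        am = aug.matrix if isinstance(aug, RigidTransform) else np.asarray(aug)
        m = am @ m
    t1_idx = np.indices(t1_grid.shape).reshape(3, -1).T
    t1_centers = t1_grid.index_to_mm(t1_idx)
    pairs, dropped = [], 0
    for fi in np.ndindex(flair_grid.shape):
        c = flair_grid.index_to_mm(np.array(fi))
        w = m[:3, :3] @ c + m[:3, 3]
        # nearest center overall, but only counted if the *rounded* index is
        # inside (mirrors the drop rule)
        cont = t1_grid.mm_to_index(w)
        nearest = np.ceil(cont - 0.5).astype(int)
        if np.any(nearest < 0) or np.any(nearest >= np.array(t1_grid.shape)):
            dropped += 1
            continue
        d2 = np.sum((t1_centers - w) ** 2, axis=1)
        best = t1_idx[np.argmin(d2)]
        pairs.append((tuple(fi), tuple(best)))
    return pairs, dropped


def make_volume(rng, grid):
    return Volume(rng.uniform(0, 1, size=grid.shape), grid)
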