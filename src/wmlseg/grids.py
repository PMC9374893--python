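"""Voxel-grid geometry: index/mm mappings, rigid transforms, sparse sampling maps
and grid-to-grid resampling.

Conventions
-----------
* Indices are 0-based and voxel-center based: the mm coordinate of voxel
  ``(i, j, k)`` is ``affine @ (i, j, k, 1)``, following the NIfTI standard.
* Transform matrices act on homogeneous mm coordinates and map *source* world
  coordinates to *destination* world coordinates (e.g. a FLAIR-to-T1 rigid
  matrix maps points expressed in FLAIR world space into T1 world space).
* Rounding of a continuous index that falls exactly half-way between two
  voxels resolves toward the *lower* index, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "RigidTransform",
    "SamplingMap",
    "Volume",
    "voxel_centers",
    "build_sampling_map",
    "resample",
    "round_half_down",
]

_ORTHO_TOL = 1e-6


def _as_matrix(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
    return m


@dataclass(frozen=True)
class Grid:
    """A 3D voxel grid: shape plus an index->mm affine."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        affine = _as_matrix(self.affine)
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("grid affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_spacing(cls, shape, voxel_size, origin=(0.0, 0.0, 0.0)) -> "Grid":
        """Axis-aligned grid with the given voxel size (mm) and world origin."""
        voxel_size = np.asarray(voxel_size, dtype=float)
        if voxel_size.shape != (3,) or np.any(voxel_size <= 0):
            raise ValueError("voxel_size must be 3 positive reals")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(voxel_size)
        affine[:3, 3] = origin
        return cls(tuple(shape), affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Column norms of the rotation/scaling block (mm per voxel step)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def index_to_mm(self, idx) -> np.ndarray:
        """Map (..., 3) voxel indices to mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_index(self, mm) -> np.ndarray:
        """Map (..., 3) mm coordinates to continuous voxel indices."""
        mm = np.asarray(mm, dtype=float)
        inv = np.linalg.inv(self.affine)
        return mm @ inv[:3, :3].T + inv[:3, 3]

    def __eq__(self, other):
        return (
            isinstance(other, Grid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
        )


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous transform with an orthonormal rotation block."""

    matrix: np.ndarray

    def __post_init__(self):
        matrix = _as_matrix(self.matrix)
        r = matrix[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation block is not orthonormal (RtR != I)")
        if not np.allclose(matrix[3], [0, 0, 0, 1]):
            raise ValueError("last row must be [0, 0, 0, 1]")
        object.__setattr__(self, "matrix", matrix)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    @classmethod
    def from_file(cls, path) -> "RigidTransform":
        return cls(np.loadtxt(path))

    def to_file(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.17g")

    @property
    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return RigidTransform(self.matrix @ _transform_matrix(other))

    def apply(self, mm) -> np.ndarray:
        mm = np.asarray(mm, dtype=float)
        return mm @ self.matrix[:3, :3].T + self.matrix[:3, 3]


def _transform_matrix(t) -> np.ndarray:
    """Accept a RigidTransform or a plain (possibly non-rigid) 4x4 affine."""
    if isinstance(t, RigidTransform):
        return t.matrix
    m = _as_matrix(t)
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise ValueError("transform is not invertible")
    return m


@dataclass(frozen=True)
class SamplingMap:
    """Pairs of (FLAIR voxel index, nearest T1 voxel index) realizing the
    sparse cross-resolution supervision, plus the out-of-bounds drop count."""

    flair_indices: np.ndarray  # (n, 3) int
    t1_indices: np.ndarray  # (n, 3) int
    n_dropped: int

    @property
    def pairs(self):
        return list(zip(map(tuple, self.flair_indices), map(tuple, self.t1_indices)))

    @property
    def n_pairs(self) -> int:
        return int(len(self.flair_indices))


@dataclass
class Volume:
    """A 3D data array bound to its Grid."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.grid)


def voxel_centers(grid: Grid) -> np.ndarray:
    """mm coordinates of every voxel center, shaped (n_voxels, 3), in C order."""
    idx = np.indices(grid.shape).reshape(3, -1).T
    return grid.index_to_mm(idx)


def round_half_down(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer; exact halves resolve to the lower integer."""
    return np.ceil(np.asarray(x) - 0.5).astype(int)


def build_sampling_map(flair_grid: Grid, t1_grid: Grid, rigid, aug=None) -> SamplingMap:
    """Map each FLAIR voxel center through ``aug . rigid`` into the T1 grid and
    keep the nearest T1 voxel; centers landing outside the grid are dropped.

    ``rigid`` is the FLAIR->T1 world transform; ``aug`` (optional) is a further
    augmentation transform applied in T1 world space. T1 voxels that are never
    the nearest neighbour of any FLAIR center are simply absent from the map.
    """
    m = _transform_matrix(rigid)
    if aug is not None:
        m = _transform_matrix(aug) @ m
    centers = voxel_centers(flair_grid)
    world = centers @ m[:3, :3].T + m[:3, 3]
    cont = t1_grid.mm_to_index(world)
    nearest = round_half_down(cont)
    inside = np.all((nearest >= 0) & (nearest < np.array(t1_grid.shape)), axis=1)
    flair_idx = np.indices(flair_grid.shape).reshape(3, -1).T
    return SamplingMap(
        flair_indices=flair_idx[inside],
        t1_indices=nearest[inside],
        n_dropped=int((~inside).sum()),
    )


def resample(vol: Volume, dst: Grid, transform=None, mode: str = "trilinear") -> Volume:
    """Resample ``vol`` onto the ``dst`` grid.

    ``transform`` maps vol's world coordinates into dst's world coordinates
    (source -> destination, e.g. FLAIR->T1 when pushing FLAIR data onto a T1
    grid); identity if None. Voxels outside the source field of view are 0.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown resampling mode: {mode!r}")
    m = np.eye(4) if transform is None else _transform_matrix(transform)
    # dst index -> dst world -> src world -> src index, as one matrix
    full = np.linalg.inv(vol.grid.affine) @ np.linalg.inv(m) @ dst.affine
    idx = np.indices(dst.shape).reshape(3, -1)
    src = full[:3, :3] @ idx + full[:3, 3:4]
    order = 0 if mode == "nearest" else 1
    # grid-constant (not constant): points an epsilon outside the boundary
    # still interpolate against the edge voxel instead of snapping to cval
    out = ndimage.map_coordinates(
        vol.data.astype(float), src, order=order, mode="grid-constant", cval=0.0
    )
    return Volume(out.reshape(dst.shape), dst)
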