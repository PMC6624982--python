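"""Voxel grids and binary structure masks.

Axis convention (fixed throughout the package):

* axis 0 — left–right (LR), +x toward the patient's left
* axis 1 — anterior–posterior (AP), +y anterior
* axis 2 — inferior–superior (SI), +z superior

All physical quantities are millimetres; volumes are reported in cm^3.
Voxel ``(i, j, k)`` has its *centre* at ``origin + index * spacing``
(half-open voxel indexing, voxel-centre coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["VoxelGrid", "Mask", "default_grid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice in patient coordinates (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def indices_to_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_indices(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of physical points."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_mm(self, pts: np.ndarray) -> np.ndarray:
        idx = self.mm_to_indices(pts)
        lo = idx >= -0.5
        hi = idx <= np.asarray(self.shape) - 0.5
        return np.all(lo & hi, axis=-1)


def default_grid() -> VoxelGrid:
    """2.5 mm isotropic grid over a 40 cm pelvic cube centred on the cervix."""
    n = 160
    sp = 2.5
    half = (n - 1) / 2.0 * sp
    return VoxelGrid((n, n, n), (sp, sp, sp), (-half, -half, -half))


@dataclass
class Mask:
    """Binary occupancy of one delineated structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls, grid: VoxelGrid) -> "Mask":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    @classmethod
    def from_points_mm(cls, grid: VoxelGrid, pts: np.ndarray) -> "Mask":
        """Mark every voxel containing one of the given physical points."""
        idx = np.rint(grid.mm_to_indices(pts)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        data = np.zeros(grid.shape, dtype=bool)
        data[tuple(idx[ok].T)] = True
        return cls(grid, data)

    # -- basic measures ----------------------------------------------------
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_cm3(self) -> float:
        """Structure volume: voxel count x voxel volume / 1000."""
        return self.voxel_count() * self.grid.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty():
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.data)
        return self.grid.indices_to_mm(idx.mean(axis=0))

    def bounding_slices(self, pad_voxels: int = 0):
        """Tight bounding box as slices, optionally padded (clipped to grid)."""
        objs = ndimage.find_objects(self.data.astype(np.int8))
        if not objs or objs[0] is None:
            raise ValueError("bounding box of an empty mask is undefined")
        out = []
        for ax, sl in enumerate(objs[0]):
            lo = max(0, sl.start - pad_voxels)
            hi = min(self.grid.shape[ax], sl.stop + pad_voxels)
            out.append(slice(lo, hi))
        return tuple(out)

    # -- set algebra -------------------------------------------------------
    def _check(self, other: "Mask") -> None:
        if other.grid != self.grid:
            raise ValueError("masks are defined on different grids")

    def union(self, other: "Mask") -> "Mask":
        self._check(other)
        return Mask(self.grid, self.data | other.data)

    def intersect(self, other: "Mask") -> "Mask":
        self._check(other)
        return Mask(self.grid, self.data & other.data)

    def subtract(self, other: "Mask") -> "Mask":
        self._check(other)
        return Mask(self.grid, self.data & ~other.data)

    def contains(self, other: "Mask") -> bool:
        self._check(other)
        return not bool((other.data & ~self.data).any())

    def __or__(self, other: "Mask") -> "Mask":
        return self.union(other)

    def __and__(self, other: "Mask") -> "Mask":
        return self.intersect(other)

    def __sub__(self, other: "Mask") -> "Mask":
        return self.subtract(other)

    # -- surface -----------------------------------------------------------
    def boundary(self) -> np.ndarray:
        """Boolean array of surface voxels (mask minus its 6-conn erosion)."""
        er = ndimage.binary_erosion(self.data, structure=ndimage.generate_binary_structure(3, 1))
        return self.data & ~er

    def surface_points_mm(self) -> np.ndarray:
        """Centres of the surface voxels, (N, 3) mm."""
        idx = np.argwhere(self.boundary())
        return self.grid.indices_to_mm(idx)


def boolean(a: Mask, b: Mask, op: str) -> Mask:
    """Set operation on two masks sharing a grid: union | subtract | intersect."""
    if op == "union":
        return a.union(b)
    if op == "subtract":
        return a.subtract(b)
    if op == "intersect":
        return a.intersect(b)
    raise ValueError(f"unknown boolean op {op!r}")


def volume(mask: Mask) -> float:
    """Volume of a mask in cm^3."""
    return mask.volume_cm3()


def rotate_rigid(mask: Mask, angle_deg: float, axis: int, center_mm) -> Mask:
    """Rigidly rotate a mask about ``center_mm`` around a grid axis.

    Nearest-neighbour resampling; used for setup-rotation handling of
    bony structures.  ``axis`` is the rotation axis (0 = LR, 1 = AP, 2 = SI).
    """
    if angle_deg == 0.0:
        return Mask(mask.grid, mask.data.copy())
    g = mask.grid
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    rot = np.eye(3)
    other = [ax for ax in range(3) if ax != axis]
    rot[other[0], other[0]] = c
    rot[other[0], other[1]] = -s
    rot[other[1], other[0]] = s
    rot[other[1], other[1]] = c
    sp = np.diag(g.spacing)
    sp_inv = np.diag(1.0 / np.asarray(g.spacing))
    # backward map in index space: i_src = M @ i_dst + off
    m = sp_inv @ rot.T @ sp
    ctr_idx = g.mm_to_indices(np.asarray(center_mm, dtype=float))
    off = ctr_idx - m @ ctr_idx
    out = ndimage.affine_transform(
        mask.data.astype(np.uint8), m, offset=off, order=0, mode="constant", cval=0
    )
    return Mask(g, out.astype(bool))
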