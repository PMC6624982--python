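"""Margin expansion, surface interpolation and distance measures.

Margins follow the standard radiotherapy reading of direction-dependent
expansions: the structuring element is the union of the 8 octants of
axis-aligned ellipsoids, each octant taking its semi-axes from the margins
of its sign combination (the +AP octant uses the anterior margin, the -AP
octant the posterior one, and so on).  For an isotropic specification this
reduces to a digital ball; when the two margins of every axis pair agree it
reduces to a single ellipsoid, which is computed exactly with a scaled
Euclidean distance transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal
from scipy.spatial import cKDTree

from .grid import Mask, VoxelGrid

__all__ = [
    "MarginSpec",
    "DeformationField",
    "expand",
    "interpolate_structure",
    "min_interpolation_count",
    "max_surface_distance",
]


@dataclass(frozen=True)
class MarginSpec:
    """Per-direction margins in mm (order: LR pair, AP pair, SI pair).

    ``zero_margin_si_plane``: optional SI coordinate (mm); source voxels with
    centre strictly inferior to the plane contribute no expansion (they are
    kept as-is).  Used for the "0 mm inferior to the vaginal part" ITV rule.
    """

    left: float = 0.0
    right: float = 0.0
    anterior: float = 0.0
    posterior: float = 0.0
    inferior: float = 0.0
    superior: float = 0.0
    zero_margin_si_plane: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("left", "right", "anterior", "posterior", "inferior", "superior"):
            if getattr(self, name) < 0:
                raise ValueError(f"margin {name} must be >= 0")

    @classmethod
    def isotropic(cls, margin: float, zero_margin_si_plane: Optional[float] = None) -> "MarginSpec":
        return cls(margin, margin, margin, margin, margin, margin, zero_margin_si_plane)

    @property
    def as_array(self) -> np.ndarray:
        """(3, 2) array: per axis the margins in the -/+ directions.

        Axis 0: -x = right, +x = left; axis 1: -y = posterior, +y = anterior;
        axis 2: -z = inferior, +z = superior.
        """
        return np.array(
            [
                [self.right, self.left],
                [self.posterior, self.anterior],
                [self.inferior, self.superior],
            ]
        )

    @property
    def is_axis_symmetric(self) -> bool:
        m = self.as_array
        return bool(np.all(m[:, 0] == m[:, 1]))

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.as_array == 0))


def _octant_footprint(spec: MarginSpec, spacing: Sequence[float]) -> np.ndarray:
    """Binary structuring element for the octant-ellipsoid margin semantics."""
    m = spec.as_array  # (3, 2) margins, [-, +] per axis
    spacing = np.asarray(spacing, dtype=float)
    half = np.ceil(m.max(axis=1) / spacing).astype(int)  # symmetric half-extent
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    d = np.stack([dx, dy, dz], axis=-1)
    # per-component semi-axis depends on the sign of the component
    semi = np.where(d >= 0, m[:, 1], m[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(semi > 0, d / semi, np.where(d == 0, 0.0, np.inf))
    return (q**2).sum(axis=-1) <= 1.0 + 1e-12


def _ellipsoid_dilate(data: np.ndarray, semi_axes: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Exact dilation by an axis-aligned ellipsoid via a scaled EDT."""
    if not data.any():
        return data.copy()
    semi = np.maximum(np.asarray(semi_axes, dtype=float), 1e-9)
    sampling = np.asarray(spacing, dtype=float) / semi
    dist = ndimage.distance_transform_edt(~data, sampling=sampling)
    return dist <= 1.0 + 1e-9


def expand(mask: Mask, spec: MarginSpec) -> Mask:
    """Minkowski dilation of a mask with the anisotropic margin element.

    Extensive (result contains the input) and monotone in the margins.
    Voxels inferior to ``zero_margin_si_plane`` seed no expansion.
    """
    if mask.is_empty():
        raise ValueError("cannot expand an empty mask")
    g = mask.grid
    nonzero = [v for v in spec.as_array.ravel() if v > 0]
    if nonzero and min(nonzero) < min(g.spacing) / 2:
        warnings.warn(
            "margin smaller than half the voxel spacing is quantized away",
            stacklevel=2,
        )
    seeds = mask.data
    if spec.zero_margin_si_plane is not None:
        z = g.axis_coords(2)
        keep = z >= spec.zero_margin_si_plane
        seeds = mask.data & keep[None, None, :]
    if spec.is_zero or not seeds.any():
        return Mask(g, mask.data.copy())
    # crop to a padded bounding box for speed
    m = spec.as_array
    pad = tuple(int(np.ceil(m[ax].max() / g.spacing[ax])) + 1 for ax in range(3))
    sl = Mask(g, seeds).bounding_slices(pad_voxels=max(pad))
    sub = seeds[sl]
    if spec.is_axis_symmetric:
        dil = _ellipsoid_dilate(sub, m[:, 0], g.spacing)
    else:
        fp = _octant_footprint(spec, g.spacing)
        conv = signal.fftconvolve(sub.astype(np.float32), fp.astype(np.float32), mode="same")
        dil = conv > 0.5
    out = mask.data.copy()
    out[sl] |= dil
    return Mask(g, out)


@dataclass
class DeformationField:
    """Surface correspondence between two anatomical states.

    ``vertices``: (N, 3) mm positions sampling the source (full-bladder)
    surface; ``displacements``: (N, 3) mm vectors to the corresponding
    target (empty-bladder) surface points.  ``faces`` (optional, (M, 3)
    vertex indices) allow normal estimation for voxelization.
    """

    vertices: np.ndarray
    displacements: np.ndarray
    faces: Optional[np.ndarray] = None
    source_label: str = "full"
    target_label: str = "empty"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.vertices.shape != self.displacements.shape:
            raise ValueError("vertices and displacements must have the same shape")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement vectors must be finite")

    def moved_vertices(self, alpha: float) -> np.ndarray:
        """Source vertices displaced by the fraction ``alpha`` of the field."""
        return self.vertices + alpha * self.displacements

    @property
    def max_displacement(self) -> float:
        if len(self.vertices) == 0:
            return 0.0
        return float(np.linalg.norm(self.displacements, axis=1).max())

    def vertex_normals(self, alpha: float) -> np.ndarray:
        """Outward unit normals of the moved surface, averaged from faces."""
        if self.faces is None:
            raise ValueError("field has no face connectivity; cannot compute normals")
        v = self.moved_vertices(alpha)
        f = self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        n = np.zeros_like(v)
        for c in range(3):
            np.add.at(n, f[:, c], fn)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm


def interpolate_structure(
    field: DeformationField,
    alpha: float,
    grid: VoxelGrid,
) -> Mask:
    """Voxelize the surface obtained by scaling the deformation by ``alpha``.

    Every surface vertex v moves to v + alpha * d(v); the moved closed surface
    is rasterized with a point-in-surface test on voxel centres (signed test
    against the nearest moved vertex and its outward normal, ties toward
    inclusion), then hole-filled.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    verts = field.moved_vertices(alpha)
    normals = field.vertex_normals(alpha)
    sp = np.asarray(grid.spacing)
    lo = grid.mm_to_indices(verts.min(axis=0)) - 2
    hi = grid.mm_to_indices(verts.max(axis=0)) + 3
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int), np.asarray(grid.shape))
    if np.any(hi <= lo):
        return Mask.empty(grid)
    axes = [grid.axis_coords(ax)[lo[ax]:hi[ax]] for ax in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    tree = cKDTree(verts)
    _, nearest = tree.query(pts, workers=-1)
    signed = np.einsum("ij,ij->i", pts - verts[nearest], normals[nearest])
    inside = signed <= 0.5 * float(sp.min()) * 1e-6 + 0.0  # ties toward inclusion
    sub = inside.reshape(tuple(hi - lo))
    sub = ndimage.binary_fill_holes(sub)
    data = np.zeros(grid.shape, dtype=bool)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return Mask(grid, data)


def min_interpolation_count(field: DeformationField, max_gap: float = 10.0) -> int:
    """Least number of intermediate shapes keeping consecutive gaps <= max_gap.

    With k equally spaced interpolation fractions strictly between 0 and 1
    (endpoints included in the gap check), linear scaling makes consecutive
    corresponding vertices ``maxdisp / (k + 1)`` apart; the least admissible k
    is returned.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    maxdisp = field.max_displacement
    k = 0
    while maxdisp / (k + 1) > max_gap:
        k += 1
    return k


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, Mask):
        return obj.surface_points_mm()
    return np.asarray(obj, dtype=float)


def max_surface_distance(a, b, mode: str = "hausdorff") -> float:
    """Maximum surface distance in mm between two structures.

    ``correspondence``: both arguments must be equal-length vertex arrays in
    corresponding order; returns the largest paired Euclidean distance.
    ``hausdorff``: symmetric Hausdorff distance between the surfaces (masks
    contribute their surface voxel centres).
    """
    if mode == "correspondence":
        if isinstance(a, Mask) or isinstance(b, Mask):
            raise ValueError("correspondence mode requires paired vertex arrays")
        pa, pb = np.asarray(a, float), np.asarray(b, float)
        if pa.shape != pb.shape:
            raise ValueError("correspondence mode requires equal-length vertex arrays")
        if len(pa) == 0:
            raise ValueError("empty vertex arrays")
        return float(np.linalg.norm(pa - pb, axis=1).max())
    if mode == "hausdorff":
        pa, pb = _as_points(a), _as_points(b)
        if len(pa) == 0 or len(pb) == 0:
            raise ValueError("cannot measure distance to an empty structure")
        d_ab = cKDTree(pb).query(pa, workers=-1)[0].max()
        d_ba = cKDTree(pa).query(pb, workers=-1)[0].max()
        return float(max(d_ab, d_ba))
    raise ValueError(f"unknown mode {mode!r}")
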