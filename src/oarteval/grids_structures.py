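"""Geometric kernel: binary structure masks on regular voxel lattices.

Everything downstream (margins, contour agreement, dose scoring) reduces to
set operations on :class:`StructureMask` objects that share one
:class:`VoxelGrid`.  The anatomical axis convention is declared once, here:

* axis 0 runs right -> left  (+i = patient left)
* axis 1 runs posterior -> anterior (+j = anterior)
* axis 2 runs inferior -> superior (+k = superior)

All "direction" logic (per-direction margins, protrusion assignment) refers
to these six cardinal directions.  Voxels are node-centered: the physical
position of index ``(i, j, k)`` is ``origin + index * spacing`` (mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AXIS_LABELS",
    "DIRECTION_ORDER",
    "DIRECTIONS",
    "VoxelGrid",
    "StructureMask",
    "DoseGrid",
    "GridMismatchError",
    "volume_cc",
    "expand",
    "center_of_mass",
    "encompasses",
    "surface_voxels",
    "signed_distance_mm",
    "digitize_ellipsoid",
    "digitize_sphere",
]

#: anatomical meaning of the positive grid axes
AXIS_LABELS = ("left", "anterior", "superior")

#: deterministic tie-break order used when assigning displacements to a
#: cardinal direction
DIRECTION_ORDER = ("left", "right", "anterior", "posterior", "superior", "inferior")

#: direction name -> (grid axis, sign of the positive displacement)
DIRECTIONS = {
    "left": (0, +1),
    "right": (0, -1),
    "anterior": (1, +1),
    "posterior": (1, -1),
    "superior": (2, +1),
    "inferior": (2, -1),
}

#: absolute tolerance (mm) within which two grids count as the same lattice
GRID_TOL_MM = 1e-3

# closed-ball comparisons on float distances need a hair of slack so that a
# margin exactly equal to a representable distance includes that voxel
_DIST_EPS = 1e-9


class GridMismatchError(ValueError):
    """Raised when an operation requires two volumes on one lattice."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D lattice with physical spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid must be three dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (spacing is in mm)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def same_as(self, other: "VoxelGrid", tol_mm: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of the voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def index_to_mm(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def points_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical positions of an (n, 3) array of voxel indices."""
        return np.asarray(self.origin) + np.asarray(indices) * np.asarray(self.spacing)


def _require_same_grid(a, b):
    if not a.grid.same_as(b.grid):
        raise GridMismatchError(
            f"volumes are on different grids: {a.grid} vs {b.grid}"
        )


@dataclass
class StructureMask:
    """Binary occupancy field for one delineated structure."""

    grid: VoxelGrid
    occupancy: np.ndarray
    label: str = ""

    def __post_init__(self):
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid {self.grid.shape}"
            )
        if occ.dtype != bool:
            vals = np.unique(occ)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(
                    f"mask '{self.label}' contains non-binary values {vals[:5]}"
                )
            occ = occ.astype(bool)
        self.occupancy = occ

    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    # -- set algebra (grid-checked) -------------------------------------
    def union(self, other: "StructureMask", label: str | None = None) -> "StructureMask":
        _require_same_grid(self, other)
        return StructureMask(self.grid, self.occupancy | other.occupancy,
                             label if label is not None else self.label)

    def intersection(self, other: "StructureMask", label: str | None = None) -> "StructureMask":
        _require_same_grid(self, other)
        return StructureMask(self.grid, self.occupancy & other.occupancy,
                             label if label is not None else self.label)

    def difference(self, other: "StructureMask", label: str | None = None) -> "StructureMask":
        _require_same_grid(self, other)
        return StructureMask(self.grid, self.occupancy & ~other.occupancy,
                             label if label is not None else self.label)

    def contains(self, other: "StructureMask") -> bool:
        _require_same_grid(self, other)
        return bool(np.all(self.occupancy | ~other.occupancy))

    def with_label(self, label: str) -> "StructureMask":
        return StructureMask(self.grid, self.occupancy, label)


@dataclass
class DoseGrid:
    """Scalar absorbed-dose field in Gy, co-registered with the masks."""

    grid: VoxelGrid
    dose_Gy: np.ndarray

    def __post_init__(self):
        dose = np.asarray(self.dose_Gy, dtype=float)
        if dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {dose.shape} does not match grid {self.grid.shape}"
            )
        if np.any(dose < 0):
            raise ValueError(f"dose contains negative values (min {dose.min():.3g} Gy)")
        self.dose_Gy = dose

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.grid, self.dose_Gy * float(factor))


# ---------------------------------------------------------------------------
# mask-level operations


def volume_cc(mask: StructureMask) -> float:
    """Occupied-voxel count times voxel volume, in cm^3."""
    return mask.voxel_count * mask.grid.voxel_volume_cc


def center_of_mass(mask: StructureMask) -> np.ndarray:
    """Occupancy-weighted mean physical position (mm)."""
    if mask.is_empty():
        raise ValueError(f"center of mass of empty mask '{mask.label}'")
    idx = ndimage.center_of_mass(mask.occupancy)
    return mask.grid.index_to_mm(idx)


def encompasses(outer: StructureMask, inner: StructureMask) -> tuple[bool, float]:
    """Whether ``inner`` lies within ``outer`` plus the protruding volume (cc)."""
    _require_same_grid(outer, inner)
    protruding = inner.occupancy & ~outer.occupancy
    n = int(protruding.sum())
    return n == 0, n * outer.grid.voxel_volume_cc


def surface_voxels(mask: StructureMask) -> np.ndarray:
    """Indices (n, 3) of occupied voxels with at least one unoccupied 6-neighbor."""
    occ = mask.occupancy
    eroded = ndimage.binary_erosion(
        occ, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(occ & ~eroded)


def signed_distance_mm(mask: StructureMask) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, positive inside (mm)."""
    occ = mask.occupancy
    spacing = mask.grid.spacing
    outside = ndimage.distance_transform_edt(~occ, sampling=spacing)
    inside = ndimage.distance_transform_edt(occ, sampling=spacing)
    return inside - outside


def _crop_slices(occ: np.ndarray, pad_vox: tuple[int, int, int], shape):
    """Bounding box of the occupied region padded per axis, as slices."""
    idx = np.argwhere(occ)
    lo = np.maximum(idx.min(axis=0) - pad_vox, 0)
    hi = np.minimum(idx.max(axis=0) + pad_vox + 1, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _margin_tuple(margin) -> tuple[float, ...]:
    """Normalize a margin spec to the six-tuple (L, R, A, P, S, I) in mm."""
    if np.isscalar(margin):
        return (float(margin),) * 6
    if hasattr(margin, "as_tuple"):
        margin = margin.as_tuple()
    t = tuple(float(m) for m in margin)
    if len(t) != 6:
        raise ValueError("directional margin needs six components (L,R,A,P,S,I)")
    return t


def expand(mask: StructureMask, margin, label: str | None = None) -> StructureMask:
    """Morphological expansion of a mask by a physical margin.

    ``margin`` is either one isotropic length in mm (Euclidean closed-ball
    expansion via a distance transform, correct for anisotropic spacing) or
    six per-cardinal-direction lengths ordered (left, right, anterior,
    posterior, superior, inferior).  In the directional case a voxel is added
    when the displacement from its nearest occupied voxel, with each
    component measured against the margin of the corresponding cardinal
    direction, lies inside the unit ball — i.e. an ellipsoidal margin with
    possibly different semi-axes per half-axis.  This reduces exactly to the
    Euclidean case when all six margins are equal, and is monotone in every
    component.
    """
    margins = _margin_tuple(margin)
    if any(m < 0 for m in margins):
        raise ValueError(f"margins must be non-negative, got {margins}")
    new_label = label if label is not None else mask.label
    if mask.is_empty() or all(m == 0 for m in margins):
        return StructureMask(mask.grid, mask.occupancy.copy(), new_label)

    occ = mask.occupancy
    spacing = np.asarray(mask.grid.spacing)
    pad = tuple(int(np.ceil(max(margins) / s)) + 1 for s in spacing)
    sl = _crop_slices(occ, pad, mask.grid.shape)
    sub = occ[sl]

    isotropic = len(set(margins)) == 1
    if isotropic:
        dist = ndimage.distance_transform_edt(~sub, sampling=mask.grid.spacing)
        grown = sub | (dist <= margins[0] + _DIST_EPS)
    else:
        dist, nearest = ndimage.distance_transform_edt(
            ~sub, sampling=mask.grid.spacing, return_indices=True
        )
        own = np.indices(sub.shape)
        r2 = np.zeros(sub.shape)
        reachable = np.ones(sub.shape, dtype=bool)
        for axis in range(3):
            disp = (own[axis] - nearest[axis]) * spacing[axis]
            pos_m, neg_m = margins[2 * axis], margins[2 * axis + 1]
            m = np.where(disp >= 0, pos_m, neg_m)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(disp == 0, 0.0, (disp / m) ** 2)
            blocked = (m == 0) & (disp != 0)
            reachable &= ~blocked
            r2 += np.where(blocked, 0.0, term)
        grown = sub | (reachable & (r2 <= 1.0 + _DIST_EPS))

    out = np.zeros_like(occ)
    out[sl] = grown
    out |= occ
    return StructureMask(mask.grid, out, new_label)


# ---------------------------------------------------------------------------
# analytic digitization helpers (phantom primitives and test oracles)


def digitize_ellipsoid(grid: VoxelGrid, center_mm, semi_axes_mm, label: str = "") -> StructureMask:
    """Digitize an axis-aligned ellipsoid: voxel centers with
    sum(((x - c) / a)^2) <= 1."""
    cx = np.asarray(center_mm, dtype=float)
    ax = np.asarray(semi_axes_mm, dtype=float)
    if np.any(ax <= 0):
        raise ValueError("semi-axes must be positive")
    xs, ys, zs = grid.coordinate_axes()
    u = ((xs - cx[0]) / ax[0]) ** 2
    v = ((ys - cx[1]) / ax[1]) ** 2
    w = ((zs - cx[2]) / ax[2]) ** 2
    occ = u[:, None, None] + v[None, :, None] + w[None, None, :] <= 1.0 + _DIST_EPS
    return StructureMask(grid, occ, label)


def digitize_sphere(grid: VoxelGrid, center_mm, radius_mm: float, label: str = "") -> StructureMask:
    return digitize_ellipsoid(grid, center_mm, (radius_mm,) * 3, label)
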