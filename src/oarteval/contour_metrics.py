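"""Geometric agreement scores between two delineations.

Dice similarity coefficient, Hausdorff distance and center-of-mass distance
are the standard trio for comparing an automatically propagated contour with
its manually corrected counterpart.  All metrics operate on voxel masks that
share one grid; multiple disconnected components (e.g. several fiducial
marker dots) are treated as one point set per side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grids_structures import (
    StructureMask,
    _require_same_grid,
    center_of_mass,
    surface_voxels,
    volume_cc,
)

__all__ = ["ContourComparison", "dice", "hausdorff", "com_distance", "compare"]


@dataclass(frozen=True)
class ContourComparison:
    """Agreement summary for a pair of structures (A vs B)."""

    dsc: float
    hausdorff_mm: float
    volume_diff_cc: float  # volume(A) - volume(B), signed
    com_distance_mm: float


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) on voxel counts."""
    _require_same_grid(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks empty")
    inter = int((a.occupancy & b.occupancy).sum())
    return 2.0 * inter / (na + nb)


def _surface_points_mm(mask: StructureMask) -> np.ndarray:
    return mask.grid.points_mm(surface_voxels(mask))


def hausdorff(a: StructureMask, b: StructureMask, percentile: float = 100.0) -> float:
    """Hausdorff distance between the surfaces of two masks, in mm.

    The default is the classical maximum (symmetrised) Hausdorff distance;
    ``percentile`` < 100 gives the percentile variant (e.g. HD95).  Surfaces
    and full voxel sets give the same maximum for closed voxel sets; surfaces
    are used for speed.
    """
    _require_same_grid(a, b)
    if a.is_empty() or b.is_empty():
        raise ValueError("Hausdorff distance undefined for empty masks")
    pa, pb = _surface_points_mm(a), _surface_points_mm(b)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def com_distance(a: StructureMask, b: StructureMask) -> float:
    """Euclidean distance between the centers of mass, in mm."""
    if a.is_empty() or b.is_empty():
        raise ValueError("center-of-mass distance undefined for empty masks")
    return float(np.linalg.norm(center_of_mass(a) - center_of_mass(b)))


def compare(a: StructureMask, b: StructureMask) -> ContourComparison:
    """Full agreement summary (DSC, HD, signed volume diff, ΔCoM)."""
    return ContourComparison(
        dsc=dice(a, b),
        hausdorff_mm=hausdorff(a, b),
        volume_diff_cc=volume_cc(a) - volume_cc(b),
        com_distance_mm=com_distance(a, b),
    )
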