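"""Patient-specific elective margins and target-volume construction.

The planning protocol acquires two planning CTs ~15 min apart to estimate
intrafraction bladder filling.  The first-CT bladder is expanded 5 mm in all
directions; if the second-CT bladder is fully encompassed, a uniform 7 mm
elective PTV margin is used.  Otherwise, in each cardinal direction where the
5 mm expansion fails, the expansion necessary to encompass the bladder is
determined and increased by 50% (the on-couch time of an adaptive session
exceeds the 15 min inter-scan interval); directions that pass keep 7 mm.

Target construction: GTV -> CTV_SIB -> PTV_SIB with two 5 mm isotropic
margins; the elective CTV is the union of bladder, pelvic lymph nodes and
urethra, and the elective PTV applies the patient-specific margins to the
bladder and a 5 mm (configurable 5-7 mm) margin to nodes and urethra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids_structures import (
    DIRECTION_ORDER,
    DIRECTIONS,
    StructureMask,
    _require_same_grid,
    expand,
)

__all__ = [
    "DirectionalMargins",
    "TargetSet",
    "necessary_expansion",
    "patient_specific_margin",
    "margin_report",
    "build_targets",
    "UNIFORM_FALLBACK_MM",
    "ENVELOPE_MM",
    "SAFETY_FACTOR",
    "SIB_MARGIN_MM",
]

#: uniform elective PTV margin when the 5 mm envelope encompasses the bladder
UNIFORM_FALLBACK_MM = 7.0
#: the test envelope: isotropic expansion of the first-CT bladder
ENVELOPE_MM = 5.0
#: safety factor applied to the necessary expansion in violated directions
SAFETY_FACTOR = 1.5
#: GTV->CTV_SIB and CTV_SIB->PTV_SIB margin
SIB_MARGIN_MM = 5.0


@dataclass(frozen=True)
class DirectionalMargins:
    """Six per-cardinal-direction margins in mm (patient coordinate axes)."""

    left: float
    right: float
    anterior: float
    posterior: float
    superior: float
    inferior: float

    def __post_init__(self):
        if any(m < 0 for m in self.as_tuple()):
            raise ValueError(f"margins must be non-negative: {self}")

    @classmethod
    def uniform(cls, margin_mm: float) -> "DirectionalMargins":
        return cls(*([float(margin_mm)] * 6))

    def as_tuple(self) -> tuple[float, ...]:
        return (self.left, self.right, self.anterior, self.posterior,
                self.superior, self.inferior)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DIRECTION_ORDER, self.as_tuple()))

    @property
    def is_uniform(self) -> bool:
        t = self.as_tuple()
        return all(m == t[0] for m in t)


@dataclass
class TargetSet:
    """All target volumes of one plan, nested by construction."""

    gtv: StructureMask
    ctv_sib: StructureMask
    ptv_sib: StructureMask
    ctv_elective: StructureMask
    ptv_elective: StructureMask

    def validate_nesting(self) -> None:
        if not self.ctv_sib.contains(self.gtv):
            raise ValueError("GTV not contained in CTV_SIB")
        if not self.ptv_sib.contains(self.ctv_sib):
            raise ValueError("CTV_SIB not contained in PTV_SIB")
        if not self.ptv_elective.contains(self.ctv_elective):
            raise ValueError("CTV_elective not contained in PTV_elective")


def necessary_expansion(bladder_ct1: StructureMask,
                        bladder_ct2: StructureMask) -> DirectionalMargins:
    """Per-direction expansion of the CT1 bladder needed to cover the CT2 one.

    Each CT2 voxel outside the CT1 bladder is assigned to the cardinal
    direction dominating the displacement from its nearest CT1 surface point
    (ties broken in the fixed order L, R, A, P, S, I); the necessary
    expansion in a direction is the maximum Euclidean distance of its
    assigned voxels to the CT1 bladder.  Directions with no assigned voxels
    need no expansion.
    """
    _require_same_grid(bladder_ct1, bladder_ct2)
    if bladder_ct1.is_empty() or bladder_ct2.is_empty():
        raise ValueError("necessary expansion undefined for empty bladders")

    protruding = bladder_ct2.occupancy & ~bladder_ct1.occupancy
    result = dict.fromkeys(DIRECTION_ORDER, 0.0)
    if not protruding.any():
        return DirectionalMargins(**result)

    spacing = np.asarray(bladder_ct1.grid.spacing)
    dist, nearest = ndimage.distance_transform_edt(
        ~bladder_ct1.occupancy, sampling=bladder_ct1.grid.spacing,
        return_indices=True,
    )
    idx = np.argwhere(protruding)
    dists = dist[tuple(idx.T)]
    # displacement direction: the gradient of the distance field points away
    # from the nearest surface point and is smoother than the voxel-center
    # difference (which is badly quantized on blocky digitized surfaces);
    # fall back to the nearest-voxel difference where the gradient degenerates
    grads = np.gradient(dist, *spacing)
    disp = np.stack([g[tuple(idx.T)] for g in grads], axis=1) * dists[:, None]
    weak = np.linalg.norm(disp, axis=1) < 0.5 * dists
    if weak.any():
        near = np.stack([nearest[a][tuple(idx.T)] for a in range(3)], axis=1)
        vox_disp = (idx - near) * spacing
        disp[weak] = vox_disp[weak]

    # dominant |component|; tie-break via the declared direction order
    candidates = []  # (direction index in order, axis, sign)
    for k, name in enumerate(DIRECTION_ORDER):
        axis, sign = DIRECTIONS[name]
        candidates.append((k, axis, sign))
    comp = np.abs(disp)
    best_axis = np.full(len(idx), -1)
    best_sign = np.zeros(len(idx))
    best_val = np.full(len(idx), -1.0)
    for k, axis, sign in candidates:
        val = np.where(np.sign(disp[:, axis]) == sign, comp[:, axis], -np.inf)
        better = val > best_val + 1e-12
        best_val = np.where(better, val, best_val)
        best_axis = np.where(better, axis, best_axis)
        best_sign = np.where(better, sign, best_sign)

    for name in DIRECTION_ORDER:
        axis, sign = DIRECTIONS[name]
        sel = (best_axis == axis) & (best_sign == sign)
        if sel.any():
            result[name] = float(dists[sel].max())
    return DirectionalMargins(**result)


def patient_specific_margin(bladder_ct1: StructureMask,
                            bladder_ct2: StructureMask) -> DirectionalMargins:
    """Elective PTV margin from the two planning-CT bladders.

    If the CT2 bladder is fully encompassed by the 5 mm expansion of the CT1
    bladder the margin is a uniform 7 mm.  Otherwise each direction whose
    necessary expansion exceeds 5 mm receives 1.5x that expansion, and all
    other directions the 7 mm fallback.
    """
    envelope = expand(bladder_ct1, ENVELOPE_MM)
    if envelope.contains(bladder_ct2):
        return DirectionalMargins.uniform(UNIFORM_FALLBACK_MM)
    needed = necessary_expansion(bladder_ct1, bladder_ct2)
    out = {}
    for name, e_d in needed.as_dict().items():
        out[name] = SAFETY_FACTOR * e_d if e_d > ENVELOPE_MM else UNIFORM_FALLBACK_MM
    return DirectionalMargins(**out)


def margin_report(bladder_ct1: StructureMask,
                  bladder_ct2: StructureMask) -> dict:
    """Margins plus the branch taken, for reporting/CLI use."""
    envelope_holds = expand(bladder_ct1, ENVELOPE_MM).contains(bladder_ct2)
    margins = patient_specific_margin(bladder_ct1, bladder_ct2)
    report = {
        "branch": "uniform" if envelope_holds else "patient_specific",
        "margins_mm": margins.as_dict(),
    }
    if not envelope_holds:
        report["necessary_expansion_mm"] = necessary_expansion(
            bladder_ct1, bladder_ct2
        ).as_dict()
    return report


def build_targets(gtv: StructureMask, bladder: StructureMask,
                  lymph_nodes: StructureMask, urethra: StructureMask,
                  elective_margins: DirectionalMargins,
                  node_urethra_margin_mm: float = 5.0) -> TargetSet:
    """Construct all target volumes from the base structures."""
    _require_same_grid(gtv, bladder)
    _require_same_grid(bladder, lymph_nodes)
    _require_same_grid(lymph_nodes, urethra)
    ctv_sib = expand(gtv, SIB_MARGIN_MM, label="CTV_SIB")
    ptv_sib = expand(ctv_sib, SIB_MARGIN_MM, label="PTV_SIB")
    nodes_urethra = lymph_nodes.union(urethra, label="nodes+urethra")
    ctv_elective = bladder.union(nodes_urethra, label="CTV_elective")
    ptv_elective = expand(bladder, elective_margins).union(
        expand(nodes_urethra, node_urethra_margin_mm), label="PTV_elective"
    )
    ts = TargetSet(gtv=gtv, ctv_sib=ctv_sib, ptv_sib=ptv_sib,
                   ctv_elective=ctv_elective, ptv_elective=ptv_elective)
    ts.validate_nesting()
    return ts
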