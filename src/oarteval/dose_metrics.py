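"""Dose-based plan-quality scores.

Coverage (V95%), dose outside the target (V95%,out), conformity (Paddick CI
and the RTOG ratio), homogeneity (ICRU-83), DVH percentiles, mean dose,
coverage-based plan normalization and the clinical-goal check.

Conventions mirror standard planning practice: coverage thresholds are
inclusive ("at least 95% of the prescribed dose"), the 107% hot-spot rule is
strict ("> 107%"), DVH percentiles are computed from the exact voxel-dose
multiset (no histogram binning), and "body" always means the explicit body
mask, never the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids_structures import DoseGrid, StructureMask, _require_same_grid, volume_cc

__all__ = [
    "Prescription",
    "v_at_threshold",
    "v95_out",
    "ci_rtog",
    "ci_paddick",
    "homogeneity_index",
    "d_at_volume",
    "mean_dose",
    "normalize_plan",
    "clinical_goal_pass",
    "high_dose_outside",
    "COVERAGE_GOAL_PCT",
]

#: clinical requirement: V95% of CTV and PTV must be at least this (percent)
COVERAGE_GOAL_PCT = 98.0

# guard factor applied to the normalization scale so the voxel that defines
# D98% stays on the covered side of the threshold after float rounding
_NORM_GUARD = 1.0 + 1e-9


@dataclass(frozen=True)
class Prescription:
    """Two-level prescription: elective dose plus a simultaneous boost.

    The elective volume (bladder, urethra, pelvic lymph nodes) receives
    ``elective_dose`` in ``fractions`` fractions; the tumor bed additionally
    receives ``sib_increment`` as a simultaneous integrated boost, so the
    boost level is their sum.
    """

    elective_dose_Gy: float = 40.0
    sib_increment_Gy: float = 15.0
    fractions: int = 20

    def __post_init__(self):
        if self.elective_dose_Gy <= 0 or self.sib_increment_Gy <= 0 or self.fractions <= 0:
            raise ValueError("prescription levels and fraction count must be positive")

    @property
    def boost_dose_Gy(self) -> float:
        return self.elective_dose_Gy + self.sib_increment_Gy


def _mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    _require_same_grid(dose, mask)
    return dose.dose_Gy[mask.occupancy]


def v_at_threshold(dose: DoseGrid, mask: StructureMask, threshold_Gy: float) -> tuple[float, float]:
    """Volume (cc) and percentage of ``mask`` receiving >= ``threshold_Gy``."""
    if mask.is_empty():
        raise ValueError("coverage of an empty mask is undefined")
    vals = _mask_doses(dose, mask)
    n = int((vals >= threshold_Gy).sum())
    return n * mask.grid.voxel_volume_cc, 100.0 * n / vals.size


def v95_body_cc(dose: DoseGrid, body: StructureMask, prescription_Gy: float) -> float:
    """Volume of the body receiving at least 95% of the prescribed dose."""
    vol, _ = v_at_threshold(dose, body, 0.95 * prescription_Gy)
    return vol


def v95_out(dose: DoseGrid, target: StructureMask, body: StructureMask,
            prescription_Gy: float) -> float:
    """V95%,out = V95%,Body - V95%(target): healthy tissue at high dose (cc)."""
    _require_same_grid(target, body)
    if not body.contains(target):
        raise ValueError(f"target '{target.label}' is not contained in the body mask")
    thr = 0.95 * prescription_Gy
    v_body = v95_body_cc(dose, body, prescription_Gy)
    v_target, _ = v_at_threshold(dose, target, thr)
    return v_body - v_target


def ci_rtog(dose: DoseGrid, ptv: StructureMask, prescription_Gy: float,
            body: StructureMask) -> float:
    """RTOG conformity: (body volume at >= 95% prescription) / PTV volume."""
    if ptv.is_empty():
        raise ValueError("conformity of an empty PTV is undefined")
    return v95_body_cc(dose, body, prescription_Gy) / volume_cc(ptv)


def ci_paddick(dose: DoseGrid, ptv: StructureMask, prescription_Gy: float,
               body: StructureMask) -> float:
    """Paddick conformity index (TV_PIV)^2 / (TV * PIV), in (0, 1].

    TV is the PTV volume, PIV the 95%-prescription isodose volume within the
    body, TV_PIV their intersection.
    """
    if ptv.is_empty():
        raise ValueError("conformity of an empty PTV is undefined")
    _require_same_grid(dose, ptv)
    _require_same_grid(ptv, body)
    thr = 0.95 * prescription_Gy
    piv_occ = (dose.dose_Gy >= thr) & body.occupancy
    piv = int(piv_occ.sum())
    if piv == 0:
        raise ValueError("prescription isodose volume is empty")
    tv = ptv.voxel_count
    tv_piv = int((piv_occ & ptv.occupancy).sum())
    return tv_piv**2 / (tv * piv)


def d_at_volume(dose: DoseGrid, mask: StructureMask, volume_pct: float) -> float:
    """Dx%: the largest dose received by at least x% of the mask (Gy).

    Computed from the exact voxel-dose multiset: with the doses sorted in
    descending order, Dx% is the value at rank ceil(x/100 * n).
    """
    if not 0.0 < volume_pct <= 100.0:
        raise ValueError("volume_pct must be in (0, 100]")
    vals = _mask_doses(dose, mask)
    if vals.size == 0:
        raise ValueError("DVH percentile of an empty mask is undefined")
    desc = np.sort(vals)[::-1]
    rank = int(np.ceil(volume_pct / 100.0 * vals.size))
    return float(desc[rank - 1])


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    vals = _mask_doses(dose, mask)
    if vals.size == 0:
        raise ValueError("mean dose of an empty mask is undefined")
    return float(vals.mean())


def homogeneity_index(dose: DoseGrid, ptv: StructureMask) -> float:
    """ICRU-83 homogeneity index (D2% - D98%) / D50%."""
    d2 = d_at_volume(dose, ptv, 2.0)
    d98 = d_at_volume(dose, ptv, 98.0)
    d50 = d_at_volume(dose, ptv, 50.0)
    if d50 == 0:
        raise ValueError("homogeneity undefined: D50% is zero")
    return (d2 - d98) / d50


def normalize_plan(dose: DoseGrid, ptv_sib: StructureMask,
                   prescription: Prescription) -> DoseGrid:
    """Rescale a plan so 98% of PTV_SIB receives 95% of the boost dose.

    The scale factor is s = (0.95 * boost) / D98%(PTV_SIB); after scaling,
    coverage at the 95% threshold equals 98% up to the discrete DVH step.  A
    relative guard of 1e-9 keeps the voxel defining D98% on the covered side
    under float rounding.
    """
    d98 = d_at_volume(dose, ptv_sib, 98.0)
    if d98 <= 0:
        raise ValueError("cannot normalize: D98% of PTV_SIB is zero")
    s = 0.95 * prescription.boost_dose_Gy / d98
    return dose.scaled(s * _NORM_GUARD)


def clinical_goal_pass(dose: DoseGrid, target: StructureMask,
                       prescription_Gy: float) -> bool:
    """True iff V95% of the target is at least 98% (inclusive)."""
    _, pct = v_at_threshold(dose, target, 0.95 * prescription_Gy)
    return pct >= COVERAGE_GOAL_PCT


def high_dose_outside(dose: DoseGrid, target: StructureMask,
                      prescription_Gy: float) -> float:
    """Volume outside the target with dose strictly above 107% of the
    prescription (cc)."""
    _require_same_grid(dose, target)
    hot = (dose.dose_Gy > 1.07 * prescription_Gy) & ~target.occupancy
    return int(hot.sum()) * target.grid.voxel_volume_cc
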