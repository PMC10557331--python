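"""On-disk formats: NIfTI volumes, JSON session manifests, CSV metric tables.

Volumes (masks and dose) are stored as NIfTI with a diagonal affine built
from the grid spacing and origin; the grid axes carry the anatomical
convention declared in :mod:`oarteval.grids_structures`.  Each session is a
directory of volumes plus a JSON manifest; a cohort is a directory of
patient directories.  Masks round-trip bit-exactly, dose within float32
precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dose_metrics import Prescription
from .grids_structures import DoseGrid, GridMismatchError, StructureMask, VoxelGrid
from .margin_targets import TargetSet
from .synthetic_cohort import SessionRecord, WORKFLOW_STEPS

__all__ = [
    "SessionManifest",
    "load_volume",
    "save_volume",
    "write_metrics_table",
    "read_metrics_table",
    "write_json_report",
    "write_cohort",
    "load_cohort",
    "DiskCohort",
]

_MASK_TOL = 1e-3
_DOSE_FLOOR = -1e-6  # tolerate float32 round-off, not genuine negative dose

#: per-session mask files (attribute name -> file stem)
_SESSION_MASKS = {
    "bladder_daily": "bladder_daily",
    "gtv_clin": "gtv_clin",
    "gtv_ai": "gtv_ai",
    "markers_man": "markers_man",
    "markers_auto": "markers_auto",
}
_TARGET_MASKS = ("ctv_sib", "ptv_sib", "ctv_elective", "ptv_elective")
_PATIENT_MASKS = ("body", "bladder_ct1", "bladder_ct2", "gtv_ref", "nodes",
                  "markers_ref")


@dataclasses.dataclass
class SessionManifest:
    """File references and metadata of one treatment session."""

    patient_id: str
    fraction_index: int
    files: dict  # role -> relative path
    step_timestamps_s: dict  # step name -> seconds since session start
    corrected: bool
    in_training: bool

    def __post_init__(self):
        if self.fraction_index < 1:
            raise ValueError("fraction index is 1-based")
        ordered = [self.step_timestamps_s[s] for s in WORKFLOW_STEPS
                   if s in self.step_timestamps_s]
        if any(b < a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("timestamps must be non-decreasing in workflow order")


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> VoxelGrid:
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.max(np.abs(off)) > 1e-6:
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = np.diag(aff[:3, :3])
    if np.any(spacing <= 0):
        raise ValueError("axis flips are not supported; spacing must be positive")
    return VoxelGrid(shape=tuple(shape), spacing=tuple(spacing),
                     origin=tuple(aff[:3, 3]))


def save_volume(volume, path) -> None:
    """Write a mask (uint8) or dose (float32) volume as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, StructureMask):
        data = volume.occupancy.astype(np.uint8)
    elif isinstance(volume, DoseGrid):
        data = volume.dose_Gy.astype(np.float32)
    else:
        raise TypeError(f"cannot save {type(volume).__name__}")
    img = nib.Nifti1Image(data, _affine(volume.grid))
    nib.save(img, str(path))


def load_volume(path, expected_kind: str, label: str = ""):
    """Load a NIfTI volume as a :class:`StructureMask` or :class:`DoseGrid`.

    Masks must be binary within a small tolerance; dose must be
    non-negative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    grid = _grid_from_affine(img.affine, data.shape)
    if expected_kind == "mask":
        rounded = np.round(data)
        if np.max(np.abs(data - rounded)) > _MASK_TOL or \
                not np.all(np.isin(rounded, (0.0, 1.0))):
            raise ValueError(f"{path}: mask contains non-binary values")
        return StructureMask(grid, rounded.astype(bool), label or path.stem)
    if expected_kind == "dose":
        if data.min() < _DOSE_FLOOR:
            raise ValueError(f"{path}: negative dose ({data.min():.4g} Gy)")
        return DoseGrid(grid, np.maximum(data, 0.0))
    raise ValueError(f"unknown volume kind '{expected_kind}'")


# ---------------------------------------------------------------------------
# tables and reports


def write_metrics_table(rows, path, columns=None, float_fmt: str = "%.6f") -> None:
    """Write metric rows as CSV with a stable column order.

    ``rows`` is a DataFrame or a list of dicts sharing one schema; an empty
    list with explicit ``columns`` produces a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            schema = list(rows[0].keys())
            for r in rows:
                if list(r.keys()) != schema:
                    raise ValueError("heterogeneous row schemas")
            df = pd.DataFrame.from_records(rows, columns=schema)
        else:
            df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, index=False, float_format=float_fmt)


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json_report(data, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(data), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# cohort directories


def write_cohort(cohort, out_dir, include_ai_plan: bool = True) -> None:
    """Materialize a synthetic cohort as a directory tree of volumes and
    manifests.  Reference volumes and the scheduled (reference-plan) dose
    are written once per patient; sessions reference them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    write_json_report({
        "n_patients": cfg.n_patients,
        "n_fractions": cfg.n_fractions,
        "master_seed": cfg.master_seed,
        "prescription": dataclasses.asdict(cfg.prescription),
    }, out / "cohort.json")

    for patient in cohort.patients:
        pdir = out / patient.patient_id
        for name in _PATIENT_MASKS:
            save_volume(getattr(patient, name), pdir / f"{name}.nii.gz")
        save_volume(patient.targets_ref.ptv_elective,
                    pdir / "ptv_elective_ref.nii.gz")
        save_volume(patient.reference_dose, pdir / "reference_dose.nii.gz")
        write_json_report({
            "patient_id": patient.patient_id,
            "in_training": patient.in_training,
            "elective_margins_mm": patient.elective_margins.as_dict(),
        }, pdir / "patient.json")

    for session in cohort.iter_sessions():
        pdir = out / session.patient_id
        sdir = pdir / f"f{session.fraction_index:02d}"
        files = {}
        for attr, stem in _SESSION_MASKS.items():
            save_volume(getattr(session, attr), sdir / f"{stem}.nii.gz")
            files[attr] = f"{sdir.name}/{stem}.nii.gz"
        for name in _TARGET_MASKS:
            save_volume(getattr(session.targets_daily, name),
                        sdir / f"{name}.nii.gz")
            files[name] = f"{sdir.name}/{name}.nii.gz"
        save_volume(session.adaptive_dose, sdir / "adaptive_dose.nii.gz")
        files["adaptive_dose"] = f"{sdir.name}/adaptive_dose.nii.gz"
        files["scheduled_dose"] = "reference_dose.nii.gz"
        if include_ai_plan and session.plan_ai_dose is not None:
            save_volume(session.plan_ai_dose, sdir / "plan_ai_dose.nii.gz")
            files["plan_ai_dose"] = f"{sdir.name}/plan_ai_dose.nii.gz"
        manifest = SessionManifest(
            patient_id=session.patient_id,
            fraction_index=session.fraction_index,
            files=files,
            step_timestamps_s=session.timestamps_s,
            corrected=session.corrected,
            in_training=session.in_training,
        )
        write_json_report(dataclasses.asdict(manifest), sdir / "manifest.json")


@dataclasses.dataclass
class DiskCohort:
    """A cohort loaded from disk: materialized sessions, shared references."""

    sessions: list
    prescription: Prescription
    n_fractions: int

    def iter_sessions(self, compute_doses: bool = True):
        return iter(self.sessions)

    def materialize(self, compute_doses: bool = True):
        return list(self.sessions)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)


def load_cohort(cohort_dir) -> DiskCohort:
    """Load a cohort directory written by :func:`write_cohort`.

    All volumes of one session are validated to share one grid.
    """
    root = Path(cohort_dir)
    meta = json.loads((root / "cohort.json").read_text())
    rx = Prescription(**meta["prescription"])
    sessions = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        pmeta = json.loads((pdir / "patient.json").read_text())
        shared = {
            name: load_volume(pdir / f"{name}.nii.gz", "mask", name)
            for name in _PATIENT_MASKS
        }
        ptv_ref = load_volume(pdir / "ptv_elective_ref.nii.gz", "mask",
                              "PTV_elective_ref")
        ref_dose = load_volume(pdir / "reference_dose.nii.gz", "dose")
        for sdir in sorted(d for d in pdir.iterdir() if d.is_dir()):
            manifest = SessionManifest(**json.loads(
                (sdir / "manifest.json").read_text()))
            masks = {attr: load_volume(sdir / f"{stem}.nii.gz", "mask", stem)
                     for attr, stem in _SESSION_MASKS.items()}
            targets = {name: load_volume(sdir / f"{name}.nii.gz", "mask", name)
                       for name in _TARGET_MASKS}
            adaptive = load_volume(sdir / "adaptive_dose.nii.gz", "dose")
            ai_path = sdir / "plan_ai_dose.nii.gz"
            plan_ai = load_volume(ai_path, "dose") if ai_path.exists() else None
            volumes = ([shared["body"], ptv_ref, adaptive, ref_dose]
                       + list(masks.values()) + list(targets.values()))
            grid = volumes[0].grid
            for v in volumes[1:]:
                if not v.grid.same_as(grid):
                    raise GridMismatchError(
                        f"{sdir}: volumes are not on one grid")
            target_set = TargetSet(
                gtv=masks["gtv_clin"], ctv_sib=targets["ctv_sib"],
                ptv_sib=targets["ptv_sib"],
                ctv_elective=targets["ctv_elective"],
                ptv_elective=targets["ptv_elective"])
            sessions.append(SessionRecord(
                patient_id=manifest.patient_id,
                patient_index=int(manifest.patient_id.lstrip("P")),
                fraction_index=manifest.fraction_index,
                in_training=manifest.in_training,
                corrected=manifest.corrected,
                prescription=rx,
                body=shared["body"],
                bladder_daily=masks["bladder_daily"],
                gtv_clin=masks["gtv_clin"], gtv_ai=masks["gtv_ai"],
                gtv_ref=shared["gtv_ref"],
                markers_man=masks["markers_man"],
                markers_auto=masks["markers_auto"],
                targets_daily=target_set,
                ptv_elective_ref=ptv_ref,
                scheduled_dose=ref_dose,
                adaptive_dose=adaptive,
                plan_ai_dose=plan_ai,
                targets_ai=None,
                timestamps_s=manifest.step_timestamps_s,
            ))
    return DiskCohort(sessions=sessions, prescription=rx,
                      n_fractions=meta["n_fractions"])
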