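"""Synthetic phantom cohort emulating an online-adaptive bladder-RT study.

Generates patients (bladder on two planning CTs, tumor-bed GTV on the
bladder wall, fiducial marker dots, a lymph-node/urethra surrogate, body),
daily sessions (deformed bladder, AI-propagated vs clinically corrected
GTV, propagated vs manual markers, scheduled/adaptive/AI two-level dose
fields, workflow-step timestamps), with the statistical structure the
analysis pipeline assumes:

* the AI GTV is systematically smaller than the corrected clinical GTV
  (configurable volume-deficit distribution, enlargement in ~96% of
  corrections, corrections in ~60% of steady sessions);
* marker propagation errors are larger in corrected sessions;
* the daily bladder protrudes from the planning elective PTV in a
  configurable ~10% of sessions;
* adaptive dose fields conform to the daily targets and pass all coverage
  goals after normalization, scheduled fields conform to the planning
  targets and may fail on deformed anatomy.

Anatomy primitives are analytic (digitized ellipsoids/spheres) so that
closed-form volumes and distances are available as test oracles.  The dose
model is a distance-to-target plateau with a Gaussian penumbra, a smooth
directionally modulated conformity skirt and a few penumbral cold spots —
a geometric stand-in for an optimized VMAT dose, sufficient to exercise
every metric, not a beam model.

All randomness flows from one master seed through ``numpy`` seed sequences;
dose-shaping noise is keyed on the target geometry itself so identical
targets always yield identical dose fields.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .dose_metrics import Prescription, normalize_plan
from .grids_structures import (
    DoseGrid,
    StructureMask,
    VoxelGrid,
    digitize_ellipsoid,
    digitize_sphere,
    encompasses,
    expand,
    signed_distance_mm,
)
from .margin_targets import DirectionalMargins, TargetSet, build_targets, patient_specific_margin

__all__ = [
    "GeneratorConfig",
    "PatientAnatomy",
    "SessionRecord",
    "Cohort",
    "generate_patient",
    "generate_session",
    "generate_cohort",
    "session_flags",
    "WORKFLOW_STEPS",
]

#: ordered workflow steps of one adaptive session (timestamps refer to the
#: END of each step, in seconds since the patient entered the room)
WORKFLOW_STEPS = (
    "patient_setup",
    "cbct1",
    "structure_propagation",
    "reoptimization",
    "plan_evaluation",
    "cbct2",
    "position_verification",
    "rt",
    "cbct3",
    "patient_leaving",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_patients: int = 15
    n_fractions: int = 20
    n_training_patients: int = 5
    master_seed: int = 1234

    # grid
    grid_shape: tuple[int, int, int] = (88, 88, 88)
    spacing_mm: float = 2.0

    # reference anatomy (mm)
    body_semiaxes_mm: tuple[float, float, float] = (82.0, 80.0, 83.0)
    bladder_semiaxes_mean_mm: tuple[float, float, float] = (36.0, 31.0, 31.0)
    bladder_semiaxes_sd_mm: float = 3.0
    bladder_semiaxes_clip_mm: tuple[tuple[float, float], ...] = (
        (30.0, 42.0), (26.0, 38.0), (26.0, 38.0))
    gtv_radius_mean_mm: float = 13.0
    gtv_radius_sd_mm: float = 1.5
    gtv_radius_clip_mm: tuple[float, float] = (10.0, 16.0)
    node_tube_radius_mm: float = 7.0
    node_tube_halflength_mm: float = 28.0
    node_tube_posterior_gap_mm: float = 16.0
    node_urethra_margin_mm: float = 5.0

    # second planning CT (intrafraction filling surrogate)
    ct2_scale_mean: float = 1.08
    ct2_scale_sd: float = 0.03
    ct2_scale_clip: tuple[float, float] = (1.0, 1.16)
    ct2_translation_sd_mm: float = 2.0
    ct2_translation_clip_mm: float = 5.0

    # interfraction deformation of the daily bladder
    daily_scale_sd: float = 0.05
    daily_scale_clip: tuple[float, float] = (0.88, 1.12)
    daily_translation_sd_mm: float = 2.5
    daily_translation_clip_mm: float = 6.0
    protrusion_probability: float = 0.10

    # AI GTV propagation errors
    correction_probability: float = 0.60
    enlargement_probability: float = 0.96
    ai_deficit_median_cc: float = 2.5
    ai_deficit_sigma: float = 0.45  # lognormal log-sd of the volume deficit
    ai_center_shift_sd_mm: float = 1.0

    # fiducial markers
    marker_count_range: tuple[int, int] = (3, 5)
    marker_volume_range_cc: tuple[float, float] = (0.1, 0.2)
    marker_offset_median_corrected_mm: float = 9.0
    marker_offset_median_accepted_mm: float = 6.4
    marker_offset_sigma: float = 0.4

    # dose model
    prescription: Prescription = field(default_factory=Prescription)
    penumbra_mm: float = 5.0
    skirt_base_mm: float = 0.25
    skirt_modulation_mm: float = 1.5
    n_cold_spots: int = 3
    cold_spot_depth: float = 0.12
    cold_spot_sigma_mm: float = 4.5

    # workflow timing (minutes; per-step medians of a log-normal)
    step_median_min: dict = field(default_factory=lambda: {
        "patient_setup": 3.0,
        "cbct1": 1.0,
        "structure_propagation_accepted": 2.0,
        "structure_propagation_corrected": 6.5,
        "reoptimization": 8.0,
        "plan_evaluation": 3.5,
        "cbct2": 1.0,
        "position_verification": 1.5,
        "rt": 2.5,
        "cbct3": 1.0,
        "patient_leaving": 1.0,
    })
    step_sigma: float = 0.2
    training_time_factor: float = 1.25
    training_slow_steps: tuple[str, ...] = (
        "structure_propagation", "reoptimization", "plan_evaluation")

    def __post_init__(self):
        for p in (self.protrusion_probability, self.correction_probability,
                  self.enlargement_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        lo, hi = self.marker_volume_range_cc
        if lo < 0.1 - 1e-9 or hi > 0.2 + 1e-9 or lo > hi:
            raise ValueError("marker dot volumes must stay within [0.1, 0.2] cc")

    def grid(self) -> VoxelGrid:
        shape = tuple(self.grid_shape)
        sp = (self.spacing_mm,) * 3
        origin = tuple(-(n - 1) / 2.0 * self.spacing_mm for n in shape)
        return VoxelGrid(shape=shape, spacing=sp, origin=origin)

    @classmethod
    def zero_deformation(cls, **overrides) -> "GeneratorConfig":
        """Degenerate limit: no interfraction motion, no propagation errors."""
        base = dict(
            daily_scale_sd=0.0, daily_translation_sd_mm=0.0,
            protrusion_probability=0.0, correction_probability=0.0,
            marker_offset_median_corrected_mm=0.0,
            marker_offset_median_accepted_mm=0.0,
            ct2_scale_mean=1.0, ct2_scale_sd=0.0, ct2_translation_sd_mm=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PatientAnatomy:
    """Reference (planning) anatomy and plan of one phantom patient."""

    patient_id: str
    patient_index: int  # 1-based
    in_training: bool
    grid: VoxelGrid
    body: StructureMask
    bladder_ct1: StructureMask
    bladder_ct2: StructureMask
    nodes: StructureMask        # lymph-node + urethra surrogate (static)
    gtv_ref: StructureMask
    markers_ref: StructureMask
    elective_margins: DirectionalMargins
    targets_ref: TargetSet
    reference_dose: DoseGrid
    # analytic parameters (phantom ground truth, used for transport)
    bladder_center_mm: np.ndarray
    bladder_semiaxes_mm: np.ndarray
    gtv_direction: np.ndarray
    gtv_radius_mm: float
    gtv_center_mm: np.ndarray
    marker_specs: list  # (offset from GTV center [mm], voxel count)
    nodes_expanded: StructureMask = None  # cached expand(nodes, margin)


@dataclass
class SessionRecord:
    """One treatment fraction: daily anatomy, plans and timing."""

    patient_id: str
    patient_index: int
    fraction_index: int  # 1-based
    in_training: bool
    corrected: bool
    prescription: Prescription
    body: StructureMask
    bladder_daily: StructureMask
    gtv_clin: StructureMask
    gtv_ai: StructureMask
    gtv_ref: StructureMask
    markers_man: StructureMask
    markers_auto: StructureMask
    targets_daily: TargetSet
    ptv_elective_ref: StructureMask
    scheduled_dose: DoseGrid | None
    adaptive_dose: DoseGrid | None
    plan_ai_dose: DoseGrid | None
    targets_ai: TargetSet | None
    timestamps_s: dict  # step name -> seconds since room entry (end of step)

    @property
    def week(self) -> int:
        """Treatment week, counting consecutive blocks of 5 daily fractions."""
        return (self.fraction_index - 1) // 5 + 1


@dataclass
class Cohort:
    """Lazy cohort: patients are materialized, sessions stream on demand."""

    config: GeneratorConfig
    patients: list

    def iter_sessions(self, compute_doses: bool = True,
                      compute_ai_plan: bool = True):
        for patient in self.patients:
            for fraction in range(1, self.config.n_fractions + 1):
                yield generate_session(patient, fraction, self.config,
                                       compute_doses=compute_doses,
                                       compute_ai_plan=compute_ai_plan)

    def materialize(self, compute_doses: bool = True) -> list:
        return list(self.iter_sessions(compute_doses=compute_doses))

    @property
    def n_sessions(self) -> int:
        return len(self.patients) * self.config.n_fractions


# ---------------------------------------------------------------------------
# seeding helpers


def _patient_seed(config: GeneratorConfig, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.master_seed, 1, patient_index]))


def _session_seed(config: GeneratorConfig, patient_index: int,
                  fraction_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.master_seed, 2, patient_index, fraction_index]))


def _dose_rng(config: GeneratorConfig, *masks: StructureMask) -> np.random.Generator:
    """RNG keyed on the target geometry: identical targets -> identical dose."""
    h = hashlib.sha256()
    h.update(np.int64(config.master_seed).tobytes())
    for m in masks:
        h.update(np.packbits(m.occupancy).tobytes())
    key = np.frombuffer(h.digest()[:16], dtype=np.uint64)
    return np.random.default_rng(np.random.SeedSequence(key.tolist()))


# ---------------------------------------------------------------------------
# geometric helpers


def _ellipsoid_radius_along(semi_axes: np.ndarray, u: np.ndarray) -> float:
    """Distance from the ellipsoid center to its surface along unit vector u."""
    return 1.0 / np.sqrt(np.sum((u / semi_axes) ** 2))


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _nearest_voxel_ball(grid: VoxelGrid, center_mm, n_voxels: int) -> np.ndarray:
    """Boolean field: the ``n_voxels`` voxel centers nearest to ``center_mm``.

    Gives exact voxel-count (hence volume) control for small blobs such as
    fiducial marker dots; ties are broken deterministically by flat index.
    """
    center = np.asarray(center_mm, dtype=float)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    # candidate box comfortably larger than the final blob
    half = int(np.ceil((n_voxels ** (1 / 3) + 3)))
    ci = np.round((center - origin) / spacing).astype(int)
    lo = np.maximum(ci - half, 0)
    hi = np.minimum(ci + half + 1, grid.shape)
    occ = np.zeros(grid.shape, dtype=bool)
    sub_idx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].reshape(3, -1).T
    pts = origin + sub_idx * spacing
    d2 = np.sum((pts - center) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")[:n_voxels]
    sel = sub_idx[order]
    occ[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return occ


def _capsule_mask(grid: VoxelGrid, p0_mm, p1_mm, radius_mm: float,
                  label: str = "") -> StructureMask:
    """Capsule (cylinder with hemispherical caps) between two points."""
    p0 = np.asarray(p0_mm, float)
    p1 = np.asarray(p1_mm, float)
    xs, ys, zs = grid.coordinate_axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / max(L2, 1e-12), 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    return StructureMask(grid, dist2 <= radius_mm**2, label)


# ---------------------------------------------------------------------------
# dose model


def build_plan_dose(config: GeneratorConfig, targets: TargetSet,
                    body: StructureMask) -> DoseGrid:
    """Two-level conformal dose for a target set, normalized to its PTV_SIB.

    The elective level fills the union of both PTVs, the boost level the
    boost PTV, each with a plateau extended by a smooth directionally
    modulated skirt (conformity is never perfectly tight) and a Gaussian
    penumbra of the configured width.  A few compactly supported cold spots
    of configurable depth are placed in the penumbral rim of the boost PTV,
    attenuated to zero on the CTVs (optimizers protect CTV coverage), so
    the dose-volume histogram has a realistic low tail.  The plan is then
    normalized so 98% of PTV_SIB receives 95% of the boost dose.
    """
    grid = targets.ptv_sib.grid
    rx = config.prescription
    rng = _dose_rng(config, targets.ptv_elective, targets.ptv_sib,
                    targets.ctv_sib, targets.ctv_elective)

    union = targets.ptv_elective.union(targets.ptv_sib, label="PTV_union")
    t_union = signed_distance_mm(union)
    t_sib = signed_distance_mm(targets.ptv_sib)

    delta = _skirt_field(config, grid, rng)
    w_g = config.penumbra_mm / 1.12  # Gaussian scale: 80-20% distance = penumbra

    cutoff = 6.0 * w_g  # beyond this the field is clinically zero

    def level_field(t):
        m = t + delta
        tail = np.exp(-np.minimum(0.0, np.maximum(m, -cutoff)) ** 2 / (2 * w_g**2))
        return np.where(m >= 0.0, 1.0, np.where(m <= -cutoff, 0.0, tail))

    dose = np.maximum(rx.elective_dose_Gy * level_field(t_union),
                      rx.boost_dose_Gy * level_field(t_sib))

    dip = _cold_spot_field(config, targets, rng)
    dose = dose * (1.0 - dip)

    plan = DoseGrid(grid, dose)
    return normalize_plan(plan, targets.ptv_sib, rx)


def _skirt_field(config: GeneratorConfig, grid: VoxelGrid,
                 rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency modulation of the plateau extent (mm)."""
    if config.skirt_modulation_mm == 0.0:
        return np.full(grid.shape, config.skirt_base_mm)
    xs, ys, zs = grid.coordinate_axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    g = np.zeros(grid.shape)
    n_waves = 8
    amps = rng.uniform(0.5, 1.0, size=n_waves)
    for a in amps:
        # wavelengths of ~25-50 mm: comparable to a boost PTV, so the skirt
        # covers a session-varying fraction of the PTV rim
        k = rng.uniform(0.12, 0.25) * _random_unit_vector(rng)  # rad/mm
        phi = rng.uniform(0, 2 * np.pi)
        g += a * np.cos(k[0] * X + k[1] * Y + k[2] * Z + phi)
    g /= np.sqrt(np.sum(amps**2) / 2.0)  # ~unit variance
    return config.skirt_base_mm + config.skirt_modulation_mm * g


def _cold_spot_field(config: GeneratorConfig, targets: TargetSet,
                     rng: np.random.Generator) -> np.ndarray:
    """Sum of truncated-Gaussian cold spots in the boost-PTV rim, in [0, 1)."""
    grid = targets.ptv_sib.grid
    field_ = np.zeros(grid.shape)
    if config.n_cold_spots == 0 or config.cold_spot_depth == 0.0:
        return field_
    protect_sib = expand(targets.ctv_sib, 2.0)
    allowed = (targets.ptv_sib.occupancy
               & ~protect_sib.occupancy
               & ~expand(targets.ctv_elective, 4.0).occupancy)
    candidates = np.argwhere(allowed)
    if len(candidates) == 0:
        return field_
    picks = candidates[rng.integers(0, len(candidates), size=config.n_cold_spots)]

    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    sigma = config.cold_spot_sigma_mm
    radius = 3.0 * sigma
    floor = np.exp(-radius**2 / (2 * sigma**2))
    ramp_mm = 4.0
    pad_mm = radius + ramp_mm + 2.0
    for pick in picks:
        c = origin + pick * spacing
        lo = np.maximum(np.floor((c - pad_mm - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + pad_mm - origin) / spacing).astype(int) + 1,
                        grid.shape)
        box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        sub_idx = np.mgrid[box[0], box[1], box[2]]
        pts = origin + np.moveaxis(sub_idx, 0, -1) * spacing
        r2 = np.sum((pts - c) ** 2, axis=-1)
        bump = np.maximum(0.0, np.exp(-r2 / (2 * sigma**2)) - floor) / (1.0 - floor)
        atten = _local_outside_ramp(targets.ctv_sib, box, ramp_mm)
        atten *= _local_outside_ramp(targets.ctv_elective, box, ramp_mm)
        field_[box] += config.cold_spot_depth * bump * atten
    return np.minimum(field_, 0.5)


def _local_outside_ramp(mask: StructureMask, box, ramp_mm: float) -> np.ndarray:
    """0 on the mask ramping linearly to 1 at ``ramp_mm`` outside, on a box.

    Computed on the padded crop only; if the mask is farther from the box
    than the padding the ramp is 1 everywhere, so the crop is exact.
    """
    from scipy import ndimage

    spacing = np.asarray(mask.grid.spacing)
    pad = np.ceil(ramp_mm / spacing).astype(int) + 1
    lo = np.maximum([s.start for s in box] - pad, 0)
    hi = np.minimum([s.stop for s in box] + pad, mask.grid.shape)
    outer = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = mask.occupancy[outer]
    if not sub.any():
        inner_shape = tuple(s.stop - s.start for s in box)
        return np.ones(inner_shape)
    dist = ndimage.distance_transform_edt(~sub, sampling=mask.grid.spacing)
    inner = tuple(slice(b.start - o.start, b.stop - o.start)
                  for b, o in zip(box, outer))
    return np.clip(dist[inner] / ramp_mm, 0.0, 1.0)


# ---------------------------------------------------------------------------
# patient- and session-level generation


def generate_patient(config: GeneratorConfig, patient_index: int) -> PatientAnatomy:
    """Reference anatomy, patient-specific margins and reference plan."""
    rng = _patient_seed(config, patient_index)
    grid = config.grid()
    center = np.zeros(3)

    semi = np.array([
        np.clip(rng.normal(m, config.bladder_semiaxes_sd_mm), lo, hi)
        for m, (lo, hi) in zip(config.bladder_semiaxes_mean_mm,
                               config.bladder_semiaxes_clip_mm)
    ])
    bladder_ct1 = digitize_ellipsoid(grid, center, semi, "bladder_ct1")

    scale2 = float(np.clip(rng.normal(config.ct2_scale_mean, config.ct2_scale_sd),
                           *config.ct2_scale_clip))
    shift2 = np.clip(rng.normal(0, config.ct2_translation_sd_mm, size=3),
                     -config.ct2_translation_clip_mm, config.ct2_translation_clip_mm)
    bladder_ct2 = digitize_ellipsoid(grid, center + shift2, semi * scale2,
                                     "bladder_ct2")

    body = digitize_ellipsoid(grid, center, config.body_semiaxes_mm, "body")

    gap = config.node_tube_posterior_gap_mm
    node_y = -(semi[1] + gap + config.node_tube_radius_mm)
    hl = config.node_tube_halflength_mm
    nodes = _capsule_mask(grid, (0.0, node_y, -hl), (0.0, node_y, hl),
                          config.node_tube_radius_mm, "nodes_urethra")

    u = _random_unit_vector(rng)
    radius = float(np.clip(rng.normal(config.gtv_radius_mean_mm,
                                      config.gtv_radius_sd_mm),
                           *config.gtv_radius_clip_mm))
    gtv_center = center + _ellipsoid_radius_along(semi, u) * u
    gtv_ref = digitize_sphere(grid, gtv_center, radius, "GTV_ref")

    marker_specs = []
    n_markers = int(rng.integers(config.marker_count_range[0],
                                 config.marker_count_range[1] + 1))
    vox_cc = grid.voxel_volume_cc
    lo_n = int(np.ceil(config.marker_volume_range_cc[0] / vox_cc))
    hi_n = int(np.floor(config.marker_volume_range_cc[1] / vox_cc))
    marker_occ = np.zeros(grid.shape, dtype=bool)
    for _ in range(n_markers):
        v = _random_unit_vector(rng)
        offset = radius * v
        n_vox = int(rng.integers(lo_n, hi_n + 1))
        marker_specs.append((offset, n_vox))
        marker_occ |= _nearest_voxel_ball(grid, gtv_center + offset, n_vox)
    markers_ref = StructureMask(grid, marker_occ, "markers_ref")

    margins = patient_specific_margin(bladder_ct1, bladder_ct2)
    targets_ref = build_targets(gtv_ref, bladder_ct1, nodes,
                                StructureMask(grid, np.zeros(grid.shape, bool),
                                              "urethra"),
                                margins, config.node_urethra_margin_mm)
    targets_ref = _clip_targets_to_body(targets_ref, body)
    reference_dose = build_plan_dose(config, targets_ref, body)

    return PatientAnatomy(
        patient_id=f"P{patient_index:02d}",
        patient_index=patient_index,
        in_training=patient_index <= config.n_training_patients,
        grid=grid, body=body,
        bladder_ct1=bladder_ct1, bladder_ct2=bladder_ct2,
        nodes=nodes, gtv_ref=gtv_ref, markers_ref=markers_ref,
        elective_margins=margins, targets_ref=targets_ref,
        reference_dose=reference_dose,
        bladder_center_mm=center, bladder_semiaxes_mm=semi,
        gtv_direction=u, gtv_radius_mm=radius, gtv_center_mm=gtv_center,
        marker_specs=marker_specs,
        nodes_expanded=expand(nodes, config.node_urethra_margin_mm),
    )


def _clip_targets_to_body(ts: TargetSet, body: StructureMask) -> TargetSet:
    # PTVs may not exceed the body on extreme margins; CTVs always fit
    return TargetSet(
        gtv=ts.gtv, ctv_sib=ts.ctv_sib,
        ptv_sib=ts.ptv_sib.intersection(body, label=ts.ptv_sib.label),
        ctv_elective=ts.ctv_elective,
        ptv_elective=ts.ptv_elective.intersection(body, label=ts.ptv_elective.label),
    )


def session_flags(config: GeneratorConfig, patient_index: int,
                  fraction_index: int) -> dict:
    """Cheap deterministic per-session labels (no volume construction).

    Draws the same leading random variates as :func:`generate_session`, so
    the labels match the fully generated session.
    """
    rng = _session_seed(config, patient_index, fraction_index)
    corrected = bool(rng.random() < config.correction_probability)
    protruding = bool(rng.random() < config.protrusion_probability)
    return {"corrected": corrected, "protruding_target": protruding}


def generate_session(patient: PatientAnatomy, fraction_index: int,
                     config: GeneratorConfig,
                     compute_doses: bool = True,
                     compute_ai_plan: bool = True) -> SessionRecord:
    """One daily fraction of one patient.

    ``compute_doses=False`` skips all dose fields (anatomy-only session);
    ``compute_ai_plan=False`` skips only the AI-structure plan, for
    consumers that never evaluate the propagation dosimetry.
    """
    if not 1 <= fraction_index <= config.n_fractions:
        raise ValueError(f"fraction index {fraction_index} outside "
                         f"[1, {config.n_fractions}]")
    rng = _session_seed(config, patient.patient_index, fraction_index)
    corrected = bool(rng.random() < config.correction_probability)
    protrude = bool(rng.random() < config.protrusion_probability)
    grid = patient.grid

    bladder_daily, scale_d, shift_d = _daily_bladder(patient, config, rng, protrude)

    # clinical GTV rides rigidly on the bladder wall
    semi_daily = patient.bladder_semiaxes_mm * scale_d
    c_daily = patient.bladder_center_mm + shift_d
    gtv_center = c_daily + _ellipsoid_radius_along(
        semi_daily, patient.gtv_direction) * patient.gtv_direction
    gtv_clin = digitize_sphere(grid, gtv_center, patient.gtv_radius_mm, "GTV_clin")

    gtv_ai, enlarged = _propagated_gtv(patient, config, rng, gtv_center,
                                       corrected)

    markers_man, markers_auto = _session_markers(patient, config, rng,
                                                 gtv_center, corrected)

    targets_daily = build_targets(
        gtv_clin, bladder_daily, patient.nodes,
        StructureMask(grid, np.zeros(grid.shape, bool), "urethra"),
        patient.elective_margins, config.node_urethra_margin_mm)
    targets_daily = _clip_targets_to_body(targets_daily, patient.body)

    targets_ai = None
    scheduled = adaptive = plan_ai = None
    if compute_doses:
        adaptive = build_plan_dose(config, targets_daily, patient.body)
        scheduled = patient.reference_dose
        if not compute_ai_plan:
            pass
        elif corrected:
            targets_ai = build_targets(
                gtv_ai, bladder_daily, patient.nodes,
                StructureMask(grid, np.zeros(grid.shape, bool), "urethra"),
                patient.elective_margins, config.node_urethra_margin_mm)
            targets_ai = _clip_targets_to_body(targets_ai, patient.body)
            plan_ai = build_plan_dose(config, targets_ai, patient.body)
        else:
            targets_ai = targets_daily
            plan_ai = adaptive

    timestamps = _session_timestamps(patient, config, rng, corrected)

    return SessionRecord(
        patient_id=patient.patient_id,
        patient_index=patient.patient_index,
        fraction_index=fraction_index,
        in_training=patient.in_training,
        corrected=corrected,
        prescription=config.prescription,
        body=patient.body,
        bladder_daily=bladder_daily,
        gtv_clin=gtv_clin, gtv_ai=gtv_ai, gtv_ref=patient.gtv_ref,
        markers_man=markers_man, markers_auto=markers_auto,
        targets_daily=targets_daily,
        ptv_elective_ref=patient.targets_ref.ptv_elective,
        scheduled_dose=scheduled, adaptive_dose=adaptive,
        plan_ai_dose=plan_ai, targets_ai=targets_ai,
        timestamps_s=timestamps,
    )


def _daily_bladder(patient: PatientAnatomy, config: GeneratorConfig,
                   rng: np.random.Generator, protrude: bool):
    """Affinely deformed daily bladder honoring the protrusion flag.

    The flag states whether the daily (post-treatment surrogate) bladder
    protrudes from the planning elective PTV; sampled deformations are
    nudged deterministically until the flag holds (bounded retries, with a
    clipping fallback for the 'inside' case).
    """
    grid = patient.grid
    scale = np.clip(rng.normal(1.0, config.daily_scale_sd, size=3),
                    *config.daily_scale_clip)
    shift = np.clip(rng.normal(0.0, config.daily_translation_sd_mm, size=3),
                    -config.daily_translation_clip_mm,
                    config.daily_translation_clip_mm)
    push_dir = _random_unit_vector(rng)
    ptv_ref = patient.targets_ref.ptv_elective

    for _ in range(8):
        mask = digitize_ellipsoid(grid, patient.bladder_center_mm + shift,
                                  patient.bladder_semiaxes_mm * scale,
                                  "bladder_daily")
        inside, _ = encompasses(ptv_ref, mask)
        if inside != protrude:
            return mask, scale, shift
        if protrude:  # not protruding yet: push outward
            shift = shift + 3.0 * push_dir
            scale = scale * 1.02
        else:  # protruding but should fit: relax toward identity
            shift = shift * 0.6
            scale = 1.0 + (scale - 1.0) * 0.6

    if protrude:
        return mask, scale, shift  # rare: accept the residual state
    clipped = mask.intersection(ptv_ref, label="bladder_daily")
    return clipped, scale, shift


def _propagated_gtv(patient: PatientAnatomy, config: GeneratorConfig,
                    rng: np.random.Generator, gtv_center: np.ndarray,
                    corrected: bool):
    """AI-propagated GTV: equals the clinical one unless corrected."""
    if not corrected:
        gtv_ai = digitize_sphere(patient.grid, gtv_center,
                                 patient.gtv_radius_mm, "GTV_AI")
        return gtv_ai, False
    enlarged = bool(rng.random() < config.enlargement_probability)
    deficit = float(rng.lognormal(np.log(config.ai_deficit_median_cc),
                                  config.ai_deficit_sigma))
    v_clin = 4.0 / 3.0 * np.pi * (patient.gtv_radius_mm / 10.0) ** 3  # cc
    v_ai = v_clin - deficit if enlarged else v_clin + deficit
    v_ai = max(v_ai, 0.5)
    r_ai = 10.0 * (3.0 * v_ai / (4.0 * np.pi)) ** (1.0 / 3.0)
    shift = rng.normal(0.0, config.ai_center_shift_sd_mm, size=3)
    gtv_ai = digitize_sphere(patient.grid, gtv_center + shift, r_ai, "GTV_AI")
    return gtv_ai, enlarged


def _session_markers(patient: PatientAnatomy, config: GeneratorConfig,
                     rng: np.random.Generator, gtv_center: np.ndarray,
                     corrected: bool):
    """Manual markers ride with the clinical GTV; propagated ones are offset
    by one rigid registration error, larger in corrected sessions."""
    grid = patient.grid
    median = (config.marker_offset_median_corrected_mm if corrected
              else config.marker_offset_median_accepted_mm)
    if median > 0:
        magnitude = float(rng.lognormal(np.log(median),
                                        config.marker_offset_sigma))
        offset = magnitude * _random_unit_vector(rng)
    else:
        rng.lognormal(0.0, config.marker_offset_sigma)  # keep draw order stable
        _random_unit_vector(rng)
        offset = np.zeros(3)
    man = np.zeros(grid.shape, dtype=bool)
    auto = np.zeros(grid.shape, dtype=bool)
    for rel, n_vox in patient.marker_specs:
        man |= _nearest_voxel_ball(grid, gtv_center + rel, n_vox)
        auto |= _nearest_voxel_ball(grid, gtv_center + rel + offset, n_vox)
    return (StructureMask(grid, man, "markers_man"),
            StructureMask(grid, auto, "markers_auto"))


def _session_timestamps(patient: PatientAnatomy, config: GeneratorConfig,
                        rng: np.random.Generator, corrected: bool) -> dict:
    """Cumulative end-of-step times (seconds since room entry)."""
    out = {}
    t = 0.0
    for step in WORKFLOW_STEPS:
        if step == "structure_propagation":
            key = ("structure_propagation_corrected" if corrected
                   else "structure_propagation_accepted")
        else:
            key = step
        median = config.step_median_min[key]
        if patient.in_training and step in config.training_slow_steps:
            median *= config.training_time_factor
        duration_min = median * float(rng.lognormal(0.0, config.step_sigma))
        t += duration_min * 60.0
        out[step] = t
    return out


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """All patients of the study; sessions stream from :meth:`Cohort.iter_sessions`."""
    patients = [generate_patient(config, i + 1) for i in range(config.n_patients)]
    return Cohort(config=config, patients=patients)
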