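# Methods

`oarteval` re-implements, as a tested library, the evaluation analysis of a
CBCT-guided online-adaptive radiotherapy (oART) workflow for muscle-invasive
bladder cancer with a simultaneous integrated boost (SIB): 40 Gy in 20
fractions to the elective volume (bladder, urethra, first pelvic lymph
nodes) plus a 15 Gy SIB to the tumor bed, with daily AI-propagated contours,
online plan reoptimization, and fiducial markers for tumor-bed localization.
Because the clinical dataset is not public, a synthetic phantom cohort
generator reproduces the *statistical structure* the analysis assumes, so
that every metric, rule, and statistical procedure is exercised end to end.

## Geometric model

All structures are binary occupancy masks on one regular lattice
(`VoxelGrid`: shape, spacing, origin in mm; voxels node-centered, physical
position = origin + index × spacing). Grid axes carry a fixed anatomical
convention (+i = left, +j = anterior, +k = superior); every "direction" in
the margin logic refers to these six cardinal directions. Two grids are the
same lattice when shape matches and spacing/origin agree within 10⁻³ mm.

Margins are Euclidean: an isotropic expansion by `m` mm occupies every voxel
within distance `m` (closed ball) of the input, computed with a Euclidean
distance transform in physical units, so anisotropic spacing is handled
exactly. A six-direction margin (left, right, anterior, posterior, superior,
inferior) generalizes this to a per-half-axis ellipsoid: a voxel is added
when the displacement from its nearest occupied voxel, with each component
scaled by the margin of its cardinal direction, lies inside the unit ball.
This reduces exactly to the Euclidean ball when all six margins agree and is
monotone in every component. Surface voxels (for Hausdorff distances) are
occupied voxels with at least one unoccupied 6-neighbor.

Discretization caveat: the continuum identity
`expand(expand(m, a), b) = expand(m, a + b)` holds on the lattice only in
the ⊆ direction; the ⊇ direction needs one voxel diagonal of slack, because
intermediate surface points need not be voxel centers. The tests assert the
discrete form.

## Patient-specific elective margins

The planning protocol acquires two CTs ~15 min apart to estimate
intrafraction filling. The first-CT bladder is expanded 5 mm; if the
second-CT bladder is fully encompassed, the elective PTV margin is a uniform
7 mm. Otherwise the necessary expansion to encompass the bladder is
determined per cardinal direction and increased by 50% in every direction
where it exceeds 5 mm (other directions keep 7 mm).

"Necessary expansion per direction" is made operational as: each second-CT
voxel outside the first-CT bladder is assigned to the cardinal direction
dominating its displacement from the nearest first-CT surface point (ties
broken in the fixed order L, R, A, P, S, I), and the direction's expansion
is the maximum Euclidean distance of its assigned voxels. The displacement
direction is taken from the gradient of the distance field, which points
exactly away from the nearest surface point and is far smoother than
nearest-voxel index differences on blocky digitized surfaces (with a
nearest-voxel fallback where the gradient degenerates, e.g. on ridges).

Two properties worth knowing:

* The rule is deliberately discontinuous at the 5 mm threshold (a direction
  at 5.0 mm keeps 7 mm; at 5 + ε it gets 7.5 + 1.5ε mm), mirroring the
  clinical recipe.
* A *rigid shift* of the bladder produces genuinely diagonal displacements
  at the crescent edges (up to ~0.7× the shift magnitude in the orthogonal
  directions) — this is continuum geometry, not a discretization artifact —
  so a pure translation inflates the shifted direction dominantly but not
  exclusively. A localized bulge isolates cleanly to one direction. The
  1.5× factor applies to the *total* necessary expansion, not the excess
  over 5 mm (the alternative reading of the recipe), and is exact by
  construction: margin/expansion = 1.5 in every violated direction.

## Targets

`build_targets` composes: CTV_SIB = GTV ⊕ 5 mm, PTV_SIB = CTV_SIB ⊕ 5 mm;
CTV_elective = bladder ∪ lymph nodes ∪ urethra; PTV_elective = (bladder ⊕
patient-specific margins) ∪ (nodes ∪ urethra ⊕ 5 mm, configurable 5–7 mm).
Nesting (GTV ⊆ CTV_SIB ⊆ PTV_SIB, CTV_el ⊆ PTV_el) is validated after
construction. PTVs are clipped to the body mask.

## Dose metrics

* **V95%**: fraction of a structure receiving ≥ 95% of the prescribed level
  (inclusive, "at least"); the clinical goal is V95% ≥ 98% for all CTVs and
  PTVs (inclusive).
* **V95%,out** = V95%,Body − V95%(target), with "body" always the explicit
  body mask. The conservation identity V95,Body = V95,target + V95,out is
  exact by construction and re-verified by independent voxel recounts.
* **Conformity**: Paddick CI = (TV ∩ PIV)² / (TV · PIV) and the RTOG ratio
  CI_RTOG = PIV / TV, where PIV is the 95%-isodose volume within the body.
* **Homogeneity**: ICRU-83 (D2% − D98%) / D50%. DVH percentiles Dx% come
  from the exact voxel-dose multiset (largest dose received by ≥ x% of the
  mask) — no histogram binning, hence no binning tolerance.
* **Hot spots**: volume outside a target with dose strictly above 107% of
  the prescription (strict ">", matching the clinical wording; coverage
  thresholds are inclusive "≥").
* **Normalization**: plans are rescaled so 98% of PTV_SIB receives 95% of
  the 55 Gy boost: s = 0.95·55 / D98%(PTV_SIB). This pins post-
  normalization V95%(PTV_SIB) at 98% up to one discrete DVH step. A relative
  guard of 10⁻⁹ on s keeps the voxel that defines D98% on the covered side
  under float rounding; normalization is idempotent to the same 10⁻⁹.

## Contour metrics

Dice on voxel counts (grids are enforced equal, so counts and volumes
agree); classical maximum Hausdorff distance between surface point sets in
physical mm (a percentile variant is available but not the default; for
closed voxel sets surfaces and full sets give the same maximum); ΔCoM as
the Euclidean distance between occupancy-weighted centers of mass. Multiple
fiducial dots are compared as one union mask per side.

## Synthetic cohort

Defaults are the study conditions: 15 patients × 20 fractions = 300
sessions, the first 5 patients a training group, 2 mm isotropic grid
(88³ voxels; the clinical grid resolution is unpublished, so it is a
configuration choice).

* **Anatomy**: the bladder is a digitized ellipsoid (semi-axes ~36/31/31 ±3
  mm, ~145 cc); the second planning CT scales it by ~1.08 ± 0.03 and shifts
  it by ~2 mm per axis, so both margin branches occur in a default cohort.
  The GTV (tumor bed) is a sphere of radius 13 ± 1.5 mm centered on the
  bladder wall along a random direction; a posterior capsule stands in for
  the lymph-node/urethra elective structures; the body is a large ellipsoid.
* **Fiducial markers**: 3–5 dots of 0.1–0.2 cm³ at the GTV boundary. Dots
  are built as the N voxel centers nearest a point (N chosen from the
  volume range), because a digitized sphere at 2 mm spacing cannot
  guarantee the volume contract; the voxel-count construction can, and
  remains ball-shaped.
* **Daily sessions**: the daily bladder is an affinely deformed copy
  (per-axis scale σ = 0.05, translation σ = 2.5 mm). A configurable 10% of
  sessions are flagged as protruding from the *planning* elective PTV (the
  post-treatment position-check surrogate); sampled deformations are nudged
  deterministically until the flag holds. The clinical GTV rides rigidly
  with the bladder wall. With probability 0.60 the session is "corrected":
  the AI-propagated GTV then differs from the clinical one by a lognormal
  volume deficit (median 2.5 cm³, σ_log = 0.45), an enlargement (AI smaller)
  with probability 0.96, plus a ~1 mm center jitter; otherwise GTV_AI equals
  GTV_clin. Manual markers ride with the clinical GTV; propagated markers
  are offset by one rigid registration error whose magnitude is lognormal
  with median 9.0 mm in corrected and 6.4 mm in accepted sessions (their
  overall median ≈ the reported 7.8 mm; the 2.6 mm group gap is the
  reported difference).
* **Dose fields**: not a beam model — a geometric stand-in sufficient to
  exercise every metric. Each plan is max(40 Gy × f_elective, 55 Gy ×
  f_boost) where f is 1 on the target PTV (elective: union of both PTVs)
  extended by a "conformity skirt", and falls off as a Gaussian with
  80–20% penumbra width 5 mm outside. The skirt is a smooth directional
  modulation (base 0.25 mm + 1.5 mm × unit-variance cosine field with 25–50
  mm wavelengths) emulating the session-varying tightness of a real
  optimizer: the 95% isodose includes a varying fraction of the first voxel
  shell outside the PTV, which is what keeps CI_RTOG of the boost PTV in
  the reported 1.0–1.3 band after normalization. Three compactly supported
  Gaussian cold spots (depth 12%, σ = 4.5 mm, truncated at 3σ) are placed
  in the boost-PTV rim and attenuated to zero on both CTVs (optimizers
  protect CTV coverage), giving the DVH a realistic low tail; D98-based
  normalization then lands V95%(PTV_SIB) at exactly 98% + one DVH step
  while every CTV stays fully covered. The adaptive plan conforms to the
  daily targets, the scheduled plan is the patient's reference plan (built
  on the planning targets) evaluated on the shared grid, and plan_AI
  conforms to the AI-structure targets (equal to the adaptive plan in
  uncorrected sessions). Dose-shaping randomness is keyed on a hash of the
  target masks plus the master seed, so identical targets always produce
  identical fields — in the zero-deformation limit the scheduled and
  adaptive doses coincide exactly.
* **Timing**: per-step durations are lognormal (σ_log = 0.2) around
  configured medians — setup 3, CBCT1 1, structure propagation 2 (accepted)
  / 6.5 (corrected), reoptimization 8, plan evaluation 3.5, CBCT2 1,
  position verification 1.5, delivery 2.5, CBCT3 1, leaving 1 min — with a
  1.25× slowdown of the structure/reoptimization/evaluation steps for
  training patients. On-couch time is CBCT1 start to end of delivery;
  session time is room entry to exit. The clinical report gives medians
  only; the dispersion and the accepted/corrected split are configuration
  choices consistent with the reported 5-min correction overhead.
* **Seeding**: every random draw descends from one master seed through
  `numpy` `SeedSequence([master, tag, patient, fraction])`, so sessions can
  be regenerated individually and lazily; the full pipeline is byte-
  reproducible (identical metrics CSV for identical seeds).

What the phantom does *not* emulate: image content (no CBCT pixels),
realistic bladder deformation statistics (the clinical distributions are
unpublished; the affine model is a plausible stand-in), VMAT fluence and
delivery physics, organ-at-risk dosimetry, and inter-observer delineation
variability. Passing tests therefore demonstrate correctness of the
*analysis* under controlled conditions, not clinical performance.

## Analysis pipeline

Per session, both plans are scored on the daily targets (V95% ×4, V95,out
×4, both conformity indices for both PTVs, HI and mean dose of the boost
PTV, hot-spot volumes at both levels). Plan selection is a deterministic
lexicographic stand-in for the clinical judgment: more coverage goals met,
then less high dose outside the targets, then less boost-level spill; the
adaptive plan wins exact ties.

GTV propagation is evaluated in corrected sessions of the steady group
(training patients excluded): DSC/HD/Δvolume of GTV_clin vs GTV_AI, volume
differences against the planning GTV, and the coverage delta attributable
to the correction — the clinical plan's V95% of the clinically derived
CTV/PTV minus the AI plan's V95% of those same structures. (The AI plan
conforms to the smaller AI targets, so this delta is non-negative for the
CTV whenever the AI-based PTV is uniformly covered.)

The marker evaluation samples 20 sessions per group (GTV corrected /
accepted), at most one per patient-week (weeks = consecutive blocks of five
fractions), training patients excluded, then compares the per-session ΔCoM
distributions with a Mann-Whitney test.

Cohort statistics: paired two-sided Wilcoxon signed-rank tests between the
scheduled and adaptive plan for 12 metrics (V95% ×4, V95,out ×4, Paddick CI
of both PTVs, HI, boost mean dose) at the Bonferroni-corrected working
level 5%/12 ≈ 0.4%; Mann-Whitney between training and steady session times.
Exact null distributions are used for ≤ 25 tie-free observations, normal
approximation otherwise; all-zero difference vectors are flagged degenerate
(p = 1) rather than tested. The choice of the 12 comparisons is
configuration (the clinical report does not enumerate its family); test
sidedness is two-sided throughout.

## Problem sizes and numerical choices

The test suite runs the cohort-level checks on a scaled-down study (5
patients × 5 fractions with dose; a 15 × 8 dose-free cohort for
distribution recovery), with tolerances set from binomial / lognormal
sampling error at those sizes. The acceptance script evaluates the full
300-session cohort for the coverage-goal count and a 5 × 5 cohort for the
conformity bound. Closed-form oracles (sphere volumes, lens overlap,
concentric-shell Hausdorff) are asserted within discretization tolerance
(one voxel diagonal); rank-test p-values are asserted against explicit
sign-flip / permutation enumeration at n ≤ 8.
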