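"""The study analysis pipeline.

Per-session plan scoring (coverage, conformity, homogeneity, dose outside
the targets), deterministic plan selection, evaluation of the automatic GTV
propagation, marker agreement with stratified session sampling, bladder-in-
PTV rate, workflow timing summaries and the cohort-level statistics
(paired Wilcoxon with Bonferroni correction, Mann-Whitney for group
comparisons).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import dose_metrics as dm
from .contour_metrics import ContourComparison, com_distance, compare
from .grids_structures import StructureMask, encompasses, expand, volume_cc
from .margin_targets import SIB_MARGIN_MM
from .synthetic_cohort import Cohort, SessionRecord, WORKFLOW_STEPS, session_flags

__all__ = [
    "DoseMetricsRow",
    "TestResult",
    "CohortResults",
    "evaluate_session",
    "select_plan",
    "gtv_propagation_eval",
    "marker_sample",
    "marker_com_eval",
    "paired_wilcoxon",
    "mann_whitney",
    "bonferroni_level",
    "bladder_in_ptv_rate",
    "timing_summary",
    "evaluate_cohort",
    "COMPARISON_METRICS",
]

#: the paired scheduled-vs-adaptive comparisons entering the Bonferroni family
COMPARISON_METRICS = (
    "v95_ctv_sib_pct", "v95_ptv_sib_pct", "v95_ctv_elective_pct",
    "v95_ptv_elective_pct",
    "v95out_ctv_sib_cc", "v95out_ptv_sib_cc", "v95out_ctv_elective_cc",
    "v95out_ptv_elective_cc",
    "ci_paddick_boost", "ci_paddick_elective", "hi_boost", "dmean_boost_Gy",
)

_TARGET_LEVELS = (
    ("ctv_sib", "boost"), ("ptv_sib", "boost"),
    ("ctv_elective", "elective"), ("ptv_elective", "elective"),
)


@dataclass
class DoseMetricsRow:
    """All dose-based scores of one plan in one session."""

    patient_id: str
    fraction_index: int
    plan: str
    corrected: bool
    in_training: bool
    v95_ctv_sib_pct: float = np.nan
    v95_ptv_sib_pct: float = np.nan
    v95_ctv_elective_pct: float = np.nan
    v95_ptv_elective_pct: float = np.nan
    v95out_ctv_sib_cc: float = np.nan
    v95out_ptv_sib_cc: float = np.nan
    v95out_ctv_elective_cc: float = np.nan
    v95out_ptv_elective_cc: float = np.nan
    v95_body_boost_cc: float = np.nan
    v95_body_elective_cc: float = np.nan
    ci_paddick_boost: float = np.nan
    ci_rtog_boost: float = np.nan
    ci_paddick_elective: float = np.nan
    ci_rtog_elective: float = np.nan
    hi_boost: float = np.nan
    dmean_boost_Gy: float = np.nan
    high_dose_out_boost_cc: float = np.nan
    high_dose_out_elective_cc: float = np.nan
    goals_met: int = 0

    def goal_flags(self) -> tuple[bool, ...]:
        return tuple(
            getattr(self, f"v95_{t}_pct") >= dm.COVERAGE_GOAL_PCT
            for t, _ in _TARGET_LEVELS
        )


def _score_plan(session: SessionRecord, dose, plan_name: str) -> DoseMetricsRow:
    rx = session.prescription
    levels = {"boost": rx.boost_dose_Gy, "elective": rx.elective_dose_Gy}
    t = session.targets_daily
    row = DoseMetricsRow(
        patient_id=session.patient_id, fraction_index=session.fraction_index,
        plan=plan_name, corrected=session.corrected,
        in_training=session.in_training,
    )
    for target_name, level_name in _TARGET_LEVELS:
        target = getattr(t, target_name)
        level = levels[level_name]
        _, pct = dm.v_at_threshold(dose, target, 0.95 * level)
        setattr(row, f"v95_{target_name}_pct", pct)
        setattr(row, f"v95out_{target_name}_cc",
                dm.v95_out(dose, target, session.body, level))
    row.v95_body_boost_cc = dm.v95_body_cc(dose, session.body, levels["boost"])
    row.v95_body_elective_cc = dm.v95_body_cc(dose, session.body,
                                              levels["elective"])
    row.ci_paddick_boost = dm.ci_paddick(dose, t.ptv_sib, levels["boost"],
                                         session.body)
    row.ci_rtog_boost = dm.ci_rtog(dose, t.ptv_sib, levels["boost"],
                                   session.body)
    row.ci_paddick_elective = dm.ci_paddick(dose, t.ptv_elective,
                                            levels["elective"], session.body)
    row.ci_rtog_elective = dm.ci_rtog(dose, t.ptv_elective,
                                      levels["elective"], session.body)
    row.hi_boost = dm.homogeneity_index(dose, t.ptv_sib)
    row.dmean_boost_Gy = dm.mean_dose(dose, t.ptv_sib)
    row.high_dose_out_boost_cc = dm.high_dose_outside(dose, t.ptv_sib,
                                                      levels["boost"])
    row.high_dose_out_elective_cc = dm.high_dose_outside(dose, t.ptv_elective,
                                                         levels["elective"])
    row.goals_met = sum(row.goal_flags())
    return row


def evaluate_session(session: SessionRecord) -> dict[str, DoseMetricsRow]:
    """Score the scheduled and adaptive plan of one session on the daily
    targets."""
    if session.scheduled_dose is None or session.adaptive_dose is None:
        raise ValueError("session has no dose fields (generated without doses?)")
    return {
        "scheduled": _score_plan(session, session.scheduled_dose, "scheduled"),
        "adaptive": _score_plan(session, session.adaptive_dose, "adaptive"),
    }


def select_plan(scheduled_row: DoseMetricsRow,
                adaptive_row: DoseMetricsRow) -> str:
    """Deterministic stand-in for the clinical plan choice.

    Lexicographic: more clinical goals met, then less high dose outside the
    targets, then less healthy tissue at the boost level outside the boost
    PTV; the adaptive plan wins exact ties.
    """
    def key(row: DoseMetricsRow):
        return (
            -row.goals_met,
            row.high_dose_out_boost_cc + row.high_dose_out_elective_cc,
            row.v95out_ptv_sib_cc,
        )

    return "scheduled" if key(scheduled_row) < key(adaptive_row) else "adaptive"


@dataclass
class GtvPropagationResult:
    """Geometric and dosimetric consequences of the manual GTV correction.

    Coverage percentages are V95% at the boost level of the CTV/PTV built
    from each GTV (5 + 5 mm margins), evaluated on the AI plan (optimized
    without the manual correction) and, for the clinical structures, also on
    the clinical adaptive plan.  The coverage delta — what the correction
    bought dosimetrically — is the clinical plan's coverage of the clinical
    target minus the AI plan's coverage of that same (true) target.
    """

    patient_id: str
    fraction_index: int
    corrected: bool
    contour: ContourComparison               # GTV_clin vs GTV_AI
    dvol_clin_ref_cc: float                  # volume(GTV_clin) - volume(GTV_ref)
    dvol_ai_ref_cc: float                    # volume(GTV_AI) - volume(GTV_ref)
    v95_ctv_clin_on_ai_pct: float
    v95_ptv_clin_on_ai_pct: float
    v95_ctv_ai_on_ai_pct: float
    v95_ptv_ai_on_ai_pct: float
    v95_ctv_clin_on_adaptive_pct: float
    v95_ptv_clin_on_adaptive_pct: float

    @property
    def coverage_delta_ctv(self) -> float:
        """Boost-CTV V95% gain attributable to the manual correction."""
        return self.v95_ctv_clin_on_adaptive_pct - self.v95_ctv_clin_on_ai_pct

    @property
    def coverage_delta_ptv(self) -> float:
        return self.v95_ptv_clin_on_adaptive_pct - self.v95_ptv_clin_on_ai_pct


def gtv_propagation_eval(session: SessionRecord) -> GtvPropagationResult:
    """Compare the AI-propagated GTV with the corrected clinical one.

    Contour agreement (DSC/HD/volume difference), volume difference of both
    against the planning GTV, and V95% of the boost CTV/PTV derived from
    each GTV on the AI plan dose and on the clinical adaptive plan.
    """
    if session.plan_ai_dose is None:
        raise ValueError("session lacks the AI plan dose")
    if session.adaptive_dose is None:
        raise ValueError("session lacks the adaptive dose")
    boost = session.prescription.boost_dose_Gy
    thr = 0.95 * boost
    contour = compare(session.gtv_clin, session.gtv_ai)
    v_ref = volume_cc(session.gtv_ref)

    def sib_coverage(gtv: StructureMask, dose) -> tuple[float, float]:
        ctv = expand(gtv, SIB_MARGIN_MM)
        ptv = expand(ctv, SIB_MARGIN_MM)
        _, pct_ctv = dm.v_at_threshold(dose, ctv, thr)
        _, pct_ptv = dm.v_at_threshold(dose, ptv, thr)
        return pct_ctv, pct_ptv

    ctv_clin_ai, ptv_clin_ai = sib_coverage(session.gtv_clin,
                                            session.plan_ai_dose)
    ctv_ai_ai, ptv_ai_ai = sib_coverage(session.gtv_ai, session.plan_ai_dose)
    ctv_clin_ad, ptv_clin_ad = sib_coverage(session.gtv_clin,
                                            session.adaptive_dose)
    return GtvPropagationResult(
        patient_id=session.patient_id, fraction_index=session.fraction_index,
        corrected=session.corrected, contour=contour,
        dvol_clin_ref_cc=volume_cc(session.gtv_clin) - v_ref,
        dvol_ai_ref_cc=volume_cc(session.gtv_ai) - v_ref,
        v95_ctv_clin_on_ai_pct=ctv_clin_ai,
        v95_ptv_clin_on_ai_pct=ptv_clin_ai,
        v95_ctv_ai_on_ai_pct=ctv_ai_ai,
        v95_ptv_ai_on_ai_pct=ptv_ai_ai,
        v95_ctv_clin_on_adaptive_pct=ctv_clin_ad,
        v95_ptv_clin_on_adaptive_pct=ptv_clin_ad,
    )


# ---------------------------------------------------------------------------
# statistics


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def paired_wilcoxon(x, y) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Exact distribution for <= 25 non-zero differences without ties, normal
    approximation with tie correction otherwise.  All-zero differences are
    degenerate (the statistic is undefined); flagged with p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired test needs equal-length vectors")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return TestResult(np.nan, 1.0, "degenerate", degenerate=True)
    ranks_tied = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not ranks_tied:
        res = stats.wilcoxon(x, y, zero_method="wilcox", method="exact",
                             alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue), "exact")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(x, y, zero_method="wilcox", method="approx",
                             correction=False, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue), "normal")


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney needs non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties and np.unique(pooled).size == 1:
        return TestResult(np.nan, 1.0, "degenerate", degenerate=True)
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), method)


def bonferroni_level(family_alpha: float, m: int) -> float:
    """Per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m


# ---------------------------------------------------------------------------
# marker evaluation


@dataclass
class MarkerSample:
    """Stratified session sample for the marker evaluation."""

    corrected: list
    accepted: list
    complete: bool

    def all_sessions(self) -> list:
        return list(self.corrected) + list(self.accepted)


def marker_sample(cohort, per_group: int = 20, seed: int = 0) -> MarkerSample:
    """Representative sample: per group (GTV corrected / accepted) draw at
    most one eligible session per (patient, week), training patients
    excluded, until ``per_group`` sessions are reached.

    For a lazy synthetic :class:`Cohort` the group labels come from the
    deterministic per-session flags and only the sampled sessions are
    materialized (without dose fields); any other cohort object is treated
    as a source of already-materialized sessions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    # cells[corrected][(patient, week)] -> list of sampling keys
    cells: dict[bool, dict[tuple[int, int], list]] = {True: {}, False: {}}

    if isinstance(cohort, Cohort):
        cfg = cohort.config
        patients_by_index = {p.patient_index: p for p in cohort.patients}
        for patient in cohort.patients:
            if patient.in_training:
                continue
            for fraction in range(1, cfg.n_fractions + 1):
                flags = session_flags(cfg, patient.patient_index, fraction)
                week = (fraction - 1) // 5 + 1
                cells[flags["corrected"]].setdefault(
                    (patient.patient_index, week), []).append(fraction)

        def materialize(p_idx, key):
            from .synthetic_cohort import generate_session
            return generate_session(patients_by_index[p_idx], key, cfg,
                                    compute_doses=False)
    else:
        for session in cohort.iter_sessions(compute_doses=False):
            if session.in_training:
                continue
            cells[session.corrected].setdefault(
                (session.patient_index, session.week), []).append(session)

        def materialize(p_idx, key):
            return key

    sampled = {True: [], False: []}
    complete = True
    for corrected in (True, False):
        if per_group == 0:
            continue
        keys = sorted(cells[corrected])
        rng.shuffle(keys)
        chosen = []
        for key in keys[:per_group]:
            options = cells[corrected][key]
            chosen.append((key[0], options[int(rng.integers(len(options)))]))
        if len(chosen) < per_group:
            warnings.warn(
                f"only {len(chosen)} eligible patient-weeks for "
                f"{'corrected' if corrected else 'accepted'} group "
                f"(requested {per_group})")
            complete = False
        for p_idx, key in chosen:
            sampled[corrected].append(materialize(p_idx, key))
    return MarkerSample(corrected=sampled[True], accepted=sampled[False],
                        complete=complete)


@dataclass
class MarkerEvalResult:
    dcom_corrected_mm: list
    dcom_accepted_mm: list
    median_corrected_mm: float
    median_accepted_mm: float
    median_all_mm: float
    group_test: TestResult


def marker_com_eval(sample: MarkerSample) -> MarkerEvalResult:
    """ΔCoM between propagated and manual markers, per group."""
    def dcoms(sessions):
        out = []
        for s in sessions:
            if s.markers_auto.is_empty() or s.markers_man.is_empty():
                raise ValueError(f"empty marker mask in session "
                                 f"{s.patient_id}/{s.fraction_index}")
            out.append(com_distance(s.markers_auto, s.markers_man))
        return out

    corrected = dcoms(sample.corrected)
    accepted = dcoms(sample.accepted)
    both = corrected + accepted
    return MarkerEvalResult(
        dcom_corrected_mm=corrected, dcom_accepted_mm=accepted,
        median_corrected_mm=float(np.median(corrected)) if corrected else np.nan,
        median_accepted_mm=float(np.median(accepted)) if accepted else np.nan,
        median_all_mm=float(np.median(both)) if both else np.nan,
        group_test=mann_whitney(corrected, accepted)
        if corrected and accepted else TestResult(np.nan, 1.0, "degenerate",
                                                  degenerate=True),
    )


# ---------------------------------------------------------------------------
# cohort-level aggregation


def bladder_in_ptv_rate(sessions) -> float:
    """Percent of sessions whose daily bladder is inside the planning
    elective PTV (the post-treatment position-check surrogate)."""
    flags = []
    for s in sessions:
        inside, _ = encompasses(s.ptv_elective_ref, s.bladder_daily)
        flags.append(inside)
    if not flags:
        raise ValueError("empty cohort")
    return 100.0 * float(np.mean(flags))


def _session_times_min(session: SessionRecord) -> dict:
    ts = session.timestamps_s
    prev = dict(zip(WORKFLOW_STEPS, [0.0] + [ts[s] for s in WORKFLOW_STEPS[:-1]]))
    durations = {step: (ts[step] - prev[step]) / 60.0 for step in WORKFLOW_STEPS}
    # on-couch: first daily image acquisition until end of beam delivery
    on_couch = (ts["rt"] - ts["patient_setup"]) / 60.0
    session_time = ts["patient_leaving"] / 60.0
    out = {f"step_{k}_min": v for k, v in durations.items()}
    out["on_couch_min"] = on_couch
    out["session_min"] = session_time
    return out


def _median_range(values) -> dict:
    v = np.asarray(values, float)
    return {"median": float(np.median(v)), "min": float(v.min()),
            "max": float(v.max()), "n": int(v.size)}


def timing_summary(sessions) -> dict:
    """Per-step and total timing medians/ranges, overall and by group."""
    records = []
    for s in sessions:
        for k in WORKFLOW_STEPS:
            if k not in s.timestamps_s:
                raise ValueError(f"missing timestamp '{k}' in session "
                                 f"{s.patient_id}/{s.fraction_index}")
        times = [s.timestamps_s[k] for k in WORKFLOW_STEPS]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("non-monotone timestamps")
        rec = _session_times_min(s)
        rec["in_training"] = s.in_training
        rec["corrected"] = s.corrected
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    summary = {"overall": {c: _median_range(df[c])
                           for c in df.columns if c.endswith("_min")}}
    for name, sel in [("training", df.in_training), ("steady", ~df.in_training),
                      ("corrected", df.corrected), ("accepted", ~df.corrected)]:
        sub = df[sel]
        if len(sub):
            summary[name] = {c: _median_range(sub[c])
                             for c in ("on_couch_min", "session_min")}
    tr = df[df.in_training]["session_min"]
    st = df[~df.in_training]["session_min"]
    if len(tr) and len(st):
        res = mann_whitney(tr.to_numpy(), st.to_numpy())
        summary["training_vs_steady_session_time"] = asdict(res)
    return summary


@dataclass
class CohortResults:
    """Tidy per-session metric rows plus every cohort-level summary."""

    rows: pd.DataFrame
    selected_plans: pd.DataFrame
    adaptive_all_goals_n: int
    adaptive_selection_pct: float
    bladder_in_ptv_pct: float
    stats: dict
    timing: dict
    marker_eval: MarkerEvalResult | None
    propagation: pd.DataFrame


def evaluate_cohort(cohort: Cohort, marker_per_group: int = 20,
                    family_alpha: float = 0.05,
                    n_comparisons: int = 12) -> CohortResults:
    """Run the complete analysis over a cohort (streaming the sessions)."""
    rows, selections, prop_rows = [], [], []
    bladder_flags = []
    timing_sessions = []
    for session in cohort.iter_sessions():
        scored = evaluate_session(session)
        rows.extend(asdict(scored[p]) for p in ("scheduled", "adaptive"))
        choice = select_plan(scored["scheduled"], scored["adaptive"])
        selections.append({
            "patient_id": session.patient_id,
            "fraction_index": session.fraction_index,
            "selected": choice,
        })
        inside, _ = encompasses(session.ptv_elective_ref, session.bladder_daily)
        bladder_flags.append(inside)
        if session.corrected and not session.in_training:
            prop = gtv_propagation_eval(session)
            prop_rows.append({
                "patient_id": prop.patient_id,
                "fraction_index": prop.fraction_index,
                "dsc": prop.contour.dsc,
                "hausdorff_mm": prop.contour.hausdorff_mm,
                "dvol_clin_ai_cc": prop.contour.volume_diff_cc,
                "dvol_clin_ref_cc": prop.dvol_clin_ref_cc,
                "dvol_ai_ref_cc": prop.dvol_ai_ref_cc,
                "coverage_delta_ctv": prop.coverage_delta_ctv,
                "coverage_delta_ptv": prop.coverage_delta_ptv,
            })
        timing_sessions.append(_TimingOnly(session))

    df = pd.DataFrame.from_records(rows)
    sel = pd.DataFrame.from_records(selections)
    sched = df[df.plan == "scheduled"].reset_index(drop=True)
    adapt = df[df.plan == "adaptive"].reset_index(drop=True)

    level = bonferroni_level(family_alpha, n_comparisons)
    stats_out = {"bonferroni_level": level, "family_alpha": family_alpha,
                 "n_comparisons": n_comparisons, "comparisons": {}}
    for metric in COMPARISON_METRICS:
        res = paired_wilcoxon(sched[metric].to_numpy(), adapt[metric].to_numpy())
        d = asdict(res)
        d["significant"] = bool((not res.degenerate) and res.p_value < level)
        stats_out["comparisons"][metric] = d

    marker_eval = None
    if marker_per_group > 0:
        cfg = getattr(cohort, "config", None)
        sample_seed = cfg.master_seed if cfg is not None else 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sample = marker_sample(cohort, per_group=marker_per_group,
                                   seed=sample_seed)
        marker_eval = marker_com_eval(sample)

    goals = adapt[[f"v95_{t}_pct" for t, _ in _TARGET_LEVELS]] >= dm.COVERAGE_GOAL_PCT
    return CohortResults(
        rows=df,
        selected_plans=sel,
        adaptive_all_goals_n=int(goals.all(axis=1).sum()),
        adaptive_selection_pct=100.0 * float((sel.selected == "adaptive").mean()),
        bladder_in_ptv_pct=100.0 * float(np.mean(bladder_flags)),
        stats=stats_out,
        timing=timing_summary(timing_sessions),
        marker_eval=marker_eval,
        propagation=pd.DataFrame.from_records(prop_rows),
    )


class _TimingOnly:
    """Lightweight timing/grouping view so full sessions can be freed."""

    __slots__ = ("patient_id", "fraction_index", "in_training", "corrected",
                 "timestamps_s")

    def __init__(self, session: SessionRecord):
        self.patient_id = session.patient_id
        self.fraction_index = session.fraction_index
        self.in_training = session.in_training
        self.corrected = session.corrected
        self.timestamps_s = session.timestamps_s
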