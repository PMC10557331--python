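"""Analysis pipeline: session scoring, plan selection, propagation and
marker evaluation, statistics, timing."""

import dataclasses
import itertools

import numpy as np
import pytest

from oarteval import dose_metrics as dm
from oarteval import workflow_eval as we
from oarteval.grids_structures import expand, volume_cc
from oarteval.synthetic_cohort import (
    GeneratorConfig,
    WORKFLOW_STEPS,
    generate_cohort,
    generate_session,
)


class TestEvaluateSession:
    def test_identical_doses_give_identical_rows(self, default_session):
        s = dataclasses.replace(default_session,
                                scheduled_dose=default_session.adaptive_dose)
        rows = we.evaluate_session(s)
        a = dataclasses.asdict(rows["scheduled"])
        b = dataclasses.asdict(rows["adaptive"])
        a.pop("plan"), b.pop("plan")
        assert a == b

    def test_conservation_identity_per_target(self, default_session):
        rows = we.evaluate_session(default_session)
        s = default_session
        rx = s.prescription
        for row, dose in [(rows["adaptive"], s.adaptive_dose),
                          (rows["scheduled"], s.scheduled_dose)]:
            for target_name, level in [("ctv_sib", rx.boost_dose_Gy),
                                       ("ptv_sib", rx.boost_dose_Gy),
                                       ("ctv_elective", rx.elective_dose_Gy),
                                       ("ptv_elective", rx.elective_dose_Gy)]:
                target = getattr(s.targets_daily, target_name)
                v_target, _ = dm.v_at_threshold(dose, target, 0.95 * level)
                v_body = (row.v95_body_boost_cc if level == rx.boost_dose_Gy
                          else row.v95_body_elective_cc)
                v_out = getattr(row, f"v95out_{target_name}_cc")
                assert v_body == pytest.approx(v_target + v_out, abs=1e-9)

    def test_doseless_session_rejected(self, reduced_cohort):
        s = generate_session(reduced_cohort.patients[0], 1,
                             reduced_cohort.config, compute_doses=False)
        with pytest.raises(ValueError):
            we.evaluate_session(s)


class TestSelectPlan:
    @staticmethod
    def row(goals, hot=0.0, out=10.0):
        r = we.DoseMetricsRow(patient_id="P", fraction_index=1, plan="x",
                              corrected=False, in_training=False)
        r.goals_met = goals
        r.high_dose_out_boost_cc = hot
        r.high_dose_out_elective_cc = 0.0
        r.v95out_ptv_sib_cc = out
        return r

    def test_plan_meeting_more_goals_wins(self):
        assert we.select_plan(self.row(2), self.row(4)) == "adaptive"
        assert we.select_plan(self.row(4), self.row(2)) == "scheduled"

    def test_tie_breaks_on_hot_volume_then_spill(self):
        assert we.select_plan(self.row(4, hot=5.0), self.row(4, hot=1.0)) \
            == "adaptive"
        assert we.select_plan(self.row(4, out=3.0), self.row(4, out=9.0)) \
            == "scheduled"

    def test_exact_tie_prefers_adaptive(self):
        assert we.select_plan(self.row(4), self.row(4)) == "adaptive"

    def test_adaptive_selected_on_generated_session(self, default_session):
        rows = we.evaluate_session(default_session)
        assert we.select_plan(rows["scheduled"], rows["adaptive"]) == "adaptive"


class TestGtvPropagation:
    def test_identical_gtvs_give_perfect_agreement(self, default_session):
        s = dataclasses.replace(default_session, gtv_ai=default_session.gtv_clin,
                                plan_ai_dose=default_session.adaptive_dose)
        res = we.gtv_propagation_eval(s)
        assert res.contour.dsc == 1.0
        assert res.contour.hausdorff_mm == 0.0
        assert res.contour.volume_diff_cc == 0.0
        assert res.coverage_delta_ctv == 0.0

    def test_undersegmentation_gives_positive_coverage_delta(
            self, default_session):
        # construct an under-segmented AI GTV and a plan conforming to the
        # AI-based targets: the clinical targets extend beyond the covered
        # region, so correcting the contour reveals a coverage deficit
        from oarteval.margin_targets import DirectionalMargins, build_targets
        from oarteval.synthetic_cohort import build_plan_dose
        s = default_session
        small_occ = s.gtv_clin.occupancy.copy()
        gtv_ai = dataclasses.replace(s.gtv_clin)
        gtv_ai = type(s.gtv_clin)(s.gtv_clin.grid, small_occ, "GTV_AI")
        # erode the clinical GTV by 4 mm to emulate systematic deficit
        from scipy import ndimage
        eroded = ndimage.binary_erosion(
            small_occ, iterations=2,
            structure=ndimage.generate_binary_structure(3, 1))
        gtv_ai = type(s.gtv_clin)(s.gtv_clin.grid, eroded, "GTV_AI")
        cfg = GeneratorConfig()
        # plan conforming to the AI targets only
        empty = type(s.gtv_clin)(s.gtv_clin.grid,
                                 np.zeros(s.gtv_clin.grid.shape, bool))
        ai_targets = build_targets(gtv_ai, s.bladder_daily, empty, empty,
                                   DirectionalMargins.uniform(7.0))
        ai_dose = build_plan_dose(cfg, ai_targets, s.body)
        s2 = dataclasses.replace(s, gtv_ai=gtv_ai, plan_ai_dose=ai_dose)
        res = we.gtv_propagation_eval(s2)
        assert res.contour.volume_diff_cc > 0
        assert res.coverage_delta_ptv > 0
        # enlargement never hurts the boost CTV when the AI PTV is covered
        assert res.coverage_delta_ctv >= 0


class TestStatistics:
    def test_bonferroni_level_five_percent_over_twelve(self):
        level = we.bonferroni_level(0.05, 12)
        assert level == pytest.approx(0.05 / 12)
        assert round(100 * level, 1) == 0.4  # the 0.4% working level

    def test_wilcoxon_identical_vectors_degenerate(self):
        res = we.paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_wilcoxon_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=6)
        y = x + rng.normal(0.8, 1.0, size=6)
        res = we.paired_wilcoxon(x, y)
        assert res.method == "exact"
        d = x - y
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        ws = []
        for signs in itertools.product([0, 1], repeat=6):
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.asarray(ws)
        p = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
        assert res.p_value == pytest.approx(p)

    def test_wilcoxon_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=60)
        y = x + rng.normal(0.3, 1.0, size=60)
        res = we.paired_wilcoxon(x, y)
        assert res.method == "normal"
        assert 0 < res.p_value < 1

    def test_mann_whitney_matches_permutation_enumeration(self):
        rng = np.random.default_rng(33)
        a = rng.normal(size=5)
        b = rng.normal(1.0, 1.0, size=4)
        res = we.mann_whitney(a, b)
        assert res.method == "exact"
        pooled = np.concatenate([a, b])
        n_a = len(a)

        def u_stat(sample_a, sample_b):
            return sum((x > y) + 0.5 * (x == y)
                       for x in sample_a for y in sample_b)

        u_obs = u_stat(a, b)
        us = []
        for combo in itertools.combinations(range(len(pooled)), n_a):
            mask = np.zeros(len(pooled), bool)
            mask[list(combo)] = True
            us.append(u_stat(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert res.p_value == pytest.approx(p)

    def test_mann_whitney_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            we.mann_whitney([], [1.0])


@pytest.fixture(scope="module")
def marker_cohort():
    cfg = GeneratorConfig(n_patients=4, n_fractions=10,
                          n_training_patients=1, master_seed=314)
    return generate_cohort(cfg)


class TestMarkerPipeline:
    def test_sample_respects_constraints(self, marker_cohort):
        sample = we.marker_sample(marker_cohort, per_group=4, seed=1)
        for group in (sample.corrected, sample.accepted):
            cells = [(s.patient_index, s.week) for s in group]
            assert len(cells) == len(set(cells))  # <= 1 per patient-week
            assert all(not s.in_training for s in group)
        assert all(s.corrected for s in sample.corrected)
        assert all(not s.corrected for s in sample.accepted)

    def test_sample_deterministic_under_seed(self, marker_cohort):
        a = we.marker_sample(marker_cohort, per_group=3, seed=9)
        b = we.marker_sample(marker_cohort, per_group=3, seed=9)
        key = lambda smp: [(s.patient_index, s.fraction_index)
                           for s in smp.all_sessions()]
        assert key(a) == key(b)

    def test_zero_per_group_gives_empty_sample(self, marker_cohort):
        sample = we.marker_sample(marker_cohort, per_group=0, seed=1)
        assert sample.all_sessions() == []

    def test_insufficient_sessions_flagged(self, marker_cohort):
        with pytest.warns(UserWarning, match="eligible"):
            sample = we.marker_sample(marker_cohort, per_group=50, seed=1)
        assert not sample.complete

    def test_group_offset_medians_recovered(self, marker_cohort):
        sample = we.marker_sample(marker_cohort, per_group=8, seed=2)
        result = we.marker_com_eval(sample)
        cfg = marker_cohort.config
        # lognormal medians configured per group; n=8 -> generous bounds
        assert result.median_corrected_mm == pytest.approx(
            cfg.marker_offset_median_corrected_mm, rel=0.5)
        assert result.median_accepted_mm == pytest.approx(
            cfg.marker_offset_median_accepted_mm, rel=0.5)


class TestTimingAndRates:
    def test_constructed_timestamps_recovered_exactly(self):
        base = {step: 60.0 * (i + 1) for i, step in enumerate(WORKFLOW_STEPS)}

        class S:
            patient_id = "P06"
            fraction_index = 1
            in_training = False
            corrected = False
            timestamps_s = base

        summary = we.timing_summary([S()])
        # each step lasts exactly one minute in the constructed session
        assert summary["overall"]["step_rt_min"]["median"] == 1.0
        on_couch = (base["rt"] - base["patient_setup"]) / 60.0
        assert summary["overall"]["on_couch_min"]["median"] == on_couch
        assert summary["overall"]["session_min"]["median"] == \
            base["patient_leaving"] / 60.0

    def test_single_session_median_is_that_session(self, reduced_cohort):
        s = generate_session(reduced_cohort.patients[0], 1,
                             reduced_cohort.config, compute_doses=False)
        summary = we.timing_summary([s])
        assert summary["overall"]["session_min"]["min"] == \
            summary["overall"]["session_min"]["max"]

    def test_missing_step_rejected(self):
        class S:
            patient_id = "P"
            fraction_index = 1
            in_training = False
            corrected = False
            timestamps_s = {"patient_setup": 60.0}

        with pytest.raises(ValueError, match="missing timestamp"):
            we.timing_summary([S()])

    def test_bladder_rate_trivial_cases(self, reduced_cohort):
        s = generate_session(reduced_cohort.patients[0], 1,
                             reduced_cohort.config, compute_doses=False)
        inside = dataclasses.replace(
            s, bladder_daily=s.bladder_daily.intersection(s.ptv_elective_ref))
        assert we.bladder_in_ptv_rate([inside]) == 100.0
        protruding = dataclasses.replace(
            s, bladder_daily=expand(s.bladder_daily, 25.0))
        assert we.bladder_in_ptv_rate([inside, protruding]) == 50.0
        with pytest.raises(ValueError):
            we.bladder_in_ptv_rate([])


class TestCohortEvaluation:
    def test_full_pipeline_on_tiny_cohort(self):
        cfg = GeneratorConfig(n_patients=2, n_fractions=3,
                              n_training_patients=1, master_seed=1001)
        cohort = generate_cohort(cfg)
        res = we.evaluate_cohort(cohort, marker_per_group=2)
        assert len(res.rows) == 2 * cohort.n_sessions
        assert res.adaptive_all_goals_n == cohort.n_sessions
        assert set(res.selected_plans.selected) <= {"scheduled", "adaptive"}
        assert res.stats["bonferroni_level"] == pytest.approx(0.05 / 12)
        assert 0.0 <= res.bladder_in_ptv_pct <= 100.0
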