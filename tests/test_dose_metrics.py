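"""Dose scoring: coverage, conformity, homogeneity, DVH, normalization."""

import numpy as np
import pytest

from oarteval import dose_metrics as dm
from oarteval.grids_structures import (
    DoseGrid,
    StructureMask,
    digitize_sphere,
    expand,
    volume_cc,
)


@pytest.fixture
def ptv(grid2mm):
    return digitize_sphere(grid2mm, (0, 0, 0), 12.0, "PTV")


@pytest.fixture
def body(grid2mm):
    return digitize_sphere(grid2mm, (0, 0, 0), 28.0, "body")


def uniform_dose(grid, value):
    return DoseGrid(grid, np.full(grid.shape, float(value)))


def dose_on(mask, inside_Gy, outside_Gy=0.0):
    data = np.where(mask.occupancy, float(inside_Gy), float(outside_Gy))
    return DoseGrid(mask.grid, data)


class TestCoverage:
    def test_threshold_is_inclusive(self, grid2mm, ptv):
        dose = uniform_dose(grid2mm, 52.25)
        _, pct = dm.v_at_threshold(dose, ptv, 52.25)
        assert pct == 100.0

    def test_just_below_threshold_counts_zero(self, grid2mm, ptv):
        dose = uniform_dose(grid2mm, 52.2499)
        _, pct = dm.v_at_threshold(dose, ptv, 52.25)
        assert pct == 0.0

    def test_matches_bruteforce_recount(self, grid2mm, ptv):
        rng = np.random.default_rng(5)
        dose = DoseGrid(grid2mm, rng.uniform(0, 60, grid2mm.shape))
        thr = 0.95 * 55
        vol, pct = dm.v_at_threshold(dose, ptv, thr)
        expected_n = int(np.sum((dose.dose_Gy >= thr) & ptv.occupancy))
        assert vol == pytest.approx(expected_n * grid2mm.voxel_volume_cc)
        assert pct == pytest.approx(100.0 * expected_n / ptv.voxel_count)

    def test_empty_mask_rejected(self, grid2mm):
        empty = StructureMask(grid2mm, np.zeros(grid2mm.shape, bool))
        with pytest.raises(ValueError):
            dm.v_at_threshold(uniform_dose(grid2mm, 10), empty, 5)


class TestV95Out:
    def test_dose_confined_to_target_gives_zero(self, ptv, body):
        dose = dose_on(ptv, 55.0)
        assert dm.v95_out(dose, ptv, body, 55.0) == 0.0

    def test_uniform_dose_gives_body_minus_target(self, grid2mm, ptv, body):
        dose = uniform_dose(grid2mm, 55.0)
        expected = volume_cc(body) - volume_cc(ptv)
        assert dm.v95_out(dose, ptv, body, 55.0) == pytest.approx(expected)

    def test_conservation_identity_on_random_dose(self, grid2mm, ptv, body):
        rng = np.random.default_rng(9)
        dose = DoseGrid(grid2mm, rng.uniform(0, 60, grid2mm.shape))
        thr = 0.95 * 55
        v_target, _ = dm.v_at_threshold(dose, ptv, thr)
        v_body = dm.v95_body_cc(dose, body, 55.0)
        assert v_body == pytest.approx(
            v_target + dm.v95_out(dose, ptv, body, 55.0), abs=1e-9)

    def test_target_outside_body_rejected(self, grid2mm, body):
        outside = digitize_sphere(grid2mm, (25, 0, 0), 10.0)
        with pytest.raises(ValueError, match="not contained"):
            dm.v95_out(uniform_dose(grid2mm, 10), outside, body, 55.0)


class TestConformity:
    def test_rtog_is_one_for_exact_isodose(self, ptv, body):
        dose = dose_on(ptv, 55.0)
        assert dm.ci_rtog(dose, ptv, 55.0, body) == pytest.approx(1.0)

    def test_rtog_ratio_for_expanded_isodose(self, ptv, body):
        grown = expand(ptv, 5.0)
        dose = dose_on(grown, 55.0)
        expected = volume_cc(grown) / volume_cc(ptv)
        assert dm.ci_rtog(dose, ptv, 55.0, body) == pytest.approx(expected)

    def test_rtog_bounded_below_by_target_coverage(self, grid2mm, ptv, body):
        rng = np.random.default_rng(2)
        dose = DoseGrid(grid2mm, rng.uniform(40, 60, grid2mm.shape))
        _, pct = dm.v_at_threshold(dose, ptv, 0.95 * 55)
        assert dm.ci_rtog(dose, ptv, 55.0, body) >= pct / 100.0

    def test_paddick_is_one_for_exact_isodose(self, ptv, body):
        dose = dose_on(ptv, 55.0)
        assert dm.ci_paddick(dose, ptv, 55.0, body) == pytest.approx(1.0)

    def test_paddick_equals_tv_over_piv_for_expanded_isodose(self, ptv, body):
        grown = expand(ptv, 5.0)
        dose = dose_on(grown, 55.0)
        expected = volume_cc(ptv) / volume_cc(grown)
        assert dm.ci_paddick(dose, ptv, 55.0, body) == pytest.approx(expected)

    def test_paddick_never_exceeds_one(self, grid2mm, ptv, body):
        rng = np.random.default_rng(4)
        for seed in range(5):
            dose = DoseGrid(grid2mm, rng.uniform(0, 60, grid2mm.shape))
            assert dm.ci_paddick(dose, ptv, 55.0, body) <= 1.0

    def test_matches_bruteforce_voxel_counting(self, grid2mm, ptv, body):
        rng = np.random.default_rng(8)
        dose = DoseGrid(grid2mm, rng.uniform(40, 60, grid2mm.shape))
        thr = 0.95 * 55
        piv = (dose.dose_Gy >= thr) & body.occupancy
        tv = ptv.voxel_count
        piv_n = piv.sum()
        tv_piv = (piv & ptv.occupancy).sum()
        assert dm.ci_rtog(dose, ptv, 55.0, body) == pytest.approx(piv_n / tv)
        assert dm.ci_paddick(dose, ptv, 55.0, body) == pytest.approx(
            tv_piv**2 / (tv * piv_n))


class TestDvh:
    def test_uniform_dose_percentiles_and_mean(self, grid2mm, ptv):
        dose = uniform_dose(grid2mm, 42.0)
        for pct in (2, 50, 98, 100):
            assert dm.d_at_volume(dose, ptv, pct) == 42.0
        assert dm.mean_dose(dose, ptv) == 42.0

    def test_percentile_monotonicity(self, grid2mm, ptv):
        rng = np.random.default_rng(12)
        dose = DoseGrid(grid2mm, rng.uniform(0, 60, grid2mm.shape))
        d100 = dm.d_at_volume(dose, ptv, 100)
        d50 = dm.d_at_volume(dose, ptv, 50)
        d2 = dm.d_at_volume(dose, ptv, 2)
        assert d100 <= d50 <= d2

    def test_mean_equals_integral_of_cumulative_dvh(self, grid2mm, ptv):
        rng = np.random.default_rng(13)
        dose = DoseGrid(grid2mm, rng.uniform(0, 60, grid2mm.shape))
        vals = np.sort(dose.dose_Gy[ptv.occupancy])
        # integral of the cumulative DVH (fraction >= d) over d equals the mean
        grid_d = np.linspace(0, vals.max(), 20000)
        frac = np.searchsorted(vals, grid_d, side="left")
        cum = 1.0 - frac / vals.size
        integral = np.trapezoid(cum, grid_d)
        assert integral == pytest.approx(dm.mean_dose(dose, ptv), rel=1e-3)

    def test_homogeneity_zero_for_uniform_dose(self, grid2mm, ptv):
        assert dm.homogeneity_index(uniform_dose(grid2mm, 55), ptv) == 0.0

    def test_homogeneity_of_linear_ramp_matches_uniform_percentiles(
            self, grid2mm, ptv):
        # dose rises linearly across the sphere: the dose distribution over
        # the mask is that of the x-coordinate, so Dx% follows the geometric
        # quantiles; compute the oracle directly from the voxel multiset
        xs = grid2mm.coordinate_axes()[0]
        data = np.broadcast_to(50.0 + 0.5 * xs[:, None, None],
                               grid2mm.shape).copy()
        dose = DoseGrid(grid2mm, data)
        vals = np.sort(data[ptv.occupancy])[::-1]
        n = vals.size
        d2 = vals[int(np.ceil(0.02 * n)) - 1]
        d50 = vals[int(np.ceil(0.50 * n)) - 1]
        d98 = vals[int(np.ceil(0.98 * n)) - 1]
        assert dm.homogeneity_index(dose, ptv) == pytest.approx(
            (d2 - d98) / d50)

    def test_homogeneity_invariant_under_scaling(self, grid2mm, ptv):
        rng = np.random.default_rng(17)
        dose = DoseGrid(grid2mm, rng.uniform(40, 60, grid2mm.shape))
        hi = dm.homogeneity_index(dose, ptv)
        assert dm.homogeneity_index(dose.scaled(1.7), ptv) == pytest.approx(hi)


class TestNormalization:
    def test_uniform_50Gy_scales_by_1045(self, grid2mm, ptv):
        dose = uniform_dose(grid2mm, 50.0)
        out = dm.normalize_plan(dose, ptv, dm.Prescription())
        # s = 0.95 * 55 / 50 = 1.045
        assert out.dose_Gy[0, 0, 0] == pytest.approx(50.0 * 1.045)

    def test_already_normalized_plan_unchanged(self, grid2mm, ptv):
        dose = uniform_dose(grid2mm, 0.95 * 55.0)
        out = dm.normalize_plan(dose, ptv, dm.Prescription())
        np.testing.assert_allclose(out.dose_Gy, dose.dose_Gy, rtol=1e-8)

    def test_idempotent(self, grid2mm, ptv):
        rng = np.random.default_rng(21)
        dose = DoseGrid(grid2mm, rng.uniform(30, 60, grid2mm.shape))
        once = dm.normalize_plan(dose, ptv, dm.Prescription())
        twice = dm.normalize_plan(once, ptv, dm.Prescription())
        np.testing.assert_allclose(twice.dose_Gy, once.dose_Gy, rtol=1e-8)

    def test_coverage_is_98pct_after_normalization(self, grid2mm, ptv):
        rng = np.random.default_rng(22)
        dose = DoseGrid(grid2mm, rng.uniform(45, 60, grid2mm.shape))
        rx = dm.Prescription()
        out = dm.normalize_plan(dose, ptv, rx)
        _, pct = dm.v_at_threshold(out, ptv, 0.95 * rx.boost_dose_Gy)
        step = 100.0 / ptv.voxel_count
        assert 98.0 <= pct < 98.0 + step

    def test_zero_d98_rejected(self, grid2mm, ptv):
        with pytest.raises(ValueError):
            dm.normalize_plan(uniform_dose(grid2mm, 0.0), ptv,
                              dm.Prescription())


class TestGoalsAndHotspots:
    def test_uniform_prescription_passes_goal(self, grid2mm, ptv):
        assert dm.clinical_goal_pass(uniform_dose(grid2mm, 55.0), ptv, 55.0)

    def test_zero_dose_fails_goal(self, grid2mm, ptv):
        assert not dm.clinical_goal_pass(uniform_dose(grid2mm, 0.0), ptv, 55.0)

    def test_goal_boundary_is_inclusive_at_exactly_98pct(self, grid2mm):
        # engineered mask of 50 voxels, exactly 49 covered -> 98.0%
        occ = np.zeros(grid2mm.shape, bool)
        occ.flat[:50] = True
        mask = StructureMask(grid2mm, occ)
        data = np.zeros(grid2mm.shape)
        data.flat[:49] = 55.0
        dose = DoseGrid(grid2mm, data)
        _, pct = dm.v_at_threshold(dose, mask, 0.95 * 55)
        assert pct == 98.0
        assert dm.clinical_goal_pass(dose, mask, 55.0)

    def test_hot_spot_outside_target_measured(self, grid2mm, ptv):
        hot = digitize_sphere(grid2mm, (20, 0, 0), 5.0)
        data = np.where(hot.occupancy, 1.08 * 55.0, 55.0)
        dose = DoseGrid(grid2mm, data)
        assert dm.high_dose_outside(dose, ptv, 55.0) == pytest.approx(
            volume_cc(hot))

    def test_hot_spot_inside_target_ignored(self, grid2mm, ptv):
        data = np.where(ptv.occupancy, 1.2 * 55.0, 50.0)
        dose = DoseGrid(grid2mm, data)
        assert dm.high_dose_outside(dose, ptv, 55.0) == 0.0

    def test_107pct_rule_is_strict(self, grid2mm, ptv):
        dose = uniform_dose(grid2mm, 1.07 * 55.0)
        assert dm.high_dose_outside(dose, ptv, 55.0) == 0.0


def test_prescription_levels():
    rx = dm.Prescription()
    assert rx.boost_dose_Gy == rx.elective_dose_Gy + rx.sib_increment_Gy == 55.0
    with pytest.raises(ValueError):
        dm.Prescription(elective_dose_Gy=-1)
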