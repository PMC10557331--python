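"""Shared fixtures: small analytic grids and a reduced synthetic cohort.

The reduced cohort (5 patients x 5 fractions, 2 training patients) is the
scaled-down stand-in for the full 15 x 20 study used wherever a cohort-level
property is checked; heavy per-session quantities are collected in one
streaming pass and shared session-wide.
"""

import numpy as np
import pytest
from hypothesis import settings

from oarteval.dose_metrics import Prescription
from oarteval.grids_structures import VoxelGrid, digitize_sphere
from oarteval.synthetic_cohort import (
    GeneratorConfig,
    generate_cohort,
    generate_session,
)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def grid2mm():
    """Small 2 mm grid centered on the origin."""
    return VoxelGrid(shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0),
                     origin=(-31.0, -31.0, -31.0))


@pytest.fixture
def grid1mm():
    """Finer 1 mm grid for closed-form sphere oracles."""
    return VoxelGrid(shape=(56, 56, 56), spacing=(1.0, 1.0, 1.0),
                     origin=(-27.5, -27.5, -27.5))


@pytest.fixture
def sphere20(grid1mm):
    return digitize_sphere(grid1mm, (0, 0, 0), 20.0, "sphere20")


@pytest.fixture(scope="session")
def reduced_config():
    return GeneratorConfig(n_patients=5, n_fractions=5,
                           n_training_patients=2, master_seed=20260922)


@pytest.fixture(scope="session")
def reduced_cohort(reduced_config):
    return generate_cohort(reduced_config)


@pytest.fixture(scope="session")
def default_session(reduced_cohort):
    """One fully generated session (daily anatomy + all three dose fields)."""
    return generate_session(reduced_cohort.patients[2], 1,
                            reduced_cohort.config)


@pytest.fixture(scope="session")
def reduced_session_stats(reduced_cohort):
    """One streaming pass over the reduced cohort collecting the per-session
    quantities several cohort-level tests need."""
    from oarteval import dose_metrics as dm
    from oarteval.grids_structures import encompasses

    cfg = reduced_cohort.config
    rx = cfg.prescription
    stats = {
        "conservation_residual_cc": [],
        "goal_flags": [],
        "ci_rtog_boost": [],
        "bladder_inside": [],
        "corrected": [],
        "deficit_cc": [],
    }
    for s in reduced_cohort.iter_sessions():
        t = s.targets_daily
        for target, level in [(t.ctv_sib, rx.boost_dose_Gy),
                              (t.ptv_sib, rx.boost_dose_Gy),
                              (t.ctv_elective, rx.elective_dose_Gy),
                              (t.ptv_elective, rx.elective_dose_Gy)]:
            for dose in (s.scheduled_dose, s.adaptive_dose):
                thr = 0.95 * level
                # independent recount of the conservation identity
                v_body = dm.v95_body_cc(dose, s.body, level)
                v_target, _ = dm.v_at_threshold(dose, target, thr)
                v_out = dm.v95_out(dose, target, s.body, level)
                stats["conservation_residual_cc"].append(
                    v_body - (v_target + v_out))
        flags = tuple(
            dm.clinical_goal_pass(s.adaptive_dose, target, level)
            for target, level in [(t.ctv_sib, rx.boost_dose_Gy),
                                  (t.ptv_sib, rx.boost_dose_Gy),
                                  (t.ctv_elective, rx.elective_dose_Gy),
                                  (t.ptv_elective, rx.elective_dose_Gy)])
        stats["goal_flags"].append(flags)
        stats["ci_rtog_boost"].append(
            dm.ci_rtog(s.adaptive_dose, t.ptv_sib, rx.boost_dose_Gy, s.body))
        inside, _ = encompasses(s.ptv_elective_ref, s.bladder_daily)
        stats["bladder_inside"].append(inside)
        stats["corrected"].append(s.corrected)
        from oarteval.grids_structures import volume_cc
        if s.corrected:
            stats["deficit_cc"].append(
                volume_cc(s.gtv_clin) - volume_cc(s.gtv_ai))
    return stats
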