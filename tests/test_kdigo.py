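"""Baseline determination, KDIGO AKI staging (vs an exhaustive oracle), and
category classification."""

import itertools
from datetime import datetime, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from akdscreen.errors import UsageError, ValidationError
from akdscreen.kdigo import (
    BaselineProvenance,
    BaselineResult,
    Category,
    RecoveryStatus,
    RecoveryTimepoint,
    assess_recovery,
    ckd_transition_at_followup,
    classify,
    determine_baseline,
    stage_aki,
    staging_detail,
)
from akdscreen.kidney_function import CreatinineMeasurement, CreatinineSeries, Demographics

ADMISSION = datetime(2019, 6, 1, 8, 0)


def meas(value, hours, context="inadm", source="poc"):
    return CreatinineMeasurement(value, ADMISSION + timedelta(hours=hours), source, context)


def series(*ms):
    return CreatinineSeries(ms)


def admission_series(values, hours):
    """All-in-admission series: first point is the enrollment measurement."""
    ctx = ["enrol"] + ["inadm"] * (len(values) - 1)
    return series(*(meas(v, h, c) for v, h, c in zip(values, hours, ctx)))


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------
class TestDetermineBaseline:
    def test_pre_admission_beats_higher_nadir(self):
        s = series(meas(1.0, -30 * 24, "pre"), meas(1.5, 0, "enrol"), meas(1.2, 48, "inadm"))
        b = determine_baseline(s, ADMISSION)
        assert (b.value, b.provenance) == (1.0, BaselineProvenance.COMBINED_MIN)
        # pre-admission candidate won: the AKI window anchors at its time
        assert b.window_anchor == ADMISSION + timedelta(hours=-30 * 24)

    def test_in_admission_nadir_without_pre(self):
        s = admission_series([2.0, 1.4, 1.6], [0, 24, 48])
        b = determine_baseline(s, ADMISSION)
        assert (b.value, b.provenance) == (1.4, BaselineProvenance.IN_ADMISSION_NADIR)
        assert b.window_anchor == ADMISSION  # first admission measurement

    def test_singleton_enrollment_is_its_own_nadir(self):
        b = determine_baseline(series(meas(1.8, 0, "enrol")), ADMISSION)
        assert (b.value, b.provenance) == (1.8, BaselineProvenance.IN_ADMISSION_NADIR)

    def test_pre_admission_outside_lookback_ignored(self):
        s = series(meas(0.9, -400 * 24, "pre"), meas(1.6, 0, "enrol"))
        b = determine_baseline(s, ADMISSION, lookback_days=365)
        assert b.provenance == BaselineProvenance.IN_ADMISSION_NADIR
        assert b.value == 1.6

    def test_never_exceeds_candidate_minimum(self):
        s = series(meas(1.1, -20 * 24, "pre"), meas(0.9, 0, "enrol"), meas(1.3, 24, "inadm"))
        b = determine_baseline(s, ADMISSION)
        assert b.value == min(1.1, 0.9)
        # in-admission candidate won: rolling anchor at first admission point
        assert b.window_anchor == ADMISSION

    def test_pre_admission_preferred_policy(self):
        s = series(meas(1.1, -20 * 24, "pre"), meas(0.9, 0, "enrol"))
        b = determine_baseline(s, ADMISSION, policy="pre_admission_preferred")
        assert (b.value, b.provenance) == (1.1, BaselineProvenance.PRE_ADMISSION_LATEST)

    def test_followup_only_series_has_no_baseline(self):
        b = determine_baseline(series(meas(1.0, 90 * 24, "fup")), ADMISSION)
        assert not b.available
        assert b.provenance == BaselineProvenance.UNAVAILABLE

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            determine_baseline(series(), ADMISSION)


# ---------------------------------------------------------------------------
# staging: spot examples
# ---------------------------------------------------------------------------
def fixed_baseline(value=1.0, anchor_hours=0.0):
    return BaselineResult(
        value, BaselineProvenance.IN_ADMISSION_NADIR, ADMISSION + timedelta(hours=anchor_hours)
    )


class TestStageAki:
    def test_absolute_rise_within_48h_is_stage_1(self):
        s = admission_series([1.0, 1.4], [0, 24])
        assert stage_aki(s, fixed_baseline(1.0)) == 1

    def test_ratio_3x_is_stage_3(self):
        s = admission_series([1.0, 3.2], [0, 72])
        assert stage_aki(s, fixed_baseline(1.0)) == 3

    def test_below_all_thresholds_is_stage_0(self):
        s = admission_series([1.0, 1.2], [0, 72])
        assert stage_aki(s, fixed_baseline(1.0)) == 0

    def test_krt_forces_stage_3(self):
        s = admission_series([1.0, 1.1], [0, 24])
        assert stage_aki(s, fixed_baseline(1.0), krt_initiated=True) == 3

    def test_stage_2_band(self):
        s = admission_series([1.0, 2.5], [0, 24])
        assert stage_aki(s, fixed_baseline(1.0)) == 2

    def test_value_ge_4_with_acute_rise_is_stage_3(self):
        # ratio 4.2/1.8 = 2.33 (stage 2 band) but absolute >= 4.0 with an
        # acute rise present escalates to stage 3
        s = admission_series([1.8, 4.2], [0, 24])
        d = staging_detail(s, fixed_baseline(1.8))
        assert d.stage == 3
        assert "scr_ge_4.0mgdl_with_acute_rise" in d.criteria

    def test_stable_high_value_without_acute_rise_is_not_aki(self):
        # flat 4.5 against its own nadir: no rise, ratio 1 -> not AKI
        s = admission_series([4.5, 4.5], [0, 72])
        b = determine_baseline(s, ADMISSION)
        assert stage_aki(s, b) == 0

    def test_ratio_outside_7day_window_does_not_fire(self):
        s = admission_series([1.0, 1.8], [0, 200])
        # anchor at t=0; 200 h > 168 h, and the rise is not within 48 h
        assert stage_aki(s, fixed_baseline(1.0)) == 0

    def test_unavailable_baseline_gives_stage_0_with_flag(self):
        s = admission_series([2.0], [0])
        d = staging_detail(s, BaselineResult(None, BaselineProvenance.UNAVAILABLE))
        assert d.stage == 0
        assert "baseline_unavailable" in d.criteria

    def test_old_pre_admission_baseline_does_not_anchor_admission_window(self):
        """Elevated-but-flat admission values against an old outpatient
        baseline are not AKI (duration unknown, sub-acute)."""
        s = series(meas(1.0, -60 * 24, "pre"), meas(1.9, 0, "enrol"), meas(1.9, 72, "inadm"))
        b = determine_baseline(s, ADMISSION)
        assert b.value == 1.0
        assert stage_aki(s, b) == 0

    def test_recovered_admission_with_matching_pre_baseline_detects_aki(self):
        """Nadir ties the pre-admission value: window anchors in-admission and
        the enrollment peak fires the ratio criterion."""
        s = series(
            meas(1.0, -60 * 24, "pre"),
            meas(2.1, 0, "enrol"),
            meas(1.0, 96, "disch"),
        )
        b = determine_baseline(s, ADMISSION)
        assert stage_aki(s, b) == 2


# ---------------------------------------------------------------------------
# staging: exhaustive oracle equivalence
# ---------------------------------------------------------------------------
SCR_GRID = (0.5, 1.0, 1.5, 2.0, 3.0, 4.5)
TIME_GRID_H = (0, 24, 72, 200)


def oracle_stage(values, hours, baseline, anchor_h, krt=False):
    """Independent rule-by-rule staging evaluator (plain loops)."""
    if krt:
        return 3
    if baseline is None:
        return 0
    rise = False
    for i in range(len(values)):
        for j in range(i + 1, len(values)):
            if hours[j] - hours[i] <= 48 and values[j] - values[i] >= 0.3:
                rise = True
    ratio = False
    for v, h in zip(values, hours):
        if v >= 1.5 * baseline and anchor_h <= h <= anchor_h + 7 * 24:
            ratio = True
    if not (rise or ratio):
        return 0
    stage = 1
    for v in values:
        if v / baseline >= 3.0 or v >= 4.0:
            stage = max(stage, 3)
        elif v / baseline >= 2.0:
            stage = max(stage, 2)
    return stage


def all_grid_series():
    for k in range(1, len(TIME_GRID_H) + 1):
        for hours in itertools.combinations(TIME_GRID_H, k):
            for values in itertools.product(SCR_GRID, repeat=k):
                yield values, hours


def test_staging_matches_exhaustive_oracle_with_computed_baseline():
    """All <= 4-point admission series on the grid, baseline = in-admission
    nadir (anchor: first measurement)."""
    n = 0
    for values, hours in all_grid_series():
        s = admission_series(values, hours)
        b = determine_baseline(s, ADMISSION)
        expected = oracle_stage(values, hours, b.value, anchor_h=hours[0])
        assert stage_aki(s, b) == expected, (values, hours)
        n += 1
    assert n == 2400


def test_staging_matches_exhaustive_oracle_with_fixed_baseline():
    """Same grid against an externally supplied baseline of 1.0 anchored at 0."""
    b = fixed_baseline(1.0, anchor_hours=0.0)
    for values, hours in all_grid_series():
        s = admission_series(values, hours)
        expected = oracle_stage(values, hours, 1.0, anchor_h=0.0)
        assert stage_aki(s, b) == expected, (values, hours)


@given(
    values=st.lists(st.sampled_from(SCR_GRID), min_size=1, max_size=4),
    bump_idx=st.integers(0, 3),
    bump=st.sampled_from([0.5, 1.0, 2.0]),
)
def test_staging_monotone_in_measurement_increase(values, bump_idx, bump):
    """Increasing any measurement never decreases the stage (fixed baseline)."""
    hours = TIME_GRID_H[: len(values)]
    b = fixed_baseline(1.0)
    s1 = admission_series(values, hours)
    bumped = list(values)
    i = bump_idx % len(values)
    bumped[i] = bumped[i] + bump
    s2 = admission_series(bumped, hours)
    assert stage_aki(s2, b) >= stage_aki(s1, b)


# ---------------------------------------------------------------------------
# classification, recovery, CKD transition
# ---------------------------------------------------------------------------
DEMO = Demographics(50, "male")


class TestClassify:
    def test_any_aki_stage_wins_regardless_of_chronicity(self):
        s = admission_series([1.0, 2.2], [0, 24])
        b = determine_baseline(s, ADMISSION)
        c = classify(s, DEMO, b, aki_stage=2, chronicity_evidence=True)
        assert c.category is Category.AKD_WITH_AKI
        assert c.aki_stage == 2

    def test_low_egfr_presumed_acute_is_akd_without_aki(self):
        s = admission_series([1.8], [0])  # eGFR ~ 45 for a 50 y male
        b = determine_baseline(s, ADMISSION)
        c = classify(s, DEMO, b, aki_stage=0, chronicity_evidence=None)
        assert c.category is Category.AKD_WITHOUT_AKI
        assert 40 < c.enrollment_egfr < 60
        assert "duration_unknown_presumed_acute" in c.criteria_fired

    def test_low_egfr_with_documented_chronicity_is_ckd(self):
        s = admission_series([1.8], [0])
        b = determine_baseline(s, ADMISSION)
        c = classify(s, DEMO, b, aki_stage=0, chronicity_evidence=True)
        assert c.category is Category.CKD

    def test_normal_egfr_stage0_is_nkd(self):
        s = admission_series([0.9], [0])
        b = determine_baseline(s, ADMISSION)
        c = classify(s, DEMO, b, aki_stage=0)
        assert c.category is Category.NKD
        assert c.enrollment_egfr > 60

    def test_exactly_one_category_over_input_sweep(self):
        """Classification is total and mutually exclusive on a broad sweep."""
        for scr in (0.6, 1.0, 1.5, 2.4, 4.0):
            for stage in (0, 1, 3):
                for chron in (None, True, False):
                    s = admission_series([scr], [0])
                    b = determine_baseline(s, ADMISSION)
                    c = classify(s, DEMO, b, stage, chron)
                    assert isinstance(c.category, Category)
                    assert (c.aki_stage >= 1) == (c.category is Category.AKD_WITH_AKI)


class TestRecovery:
    def akd(self, scr=2.0):
        s = admission_series([scr], [0])
        b = determine_baseline(s, ADMISSION)
        # force an AKD classification with a 1.0 reference baseline
        bl = fixed_baseline(1.0)
        return classify(s, DEMO, bl, aki_stage=1), bl

    @pytest.mark.parametrize(
        "fup_scr, status",
        [
            (None, RecoveryStatus.UNKNOWN),
            (1.1, RecoveryStatus.COMPLETE),
            (1.8, RecoveryStatus.NONE),
            (1.3, RecoveryStatus.NONE),  # >= baseline + 0.3
            (1.27, RecoveryStatus.INCOMPLETE),
        ],
    )
    def test_status_thresholds(self, fup_scr, status):
        c, bl = self.akd()
        r = assess_recovery(c, bl, fup_scr, RecoveryTimepoint.DAY90)
        assert r.status is status
        assert r.timepoint is RecoveryTimepoint.DAY90

    def test_usage_error_for_non_akd(self):
        s = admission_series([0.9], [0])
        b = determine_baseline(s, ADMISSION)
        c = classify(s, DEMO, b, 0)
        assert c.category is Category.NKD
        with pytest.raises(UsageError):
            assess_recovery(c, b, 1.0, RecoveryTimepoint.DISCHARGE)


class TestCkdTransition:
    def test_threshold_and_missing(self):
        c, _ = TestRecovery().akd()
        assert ckd_transition_at_followup(c, 45.0) is True
        assert ckd_transition_at_followup(c, 75.0) is False
        assert ckd_transition_at_followup(c, None) is None

    def test_usage_error_for_nkd(self):
        s = admission_series([0.9], [0])
        b = determine_baseline(s, ADMISSION)
        c = classify(s, DEMO, b, 0)
        with pytest.raises(UsageError):
            ckd_transition_at_followup(c, 50.0)
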