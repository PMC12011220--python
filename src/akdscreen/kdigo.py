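"""Baseline creatinine, KDIGO AKI staging, and AKD/CKD/NKD classification.

The classification operationalises the KDIGO functional criteria on serum
creatinine only (urine output and urinalysis are not part of the record):

* **Baseline creatinine** is the minimum of (a) the latest documented value
  before admission within a look-back window and (b) the lowest value during
  the admission. No baseline is ever imputed from an assumed eGFR.
* **AKI** is present when creatinine rises by >= 0.3 mg/dL between two
  measurements <= 48 h apart, or when any value reaches >= 1.5x baseline
  within 7 days of the baseline anchor. Stages: 1 for ratio in [1.5, 2.0) or
  the absolute-rise criterion alone; 2 for [2.0, 3.0); 3 for >= 3.0, for a
  value >= 4.0 mg/dL with an acute-rise criterion also met, or when kidney
  replacement therapy is initiated.
* **Category**: AKI of any stage -> AKD with AKI. Otherwise kidney
  dysfunction (enrollment eGFR < 60 or SCr > 1.5x baseline) of duration
  < 90 days or unknown -> AKD without AKI; documented duration >= 90 days
  with eGFR < 60 -> CKD; else NKD (no kidney disease).

Because true AKI onset is unobserved, the 7-day window for the 1.5x
criterion is anchored at the pre-admission baseline measurement when that
measurement defines the baseline, and otherwise at the first in-admission
measurement (a rolling, presumed-recent-onset reading). Ties between the two
baseline candidates anchor in-admission, so a fully recovered admission
remains assessable for AKI.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

from .errors import UsageError, ValidationError
from .kidney_function import (
    ADMISSION_CONTEXTS,
    Context,
    CreatinineSeries,
    Demographics,
    GfrEquationParams,
    egfr,
)

#: KDIGO creatinine thresholds (mg/dL, ratios, hours/days).
ABSOLUTE_RISE_MGDL = 0.3
ABSOLUTE_RISE_WINDOW_H = 48.0
RATIO_THRESHOLD = 1.5
RATIO_WINDOW_DAYS = 7.0
STAGE2_RATIO = 2.0
STAGE3_RATIO = 3.0
STAGE3_ABSOLUTE_MGDL = 4.0
EGFR_DYSFUNCTION_THRESHOLD = 60.0
CHRONICITY_DAYS = 90


class Category(str, enum.Enum):
    AKD_WITH_AKI = "AKD_with_AKI"
    AKD_WITHOUT_AKI = "AKD_without_AKI"
    CKD = "CKD"
    NKD = "NKD"


AKD_CATEGORIES = frozenset({Category.AKD_WITH_AKI, Category.AKD_WITHOUT_AKI})


class BaselineProvenance(str, enum.Enum):
    PRE_ADMISSION_LATEST = "pre_admission_latest"
    IN_ADMISSION_NADIR = "in_admission_nadir"
    COMBINED_MIN = "combined_min"
    UNAVAILABLE = "unavailable"


class RecoveryStatus(str, enum.Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    NONE = "none"
    UNKNOWN = "unknown"


class RecoveryTimepoint(str, enum.Enum):
    DISCHARGE = "discharge"
    DAY90 = "day90"


@dataclass(frozen=True)
class BaselineResult:
    """Baseline creatinine with its provenance and the AKI-window anchor time."""

    value: Optional[float]
    provenance: BaselineProvenance
    window_anchor: Optional[datetime] = None

    def __post_init__(self):
        if (self.value is None) != (self.provenance is BaselineProvenance.UNAVAILABLE):
            raise ValidationError("baseline value is absent iff provenance is 'unavailable'")

    @property
    def available(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class StagingDetail:
    stage: int
    criteria: tuple[str, ...]
    peak_value: Optional[float] = None
    peak_ratio: Optional[float] = None


@dataclass(frozen=True)
class KidneyClassification:
    """One mutually exclusive kidney-status category per patient."""

    category: Category
    aki_stage: int
    baseline: BaselineResult
    criteria_fired: tuple[str, ...]
    enrollment_scr: Optional[float] = None
    enrollment_egfr: Optional[float] = None

    def __post_init__(self):
        if (self.aki_stage >= 1) != (self.category is Category.AKD_WITH_AKI):
            raise ValidationError("aki_stage >= 1 iff category is AKD_with_AKI")


@dataclass(frozen=True)
class RecoveryAssessment:
    status: RecoveryStatus
    timepoint: RecoveryTimepoint
    reference_scr: Optional[float] = None


@dataclass(frozen=True)
class RecoveryThresholds:
    """Ratios/offsets defining recovery status relative to baseline.

    ``none`` (no recovery) takes precedence over ``complete`` in the narrow
    low-baseline regime where baseline + 0.3 mg/dL falls below
    complete_ratio * baseline.
    """

    complete_ratio: float = 1.25
    none_ratio: float = 1.5
    none_absolute_mgdl: float = ABSOLUTE_RISE_MGDL


def determine_baseline(
    series: CreatinineSeries,
    admission_time: datetime,
    lookback_days: int = 365,
    policy: str = "combined_min",
) -> BaselineResult:
    """Determine the reference (baseline) creatinine for AKI assessment.

    Candidates are the latest pre-admission measurement within
    ``lookback_days`` and the lowest measurement during the admission
    (enrollment, in-admission and discharge contexts). Under the default
    ``combined_min`` policy the smaller of the two is the baseline; the
    alternative ``pre_admission_preferred`` policy uses the pre-admission
    value whenever one exists. A baseline is never imputed: with no usable
    candidate the result is ``unavailable``.
    """
    if len(series) == 0:
        raise ValidationError("cannot determine a baseline from an empty creatinine series")
    if lookback_days <= 0:
        raise ValidationError(f"lookback_days must be positive, got {lookback_days}")
    if policy not in ("combined_min", "pre_admission_preferred"):
        raise ValidationError(f"unknown baseline policy: {policy!r}")

    horizon = admission_time - timedelta(days=lookback_days)
    pre = [
        m
        for m in series
        if m.context is Context.PRE_ADMISSION and horizon <= m.time <= admission_time
    ]
    adm = [m for m in series if m.context in ADMISSION_CONTEXTS]

    pre_latest = max(pre, key=lambda m: m.time) if pre else None
    nadir = min(adm, key=lambda m: (m.value, m.time)) if adm else None
    first_adm_time = min(m.time for m in adm) if adm else None

    if pre_latest is None and nadir is None:
        return BaselineResult(None, BaselineProvenance.UNAVAILABLE)
    if pre_latest is None:
        return BaselineResult(nadir.value, BaselineProvenance.IN_ADMISSION_NADIR, first_adm_time)
    if nadir is None:
        return BaselineResult(
            pre_latest.value, BaselineProvenance.PRE_ADMISSION_LATEST, pre_latest.time
        )
    if policy == "pre_admission_preferred":
        return BaselineResult(
            pre_latest.value, BaselineProvenance.PRE_ADMISSION_LATEST, pre_latest.time
        )
    # combined_min: the winning candidate anchors the AKI window; ties favour
    # the in-admission anchor (presumed recent onset).
    if nadir.value <= pre_latest.value:
        anchor = first_adm_time
        value = nadir.value
    else:
        anchor = pre_latest.time
        value = pre_latest.value
    return BaselineResult(value, BaselineProvenance.COMBINED_MIN, anchor)


def staging_detail(
    series: CreatinineSeries,
    baseline: BaselineResult,
    krt_initiated: bool = False,
) -> StagingDetail:
    """KDIGO AKI staging with the list of criteria that fired.

    Follow-up measurements are excluded: staging concerns the index illness.
    An unavailable baseline yields stage 0 with a ``baseline_unavailable``
    marker (a signal, not an exception) unless KRT was initiated, which is
    stage 3 by itself.
    """
    criteria: list[str] = []
    if krt_initiated:
        criteria.append("krt_initiated")

    if not baseline.available:
        criteria.append("baseline_unavailable")
        return StagingDetail(3 if krt_initiated else 0, tuple(criteria))

    ms = [m for m in series if m.context is not Context.FOLLOWUP]
    base = baseline.value

    # Absolute-rise criterion: >= 0.3 mg/dL increase across any pair <= 48 h apart.
    rise_met = False
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            dt_h = (ms[j].time - ms[i].time).total_seconds() / 3600.0
            if dt_h <= ABSOLUTE_RISE_WINDOW_H and ms[j].value - ms[i].value >= ABSOLUTE_RISE_MGDL:
                rise_met = True
                break
        if rise_met:
            break

    # Ratio criterion: >= 1.5x baseline within 7 days of the window anchor.
    ratio_met = False
    if baseline.window_anchor is not None:
        window_end = baseline.window_anchor + timedelta(days=RATIO_WINDOW_DAYS)
        for m in ms:
            if (
                m.value >= RATIO_THRESHOLD * base
                and baseline.window_anchor <= m.time <= window_end
            ):
                ratio_met = True
                break

    if rise_met:
        criteria.append("scr_rise_0.3mgdl_48h")
    if ratio_met:
        criteria.append("scr_1.5x_baseline_7d")

    aki = rise_met or ratio_met
    if not aki:
        return StagingDetail(3 if krt_initiated else 0, tuple(criteria))

    peak = max(m.value for m in ms)
    peak_ratio = peak / base
    stage = 1
    for m in ms:
        r = m.value / base
        if r >= STAGE3_RATIO or m.value >= STAGE3_ABSOLUTE_MGDL:
            stage = max(stage, 3)
        elif r >= STAGE2_RATIO:
            stage = max(stage, 2)
    if krt_initiated:
        stage = 3
    if stage == 3 and peak_ratio < STAGE3_RATIO and peak >= STAGE3_ABSOLUTE_MGDL:
        criteria.append("scr_ge_4.0mgdl_with_acute_rise")
    return StagingDetail(stage, tuple(criteria), peak, peak_ratio)


def stage_aki(
    series: CreatinineSeries,
    baseline: BaselineResult,
    krt_initiated: bool = False,
) -> int:
    """KDIGO AKI stage 0-3 (0 = no AKI or not assessable)."""
    return staging_detail(series, baseline, krt_initiated).stage


def classify(
    series: CreatinineSeries,
    demo: Demographics,
    baseline: BaselineResult,
    aki_stage: int,
    chronicity_evidence: Optional[bool] = None,
    params: GfrEquationParams | None = None,
    extra_criteria: Sequence[str] = (),
) -> KidneyClassification:
    """Assign exactly one of AKD_with_AKI, AKD_without_AKI, CKD, NKD.

    Priority: (1) any AKI stage -> AKD with AKI; (2) kidney dysfunction
    (enrollment eGFR < 60 mL/min/1.73 m^2, or SCr > 1.5x baseline) of
    duration < 90 days or unknown (presumed acute) -> AKD without AKI;
    (3) eGFR < 60 with documented chronicity (>= 90 days) -> CKD; (4) NKD.

    ``chronicity_evidence`` is an input label (True: dysfunction documented
    >= 90 days; False: documented acute; None: unknown, presumed acute).
    """
    enrol = [m for m in series if m.context is Context.ENROLLMENT]
    if not enrol:
        enrol = [m for m in series if m.context in ADMISSION_CONTEXTS]
    if not enrol:
        raise ValidationError("enrollment eGFR is not computable: no admission measurements")
    index = enrol[0]
    enrollment_egfr = egfr(index.value, demo, params)

    criteria = list(extra_criteria)
    if aki_stage >= 1:
        criteria.append("aki_stage_ge_1")
        return KidneyClassification(
            Category.AKD_WITH_AKI, int(aki_stage), baseline, tuple(criteria),
            index.value, enrollment_egfr,
        )

    low_egfr = enrollment_egfr < EGFR_DYSFUNCTION_THRESHOLD
    scr_elevated = baseline.available and index.value > RATIO_THRESHOLD * baseline.value
    if low_egfr:
        criteria.append("enrollment_egfr_lt_60")
    if scr_elevated:
        criteria.append("enrollment_scr_gt_1.5x_baseline")

    if (low_egfr or scr_elevated) and chronicity_evidence is not True:
        if chronicity_evidence is None:
            criteria.append("duration_unknown_presumed_acute")
        return KidneyClassification(
            Category.AKD_WITHOUT_AKI, 0, baseline, tuple(criteria),
            index.value, enrollment_egfr,
        )
    if low_egfr and chronicity_evidence is True:
        criteria.append("chronicity_documented_ge_90d")
        return KidneyClassification(
            Category.CKD, 0, baseline, tuple(criteria), index.value, enrollment_egfr
        )
    return KidneyClassification(
        Category.NKD, 0, baseline, tuple(criteria), index.value, enrollment_egfr
    )


def assess_recovery(
    classification: KidneyClassification,
    baseline: BaselineResult,
    timepoint_scr: Optional[float],
    timepoint: RecoveryTimepoint,
    thresholds: RecoveryThresholds | None = None,
) -> RecoveryAssessment:
    """Kidney recovery relative to baseline at discharge or 90-day follow-up.

    Defined only for AKD patients. ``unknown`` when no repeat creatinine
    exists at the timepoint (or no baseline is available to compare against);
    ``complete`` below complete_ratio x baseline; ``none`` at or above
    none_ratio x baseline or baseline + 0.3 mg/dL; ``incomplete`` otherwise.
    """
    timepoint = RecoveryTimepoint(timepoint)
    if classification.category not in AKD_CATEGORIES:
        raise UsageError(
            f"recovery is assessed only for AKD patients, not {classification.category.value}"
        )
    th = thresholds or RecoveryThresholds()
    if timepoint_scr is None or not baseline.available:
        return RecoveryAssessment(RecoveryStatus.UNKNOWN, timepoint, timepoint_scr)
    base = baseline.value
    if timepoint_scr >= th.none_ratio * base or timepoint_scr >= base + th.none_absolute_mgdl:
        return RecoveryAssessment(RecoveryStatus.NONE, timepoint, timepoint_scr)
    if timepoint_scr < th.complete_ratio * base:
        return RecoveryAssessment(RecoveryStatus.COMPLETE, timepoint, timepoint_scr)
    return RecoveryAssessment(RecoveryStatus.INCOMPLETE, timepoint, timepoint_scr)


def ckd_transition_at_followup(
    classification: KidneyClassification, day90_egfr: Optional[float]
) -> Optional[bool]:
    """Whether an AKD patient meets the CKD threshold (eGFR < 60) at day 90.

    Returns ``None`` (not assessable) when no day-90 eGFR exists — missing is
    distinct from negative.
    """
    if classification.category not in AKD_CATEGORIES:
        raise UsageError("CKD transition applies only to AKD patients")
    if day90_egfr is None:
        return None
    return day90_egfr < EGFR_DYSFUNCTION_THRESHOLD
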