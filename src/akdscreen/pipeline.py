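"""End-to-end pipeline: score -> eGFR -> baseline -> stage -> classify -> summarize."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_analysis import CohortSummary, ScorePerformance, evaluate_score, summarize_cohort
from .errors import AkdScreenError, ValidationError
from .io import RunConfig
from .kdigo import (
    AKD_CATEGORIES,
    Category,
    RecoveryThresholds,
    RecoveryTimepoint,
    assess_recovery,
    ckd_transition_at_followup,
    classify,
    determine_baseline,
    staging_detail,
)
from .kidney_function import (
    Context,
    CreatinineMeasurement,
    CreatinineSeries,
    Demographics,
    GfrEquationParams,
    egfr,
)
from .risk_scoring import score_patients

log = logging.getLogger("akdscreen")


@dataclass
class PipelineResult:
    """Classified per-patient frame plus cohort summary and score performance."""

    frame: pd.DataFrame
    summary: CohortSummary
    performance: Optional[ScorePerformance]


class StageFailure(AkdScreenError):
    """A pipeline stage failed for one patient; carries stage and patient id."""

    def __init__(self, stage: str, patient_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for patient {patient_id!r}: {cause}")
        self.stage = stage
        self.patient_id = patient_id


def _series_from_rows(times, values, sources, contexts) -> CreatinineSeries:
    return CreatinineSeries(
        CreatinineMeasurement(float(v), t.to_pydatetime(), str(s), str(c))
        for t, v, s, c in zip(times, values, sources, contexts)
    )


def run_pipeline(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full identification pipeline on a validated cohort.

    Stages, in order: risk scoring; per-patient baseline determination, KDIGO
    AKI staging, category classification, recovery assessment at discharge
    and at the 90-day follow-up window, and CKD-transition flagging; then
    cohort summarisation and score evaluation (labels: classified AKD vs
    not). Patients with no creatinine data are carried with a null category
    and excluded from classification tallies.
    """
    cfg = config or RunConfig()
    weights = cfg.weights()
    params = GfrEquationParams.variant(cfg.egfr_variant)
    thresholds = RecoveryThresholds(
        cfg.recovery_complete_ratio, cfg.recovery_none_ratio, cfg.recovery_none_absolute
    )

    if len(patients) == 0:
        log.warning("empty cohort: producing empty outputs")
        frame = patients.copy()
        for c in ("risk_score", "inclusion_route", "category", "aki_stage"):
            frame[c] = pd.Series(dtype=object)
        return PipelineResult(frame, summarize_cohort(frame), None)

    scored = score_patients(patients, weights, cfg.absent_if_missing)

    meas = measurements.sort_values(["patient_id", "scr_time"], kind="mergesort")
    groups = {pid: g for pid, g in meas.groupby("patient_id")} if len(meas) else {}

    lo_fup, hi_fup = cfg.followup_window_days
    rows = []
    for p in scored.itertuples(index=False):
        pid = p.patient_id
        out = {
            "patient_id": pid,
            "category": None,
            "aki_stage": np.nan,
            "baseline_scr": np.nan,
            "baseline_provenance": None,
            "enrollment_scr": np.nan,
            "enrollment_egfr": np.nan,
            "enrollment_source": None,
            "criteria_fired": "",
            "recovery_discharge": None,
            "recovery_day90": None,
            "new_ckd_day90": None,
        }
        g = groups.get(pid)
        if g is None or len(g) == 0:
            out["criteria_fired"] = "no_creatinine_data"
            rows.append(out)
            continue
        try:
            demo = Demographics(int(p.age), str(p.sex).lower())
            series = _series_from_rows(
                g["scr_time"], g["scr_value"], g["scr_source"], g["scr_context"]
            )
            admission = pd.Timestamp(p.admission_time).to_pydatetime()
            baseline = determine_baseline(
                series, admission, cfg.lookback_days, cfg.baseline_policy
            )
            krt = bool(getattr(p, "krt_provided", False) or False)
            detail = staging_detail(series, baseline, krt_initiated=krt)
            chron = getattr(p, "chronicity_evidence", None)
            chron = None if chron is None or (isinstance(chron, float) and np.isnan(chron)) else bool(chron)
            cls = classify(
                series, demo, baseline, detail.stage, chron, params, detail.criteria
            )
        except AkdScreenError as exc:
            raise StageFailure("classify", str(pid), exc) from exc

        out.update(
            category=cls.category.value,
            aki_stage=cls.aki_stage,
            baseline_scr=baseline.value if baseline.available else np.nan,
            baseline_provenance=baseline.provenance.value,
            enrollment_scr=cls.enrollment_scr,
            enrollment_egfr=cls.enrollment_egfr,
            criteria_fired=";".join(cls.criteria_fired),
        )
        enrol_rows = g[g["scr_context"] == Context.ENROLLMENT.value]
        if len(enrol_rows):
            out["enrollment_source"] = str(enrol_rows.iloc[0]["scr_source"])

        if cls.category in AKD_CATEGORIES:
            disch = g[g["scr_context"] == Context.DISCHARGE.value]
            disch_scr = float(disch.iloc[-1]["scr_value"]) if len(disch) else None
            out["recovery_discharge"] = assess_recovery(
                cls, baseline, disch_scr, RecoveryTimepoint.DISCHARGE, thresholds
            ).status.value

            fup = g[g["scr_context"] == Context.FOLLOWUP.value].copy()
            day90_scr = None
            if len(fup):
                days = (
                    pd.to_datetime(fup["scr_time"]) - pd.Timestamp(p.admission_time)
                ).dt.total_seconds() / 86400.0
                in_window = fup[(days >= lo_fup) & (days <= hi_fup)]
                if len(in_window):
                    nearest = (days[in_window.index] - 90.0).abs().idxmin()
                    day90_scr = float(fup.loc[nearest, "scr_value"])
            out["recovery_day90"] = assess_recovery(
                cls, baseline, day90_scr, RecoveryTimepoint.DAY90, thresholds
            ).status.value
            day90_egfr = egfr(day90_scr, demo, params) if day90_scr is not None else None
            out["new_ckd_day90"] = ckd_transition_at_followup(cls, day90_egfr)
        rows.append(out)

    frame = scored.merge(pd.DataFrame(rows), on="patient_id", how="left", validate="1:1")
    summary = summarize_cohort(frame)

    performance = None
    classified = frame[frame["category"].notna()]
    if len(classified):
        labels = classified["category"].isin([c.value for c in AKD_CATEGORIES])
        if 0 < labels.sum() < len(labels):
            performance = evaluate_score(
                classified["risk_score"].to_numpy(), labels.to_numpy(), weights.cutoff
            )
    return PipelineResult(frame, summary, performance)
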