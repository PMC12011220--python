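"""Seeded synthetic patient cohorts with the latent structure the analysis assumes.

The generator emulates a pooled screening cohort: a latent kidney-status
mixture (AKD with AKI / AKD without AKI / CKD / NKD), symptom prevalences
conditional on status calibrated so the additive risk score attains the
published operating characteristics, creatinine trajectories consistent with
the KDIGO stage bands, proportional measurement noise by device, and
stage-dependent outcomes. Identical seed + config gives a bit-identical
cohort.

Latent truth (category, stage, true baseline/peak creatinine) is carried in
``latent_*`` / ``true_*`` columns so classification pipelines can be scored
against it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, DomainError, ValidationError
from .kdigo import Category
from .kidney_function import Demographics, GfrEquationParams, egfr_values
from .risk_scoring import (
    DEFAULT_CUTOFF,
    SYMPTOM_COLUMNS,
    SYMPTOM_FIELDS,
    ScoreWeights,
)

# Calibrated per-category symptom probabilities. The three kidney-disease
# categories share one elevated vector, NKD a background vector; the pair was
# produced once by calibrate_symptom_probs against the published operating
# characteristics (AUROC 0.824, sensitivity 0.929 / specificity 0.589 at the
# 10-point cutoff) and frozen here.
DISEASE_SYMPTOM_PROBS: dict[str, float] = {
    "vomiting_dehydration": 0.644,
    "low_oral_intake_dehydration": 0.876,
    "weakness": 0.581,
    "oliguria_reported": 0.411,
    "hypotension": 0.062,
    "appetite_loss": 0.878,
    "swelling": 0.120,
}
BACKGROUND_SYMPTOM_PROBS: dict[str, float] = {
    "vomiting_dehydration": 0.638,
    "low_oral_intake_dehydration": 0.769,
    "weakness": 0.566,
    "oliguria_reported": 0.165,
    "hypotension": 0.062,
    "appetite_loss": 0.193,
    "swelling": 0.107,
}

#: Multiplicative creatinine excursions (peak / true baseline) by latent state.
STAGE_MULTIPLIER_BOUNDS: dict[int, tuple[float, float]] = {
    1: (1.5, 1.9),
    2: (2.0, 2.9),
    3: (3.0, 5.0),
}
SUBACUTE_MULTIPLIER_BOUNDS = (1.5, 2.5)

_CAT_ORDER = (
    Category.AKD_WITH_AKI.value,
    Category.AKD_WITHOUT_AKI.value,
    Category.CKD.value,
    Category.NKD.value,
)

_EPOCH = np.datetime64("2018-09-01T00:00")


def _default_prevalence() -> dict[str, float]:
    # exact count ratios from the pooled cohort table (634/2288/37/1352 of 4311)
    return {
        Category.AKD_WITH_AKI.value: 634 / 4311,
        Category.AKD_WITHOUT_AKI.value: 2288 / 4311,
        Category.CKD.value: 37 / 4311,
        Category.NKD.value: 1352 / 4311,
    }


def _default_symptom_probs() -> dict[str, dict[str, float]]:
    return {
        Category.AKD_WITH_AKI.value: dict(DISEASE_SYMPTOM_PROBS),
        Category.AKD_WITHOUT_AKI.value: dict(DISEASE_SYMPTOM_PROBS),
        Category.CKD.value: dict(DISEASE_SYMPTOM_PROBS),
        Category.NKD.value: dict(BACKGROUND_SYMPTOM_PROBS),
    }


def _default_outcome_probs() -> dict[str, float]:
    return {
        "death_nkd": 0.005,
        "death_ckd": 0.02,
        "death_akd_without_aki": 0.028,
        "death_stage1": 0.01,
        "death_stage2": 0.03,
        "death_stage3": 0.12,
        "krt_indicated_stage3": 0.311,
        "krt_provided_given_indicated": 0.813,
        "transfer_recommended_akd": 0.061,
        "transfer_recommended_other": 0.01,
        "transfer_occurred_given_recommended": 0.742,
        "followup_attendance": 0.623,
    }


@dataclass
class CohortConfig:
    """All tunable knobs of the synthetic cohort generator.

    Defaults are anchored to the pooled cohort: category prevalences
    14.7/53.1/0.9/31.4%, AKI stage mix 61.7/22.1/16.3%, 53.1% female, median
    age 57 (IQR 42-70), 73.0% point-of-care measurement. Measurement noise is
    proportional Gaussian with a device-specific coefficient of variation
    (7% POC, 3% laboratory).
    """

    n_patients: int = 5000
    seed: int = 0
    category_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    stage_mix: dict[int, float] = field(
        default_factory=lambda: {1: 391 / 634, 2: 140 / 634, 3: 103 / 634}
    )
    symptom_probs: dict[str, dict[str, float]] = field(default_factory=_default_symptom_probs)
    poc_fraction: float = 3145 / 4311
    poc_cv: float = 0.07
    lab_cv: float = 0.03
    outcome_probs: dict[str, float] = field(default_factory=_default_outcome_probs)
    female_fraction: float = 2289 / 4311
    # age = age_loc - LogNormal(age_mu, age_sigma), truncated to bounds; the
    # three parameters were solved once from median 57 and IQR 42-70.
    age_loc: float = 154.5
    age_mu: float = 4.579899
    age_sigma: float = 0.212163
    age_bounds: tuple[int, int] = (18, 100)
    # true baseline eGFR ranges (mL/min/1.73 m^2) by latent state
    egfr_range_nkd: tuple[float, float] = (70.0, 115.0)
    egfr_range_ckd: tuple[float, float] = (20.0, 55.0)
    egfr_range_aki_baseline: tuple[float, float] = (65.0, 110.0)
    pre_admission_prob: float = 0.3
    discharge_scr_prob: float = 0.5
    followup_scr_prob: float = 0.9
    persistent_dysfunction_prob: float = 0.5
    # reporting precision of creatinine values (decimals); None = exact
    scr_decimals: Optional[int] = 2
    egfr_variant: str = "ckd_epi_2021"

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be non-negative")
        prev = [self.category_prevalence.get(c, 0.0) for c in _CAT_ORDER]
        if abs(sum(prev) - 1.0) > 1e-9:
            raise ValidationError(
                f"category_prevalence must sum to 1 (got {sum(prev):.12f})"
            )
        if abs(sum(self.stage_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("stage_mix must sum to 1")
        probs = list(prev) + list(self.stage_mix.values()) + [
            self.poc_fraction,
            self.female_fraction,
            self.pre_admission_prob,
            self.discharge_scr_prob,
            self.followup_scr_prob,
            self.persistent_dysfunction_prob,
            *self.outcome_probs.values(),
        ]
        for cat, vec in self.symptom_probs.items():
            if set(vec) != set(SYMPTOM_FIELDS):
                raise ValidationError(f"symptom_probs[{cat!r}] must cover all seven symptoms")
            probs.extend(vec.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.poc_cv < 0 or self.lab_cv < 0:
            raise ValidationError("measurement CVs must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_mix"] = {str(k): v for k, v in self.stage_mix.items()}
        d["age_bounds"] = list(self.age_bounds)
        for k in ("egfr_range_nkd", "egfr_range_ckd", "egfr_range_aki_baseline"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "stage_mix" in d:
            d["stage_mix"] = {int(k): float(v) for k, v in d["stage_mix"].items()}
        for k in ("age_bounds", "egfr_range_nkd", "egfr_range_ckd", "egfr_range_aki_baseline"):
            if k in d:
                d[k] = tuple(d[k])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class CalibrationTargets:
    """Published operating characteristics the symptom calibration aims at."""

    auroc: float = 0.824
    sensitivity_at_cutoff: float = 0.929
    specificity_at_cutoff: float = 0.589
    cutoff: int = DEFAULT_CUTOFF
    tolerance: Mapping[str, float] = field(
        default_factory=lambda: {"auroc": 0.02, "sensitivity": 0.03, "specificity": 0.03}
    )

    def __post_init__(self):
        for v in (self.auroc, self.sensitivity_at_cutoff, self.specificity_at_cutoff):
            if not (0.0 < v <= 1.0):
                raise ValidationError("calibration targets must lie in (0, 1]")


@dataclass(frozen=True)
class SyntheticPatient:
    """One generated patient: observable record fields plus latent truth."""

    patient_id: str
    age: int
    female: bool
    symptoms: dict[str, bool]
    clinical_judgment: bool
    admission_time: pd.Timestamp
    facility_type: str
    died_inhospital: bool
    krt_indicated: bool
    krt_provided: bool
    transfer_recommended: bool
    transfer_occurred: bool
    followup_attended: bool
    chronicity_evidence: Optional[bool]
    latent_category: str
    latent_stage: int
    true_baseline_scr: float
    true_peak_scr: float


class SyntheticCohort:
    """DataFrame-backed container for a generated cohort.

    ``patients`` has one row per patient (record schema plus ``latent_*`` /
    ``true_*`` columns); ``measurements`` is the long-format creatinine table
    (one row per measurement, keyed by ``patient_id``).
    """

    def __init__(self, patients: pd.DataFrame, measurements: pd.DataFrame, config: CohortConfig):
        self.patients = patients
        self.measurements = measurements
        self.config = config

    def __len__(self) -> int:
        return len(self.patients)

    def to_records(self) -> list[SyntheticPatient]:
        out = []
        for row in self.patients.itertuples(index=False):
            out.append(
                SyntheticPatient(
                    patient_id=row.patient_id,
                    age=int(row.age),
                    female=bool(row.female),
                    symptoms={
                        f: bool(getattr(row, SYMPTOM_COLUMNS[f])) for f in SYMPTOM_FIELDS
                    },
                    clinical_judgment=bool(row.clinical_judgment),
                    admission_time=pd.Timestamp(row.admission_time),
                    facility_type=row.facility_type,
                    died_inhospital=bool(row.died_inhospital),
                    krt_indicated=bool(row.krt_indicated),
                    krt_provided=bool(row.krt_provided),
                    transfer_recommended=bool(row.transfer_recommended),
                    transfer_occurred=bool(row.transfer_occurred),
                    followup_attended=bool(row.followup_attended),
                    chronicity_evidence=(None if pd.isna(row.chronicity_evidence) else bool(row.chronicity_evidence)),
                    latent_category=row.latent_category,
                    latent_stage=int(row.latent_stage),
                    true_baseline_scr=float(row.true_baseline_scr),
                    true_peak_scr=float(row.true_peak_scr),
                )
            )
        return out


def scr_from_egfr(
    target_egfr: float, demo: Demographics, params: GfrEquationParams | None = None
) -> float:
    """Serum creatinine (mg/dL) whose eGFR equals ``target_egfr``.

    The eGFR equation is strictly decreasing in creatinine, so the inverse is
    found by root bracketing on [0.05, 40] mg/dL to within 1e-6.
    """
    if not (1.0 < target_egfr < 200.0):
        raise DomainError(f"target eGFR must lie in (1, 200), got {target_egfr!r}")
    p = params or GfrEquationParams()
    lo, hi = 0.05, 40.0
    g_lo = float(egfr_values(lo, demo.age, demo.female, p))
    g_hi = float(egfr_values(hi, demo.age, demo.female, p))
    if not (g_hi < target_egfr < g_lo):
        raise DomainError(
            f"target eGFR {target_egfr} not achievable for age {demo.age} {demo.sex.value}"
        )
    f = lambda s: float(egfr_values(s, demo.age, demo.female, p)) - target_egfr
    return float(brentq(f, lo, hi, xtol=1e-9))


def _scr_from_egfr_vec(target, age, female, params: GfrEquationParams) -> np.ndarray:
    """Vectorised bisection inverse of the eGFR equation."""
    target = np.asarray(target, dtype=float)
    lo = np.full_like(target, 0.05)
    hi = np.full_like(target, 40.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = egfr_values(mid, age, female, params)
        too_high = g > target  # eGFR too high -> creatinine too low
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
    return 0.5 * (lo + hi)


def _draw_ages(rng: np.random.Generator, n: int, cfg: CohortConfig) -> np.ndarray:
    """Reflected, truncated log-normal age draw (left-skewed)."""
    lo, hi = cfg.age_bounds
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = cfg.age_loc - rng.lognormal(cfg.age_mu, cfg.age_sigma, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)
        out[idx[ok]] = draw[ok]
        need[idx[ok]] = False
    return np.floor(out).astype(int)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a seeded synthetic cohort under ``config``.

    Per patient: draw the latent category (and AKI stage), demographics, a
    true baseline eGFR consistent with the category, invert it to a baseline
    creatinine, apply the acute multiplier, and emit a 1-4 point observed
    creatinine series (optional pre-admission value, enrollment, in-admission
    and discharge points for acute courses, and a follow-up value for
    attendees) with proportional Gaussian noise by measurement source.
    Symptoms are Bernoulli draws per category; outcomes depend on stage.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    params = GfrEquationParams.variant(cfg.egfr_variant)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    cats = rng.choice(
        np.array(_CAT_ORDER),
        size=n,
        p=np.array([cfg.category_prevalence[c] for c in _CAT_ORDER]),
    )
    is_aki = cats == Category.AKD_WITH_AKI.value
    is_woaki = cats == Category.AKD_WITHOUT_AKI.value
    is_ckd = cats == Category.CKD.value
    is_nkd = cats == Category.NKD.value

    stage = np.zeros(n, dtype=int)
    stage[is_aki] = rng.choice(
        [1, 2, 3], size=int(is_aki.sum()), p=[cfg.stage_mix[1], cfg.stage_mix[2], cfg.stage_mix[3]]
    )

    female = rng.random(n) < cfg.female_fraction
    age = _draw_ages(rng, n, cfg)

    mult = np.ones(n)
    for st, (lo, hi) in STAGE_MULTIPLIER_BOUNDS.items():
        m = stage == st
        mult[m] = rng.uniform(lo, hi, size=int(m.sum()))
    mult[is_woaki] = rng.uniform(*SUBACUTE_MULTIPLIER_BOUNDS, size=int(is_woaki.sum()))

    base_egfr = np.empty(n)
    base_egfr[is_nkd] = rng.uniform(*cfg.egfr_range_nkd, size=int(is_nkd.sum()))
    base_egfr[is_ckd] = rng.uniform(*cfg.egfr_range_ckd, size=int(is_ckd.sum()))
    base_egfr[is_aki] = rng.uniform(*cfg.egfr_range_aki_baseline, size=int(is_aki.sum()))
    # Sub-acute dysfunction is *defined* by reduced function at presentation:
    # redraw (baseline eGFR, multiplier) until the enrollment eGFR after the
    # excursion lands below 55, so the latent category matches its meaning
    # with margin against device noise at the 60 threshold.
    wo_idx = np.flatnonzero(is_woaki)
    need = np.ones(len(wo_idx), dtype=bool)
    for _ in range(100):
        if not need.any():
            break
        k = wo_idx[need]
        base_egfr[k] = rng.uniform(62.0, 100.0, size=len(k))
        mult[k] = rng.uniform(*SUBACUTE_MULTIPLIER_BOUNDS, size=len(k))
        scr_b = _scr_from_egfr_vec(base_egfr[k], age[k], female[k], params)
        g_enrol = egfr_values(scr_b * mult[k], age[k], female[k], params)
        need[need] = g_enrol >= 55.0

    true_baseline_scr = _scr_from_egfr_vec(base_egfr, age, female, params)
    true_peak_scr = true_baseline_scr * mult

    admission_offset_h = rng.uniform(0, 700 * 24, size=n)
    admission_time = _EPOCH + np.round(admission_offset_h * 60).astype("timedelta64[m]")

    poc = rng.random(n) < cfg.poc_fraction
    patient_source = np.where(poc, "poc", "lab")

    # symptoms per category
    cat_to_row = {c: i for i, c in enumerate(_CAT_ORDER)}
    cat_index = np.array([cat_to_row[c] for c in cats], dtype=int)
    prob_matrix = np.array(
        [[cfg.symptom_probs[c][f] for f in SYMPTOM_FIELDS] for c in _CAT_ORDER]
    )
    sx = rng.random((n, len(SYMPTOM_FIELDS))) < prob_matrix[cat_index]
    weights = ScoreWeights()
    score = sx @ weights.as_vector()
    clinical_judgment = score < weights.cutoff  # below-cutoff patients entered by judgment

    # outcomes
    op = cfg.outcome_probs
    death_p = np.full(n, op["death_nkd"])
    death_p[is_ckd] = op["death_ckd"]
    death_p[is_woaki] = op["death_akd_without_aki"]
    for st in (1, 2, 3):
        death_p[stage == st] = op[f"death_stage{st}"]
    died = rng.random(n) < death_p
    krt_indicated = (stage == 3) & (rng.random(n) < op["krt_indicated_stage3"])
    krt_provided = krt_indicated & (rng.random(n) < op["krt_provided_given_indicated"])
    is_akd = is_aki | is_woaki
    transfer_p = np.where(is_akd, op["transfer_recommended_akd"], op["transfer_recommended_other"])
    transfer_recommended = rng.random(n) < transfer_p
    transfer_occurred = transfer_recommended & (
        rng.random(n) < op["transfer_occurred_given_recommended"]
    )
    followup_attended = is_akd & ~died & (rng.random(n) < op["followup_attendance"])

    facility = rng.choice(
        np.array(["HCC", "district", "tertiary"]), size=n, p=[0.316, 0.157, 0.527]
    )
    chronicity = np.where(is_ckd, 1.0, np.nan)  # documented >= 90 d only for latent CKD

    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])

    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "female": female.astype(int),
            "admission_time": pd.Series(admission_time),
            "facility_type": facility,
            "clinical_judgment": clinical_judgment.astype(int),
            "chronicity_evidence": chronicity,
            "died_inhospital": died.astype(int),
            "krt_indicated": krt_indicated.astype(int),
            "krt_provided": krt_provided.astype(int),
            "transfer_recommended": transfer_recommended.astype(int),
            "transfer_occurred": transfer_occurred.astype(int),
            "followup_attended": followup_attended.astype(int),
            "latent_category": cats,
            "latent_stage": stage,
            "true_baseline_scr": true_baseline_scr,
            "true_peak_scr": true_peak_scr,
            "true_baseline_egfr": base_egfr,
        }
    )
    for j, f in enumerate(SYMPTOM_FIELDS):
        patients[SYMPTOM_COLUMNS[f]] = sx[:, j].astype(int)

    # ---- creatinine series construction -------------------------------
    slots = []  # (mask, time_offset_hours, true_value, source, context)
    has_pre = rng.random(n) < cfg.pre_admission_prob
    pre_offset = -rng.uniform(14 * 24, 180 * 24, size=n)
    slots.append((has_pre, pre_offset, true_baseline_scr, np.full(n, "lab"), "pre"))

    slots.append((np.ones(n, bool), np.zeros(n), true_peak_scr, patient_source, "enrol"))

    mid_val = true_baseline_scr + 0.4 * (true_peak_scr - true_baseline_scr)
    slots.append((is_aki, np.full(n, 48.0), mid_val, patient_source, "inadm"))
    slots.append((is_aki, np.full(n, 120.0), true_baseline_scr, patient_source, "disch"))

    has_disch_woaki = is_woaki & (rng.random(n) < cfg.discharge_scr_prob)
    disch_val_woaki = true_peak_scr * rng.uniform(0.9, 1.05, size=n)
    slots.append((has_disch_woaki, np.full(n, 96.0), disch_val_woaki, patient_source, "disch"))

    has_fup = followup_attended & (rng.random(n) < cfg.followup_scr_prob)
    fup_offset = rng.uniform(75 * 24, 105 * 24, size=n)
    persistent = rng.random(n) < cfg.persistent_dysfunction_prob
    fup_val = np.where(
        persistent,
        true_baseline_scr * rng.uniform(1.35, 2.0, size=n),
        true_baseline_scr * rng.uniform(0.92, 1.12, size=n),
    )
    slots.append((has_fup, fup_offset, fup_val, patient_source, "fup"))

    frames = []
    for mask, offset_h, value, source, context in slots:
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        t = admission_time[idx] + np.round(offset_h[idx] * 60).astype("timedelta64[m]")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": ids[idx],
                    "scr_time": pd.Series(t),
                    "scr_value_true": value[idx],
                    "scr_source": source[idx],
                    "scr_context": context,
                }
            )
        )
    meas = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["patient_id", "scr_time", "scr_value_true", "scr_source", "scr_context"]
        )
    )
    meas = meas.sort_values(["patient_id", "scr_time"], kind="mergesort").reset_index(drop=True)

    cv = np.where(meas["scr_source"].to_numpy() == "poc", cfg.poc_cv, cfg.lab_cv)
    noise = 1.0 + cv * rng.standard_normal(len(meas))
    observed = np.maximum(meas["scr_value_true"].to_numpy() * noise, 0.05)
    if cfg.scr_decimals is not None:
        # reporting precision applies to both columns, so zero-CV observed
        # values equal the true values exactly and CSV round-trips are
        # value-stable
        meas["scr_value_true"] = np.round(meas["scr_value_true"].to_numpy(), cfg.scr_decimals)
        observed = np.round(
            np.maximum(meas["scr_value_true"].to_numpy() * noise, 0.05), cfg.scr_decimals
        )
    meas.insert(1, "scr_value", observed)
    meas.insert(2, "scr_unit", "mgdl")

    return SyntheticCohort(patients, meas, cfg)


# ---------------------------------------------------------------------------
# Operating characteristics and symptom-probability calibration
# ---------------------------------------------------------------------------

def exact_operating_characteristics(
    symptom_probs: Mapping[str, Mapping[str, float]],
    prevalence: Mapping[str, float],
    weights: ScoreWeights | None = None,
) -> dict[str, float]:
    """Exact AUROC / sensitivity / specificity of the score at its cutoff.

    The score takes one of at most 128 profiles, so given independent
    Bernoulli symptoms per category the score distribution for the AKD
    (positive) and non-AKD (negative) classes is available in closed form;
    AUROC uses ties-count-1/2.
    """
    w = (weights or ScoreWeights())
    vec = w.as_vector()
    combos = np.array(list(itertools.product([0, 1], repeat=len(SYMPTOM_FIELDS))))
    scores = combos @ vec
    max_score = int(vec.sum())

    def pmf(probs: Mapping[str, float]) -> np.ndarray:
        p = np.array([probs[f] for f in SYMPTOM_FIELDS])
        mass = np.prod(np.where(combos == 1, p, 1.0 - p), axis=1)
        out = np.zeros(max_score + 1)
        np.add.at(out, scores, mass)
        return out

    pos_cats = [Category.AKD_WITH_AKI.value, Category.AKD_WITHOUT_AKI.value]
    neg_cats = [Category.CKD.value, Category.NKD.value]
    p_pos = sum(prevalence[c] for c in pos_cats)
    p_neg = sum(prevalence[c] for c in neg_cats)
    pos = sum(prevalence[c] * pmf(symptom_probs[c]) for c in pos_cats) / p_pos
    neg = sum(prevalence[c] * pmf(symptom_probs[c]) for c in neg_cats) / p_neg

    cum_neg = np.cumsum(neg)
    below = np.concatenate([[0.0], cum_neg[:-1]])  # P(S_neg < s)
    auroc = float(np.sum(pos * (below + 0.5 * neg)))
    sens = float(pos[w.cutoff:].sum())
    spec = float(neg[: w.cutoff].sum())
    return {"auroc": auroc, "sensitivity": sens, "specificity": spec}


def simulated_operating_characteristics(
    symptom_probs: Mapping[str, Mapping[str, float]],
    prevalence: Mapping[str, float],
    n_sim: int,
    seed: int,
    weights: ScoreWeights | None = None,
) -> dict[str, float]:
    """Monte-Carlo counterpart of :func:`exact_operating_characteristics`."""
    from .cohort_analysis import evaluate_score

    w = weights or ScoreWeights()
    rng = np.random.default_rng(seed)
    cats = rng.choice(
        np.array(_CAT_ORDER), size=n_sim, p=np.array([prevalence[c] for c in _CAT_ORDER])
    )
    cat_to_row = {c: i for i, c in enumerate(_CAT_ORDER)}
    pm = np.array([[symptom_probs[c][f] for f in SYMPTOM_FIELDS] for c in _CAT_ORDER])
    idx = np.array([cat_to_row[c] for c in cats])
    sx = rng.random((n_sim, len(SYMPTOM_FIELDS))) < pm[idx]
    scores = sx @ w.as_vector()
    labels = np.isin(cats, [Category.AKD_WITH_AKI.value, Category.AKD_WITHOUT_AKI.value])
    perf = evaluate_score(scores, labels, w.cutoff)
    return {
        "auroc": perf.auroc,
        "sensitivity": perf.sensitivity_at_cutoff,
        "specificity": perf.specificity_at_cutoff,
    }


def calibrate_symptom_probs(
    targets: CalibrationTargets | None = None,
    base_config: CohortConfig | None = None,
    n_sim: int = 20000,
    seed: int = 0,
    max_rounds: int = 40,
) -> dict[str, dict[str, float]]:
    """Search per-category symptom probabilities hitting the target metrics.

    Coordinate descent over a bounded probability grid, with the
    kidney-disease categories sharing one elevated vector and NKD a
    background vector. The objective is the squared distance of the exact
    operating characteristics from the targets; the accepted solution is then
    validated by a seeded simulation of ``n_sim`` patients. Raises
    :class:`CalibrationError` (reporting the best metrics achieved) when no
    solution lands within ``targets.tolerance``.
    """
    if n_sim < 5000:
        raise ValidationError("n_sim must be at least 5000")
    targets = targets or CalibrationTargets()
    cfg = base_config or CohortConfig()
    prevalence = cfg.category_prevalence
    weights = ScoreWeights(cutoff=targets.cutoff)

    disease = dict(DISEASE_SYMPTOM_PROBS)
    background = dict(BACKGROUND_SYMPTOM_PROBS)
    grid = np.round(np.arange(0.02, 0.97, 0.01), 2)

    def assemble(d, b):
        return {
            Category.AKD_WITH_AKI.value: dict(d),
            Category.AKD_WITHOUT_AKI.value: dict(d),
            Category.CKD.value: dict(d),
            Category.NKD.value: dict(b),
        }

    tgt = {
        "auroc": targets.auroc,
        "sensitivity": targets.sensitivity_at_cutoff,
        "specificity": targets.specificity_at_cutoff,
    }

    def loss(d, b):
        m = exact_operating_characteristics(assemble(d, b), prevalence, weights)
        return sum((m[k] - tgt[k]) ** 2 for k in tgt), m

    best_loss, best_metrics = loss(disease, background)
    already_ok = all(
        abs(best_metrics[k] - tgt[k]) <= 0.5 * _tol(targets, k) for k in tgt
    )
    for _ in range(0 if already_ok else max_rounds):
        improved = False
        for vec in (disease, background):
            for name in SYMPTOM_FIELDS:
                orig = vec[name]
                candidates = []
                for g in grid:
                    vec[name] = float(g)
                    l, m = loss(disease, background)
                    candidates.append((l, float(g), m))
                l, g, m = min(candidates, key=lambda t: t[0])
                if l < best_loss - 1e-12:
                    best_loss, best_metrics = l, m
                    vec[name] = g
                    improved = True
                else:
                    vec[name] = orig
        exact_ok = all(abs(best_metrics[k] - tgt[k]) <= 0.5 * _tol(targets, k) for k in tgt)
        if not improved or exact_ok:
            break

    solution = assemble(disease, background)
    sim = simulated_operating_characteristics(solution, prevalence, n_sim, seed, weights)
    failed = {
        k: sim[k] for k in tgt if abs(sim[k] - tgt[k]) > _tol(targets, k)
    }
    if failed:
        raise CalibrationError(
            "calibration did not reach its targets within tolerance; "
            f"best simulated metrics: {sim}",
            best=sim,
        )
    return solution


def _tol(targets: CalibrationTargets, key: str) -> float:
    return dict(targets.tolerance).get(key, 0.02)
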