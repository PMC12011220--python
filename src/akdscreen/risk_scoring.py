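"""Additive symptom-based screening score for acute kidney disease (AKD) risk.

Seven presentation-time symptoms each contribute a fixed number of points; a
patient whose total reaches the cutoff (default 10) is considered at risk of
AKD and proceeds to serum-creatinine testing. Patients below the cutoff may
still be included at the discretion of the clinical team (the "judgment"
route), which never overrides a score-qualified inclusion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Order of symptom fields, used everywhere a vector of symptoms is handled.
SYMPTOM_FIELDS = (
    "vomiting_dehydration",
    "low_oral_intake_dehydration",
    "weakness",
    "oliguria_reported",
    "hypotension",
    "appetite_loss",
    "swelling",
)

#: Default point values for each symptom (sum 37) and screening cutoff.
DEFAULT_POINTS: dict[str, int] = {
    "vomiting_dehydration": 4,
    "low_oral_intake_dehydration": 2,
    "weakness": 2,
    "oliguria_reported": 8,
    "hypotension": 8,
    "appetite_loss": 8,
    "swelling": 5,
}
DEFAULT_CUTOFF = 10

#: CSV column name for each symptom field.
SYMPTOM_COLUMNS: dict[str, str] = {
    "vomiting_dehydration": "sx_vomiting",
    "low_oral_intake_dehydration": "sx_low_intake",
    "weakness": "sx_weakness",
    "oliguria_reported": "sx_oliguria",
    "hypotension": "sx_hypotension",
    "appetite_loss": "sx_appetite_loss",
    "swelling": "sx_swelling",
}


class InclusionRoute(str, enum.Enum):
    """How a patient entered the at-risk cohort."""

    SCORE = "score"
    JUDGMENT = "judgment"
    NOT_INCLUDED = "not_included"


@dataclass(frozen=True)
class SymptomProfile:
    """The seven screening symptoms for one patient at presentation.

    Every field must be an explicit boolean; a missing symptom is rejected at
    construction time rather than silently treated as absent, because an
    imputed-absent symptom can only deflate the score and hide at-risk
    patients. Use :meth:`from_mapping` with ``absent_if_missing=True`` for the
    permissive behaviour when ingesting messy field data.
    """

    vomiting_dehydration: bool
    low_oral_intake_dehydration: bool
    weakness: bool
    oliguria_reported: bool
    hypotension: bool
    appetite_loss: bool
    swelling: bool

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (bool, np.bool_)):
                continue
            if v in (0, 1):  # accept 0/1 integers from CSV ingestion
                object.__setattr__(self, f.name, bool(v))
                continue
            raise ValidationError(
                f"symptom flag {f.name!r} must be present/absent (True/False or 0/1), "
                f"got {v!r}"
            )

    @classmethod
    def from_mapping(
        cls, data: Mapping[str, object], absent_if_missing: bool = False
    ) -> "SymptomProfile":
        """Build a profile from a mapping keyed by field name.

        Missing or null entries raise :class:`ValidationError` naming the
        field, unless ``absent_if_missing`` is set, in which case they are
        recorded as absent.
        """
        values = {}
        for name in SYMPTOM_FIELDS:
            v = data.get(name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                if absent_if_missing:
                    v = False
                else:
                    raise ValidationError(f"missing symptom flag: {name!r}")
            values[name] = v
        return cls(**values)

    def present(self) -> tuple[str, ...]:
        """Names of the symptoms that are present."""
        return tuple(n for n in SYMPTOM_FIELDS if getattr(self, n))


@dataclass(frozen=True)
class ScoreWeights:
    """Point values per symptom plus the at-risk cutoff."""

    points: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_POINTS))
    cutoff: int = DEFAULT_CUTOFF

    def __post_init__(self):
        missing = set(SYMPTOM_FIELDS) - set(self.points)
        extra = set(self.points) - set(SYMPTOM_FIELDS)
        if missing:
            raise ValidationError(f"weights missing symptoms: {sorted(missing)}")
        if extra:
            raise ValidationError(f"weights name unknown symptoms: {sorted(extra)}")
        for name, pts in self.points.items():
            if not (isinstance(pts, (int, np.integer)) and pts >= 0):
                raise ValidationError(
                    f"points for {name!r} must be a non-negative integer, got {pts!r}"
                )
        if not (isinstance(self.cutoff, (int, np.integer)) and self.cutoff >= 0):
            raise ValidationError(f"cutoff must be a non-negative integer, got {self.cutoff!r}")

    @property
    def max_score(self) -> int:
        return int(sum(self.points.values()))

    def as_vector(self) -> np.ndarray:
        """Points in :data:`SYMPTOM_FIELDS` order."""
        return np.array([self.points[n] for n in SYMPTOM_FIELDS], dtype=int)


@dataclass(frozen=True)
class RiskAssessment:
    """Outcome of screening one patient: score, at-risk flag, inclusion route."""

    score: int
    at_risk: bool
    inclusion_route: InclusionRoute

    def __post_init__(self):
        if self.at_risk != (self.inclusion_route != InclusionRoute.NOT_INCLUDED):
            raise ValidationError("at_risk must match inclusion_route")


def compute_risk_score(profile: SymptomProfile, weights: ScoreWeights | None = None) -> int:
    """Sum the point values of the symptoms present in ``profile``.

    Returns an integer in ``[0, weights.max_score]`` (0..37 with the default
    weights).
    """
    weights = weights or ScoreWeights()
    return int(sum(weights.points[name] for name in profile.present()))


def assess_risk(
    score: int, clinical_judgment: bool, weights: ScoreWeights | None = None
) -> RiskAssessment:
    """Determine at-risk status and inclusion route for a screened patient.

    A score at or above the cutoff always takes the score route, regardless of
    the judgment flag; clinical judgment can only add patients below the
    cutoff. The two routes are therefore disjoint.
    """
    weights = weights or ScoreWeights()
    if score < 0:
        raise ValidationError(f"risk score must be non-negative, got {score}")
    if score >= weights.cutoff:
        return RiskAssessment(int(score), True, InclusionRoute.SCORE)
    if clinical_judgment:
        return RiskAssessment(int(score), True, InclusionRoute.JUDGMENT)
    return RiskAssessment(int(score), False, InclusionRoute.NOT_INCLUDED)


def derive_hypotension(systolic: float, diastolic: float) -> bool:
    """Derive the hypotension flag from a measured blood pressure.

    The clinical rule "BP < 90/60 mmHg" is read disjunctively: systolic below
    90 OR diastolic below 60. A clinician-supplied hypotension flag (which may
    encode *relative* hypotension no threshold can capture) always takes
    precedence over this derivation; callers apply it only when the flag is
    absent and a measured BP exists.
    """
    if not (systolic > diastolic > 0):
        raise ValidationError(
            f"non-physiological blood pressure: systolic={systolic!r}, diastolic={diastolic!r}"
        )
    return systolic < 90 or diastolic < 60


def score_patients(
    patients: pd.DataFrame,
    weights: ScoreWeights | None = None,
    absent_if_missing: bool = False,
) -> pd.DataFrame:
    """Vectorised scoring of a patient table (one row per patient).

    Expects the ``sx_*`` columns of the patient-record CSV schema plus an
    optional ``clinical_judgment`` column (treated as 0 when absent). When
    ``sx_hypotension`` is null for a row and ``sbp``/``dbp`` are present, the
    flag is derived from the measured pressure. Returns a copy with
    ``risk_score``, ``at_risk`` and ``inclusion_route`` columns appended.
    """
    weights = weights or ScoreWeights()
    out = patients.copy()

    cols = {}
    for name in SYMPTOM_FIELDS:
        col = SYMPTOM_COLUMNS[name]
        if col not in out.columns:
            raise ValidationError(f"missing required symptom column: {col!r}")
        cols[name] = out[col].copy()

    hypo = cols["hypotension"]
    if hypo.isna().any() and {"sbp", "dbp"}.issubset(out.columns):
        derivable = hypo.isna() & out["sbp"].notna() & out["dbp"].notna()
        if derivable.any():
            sbp = out.loc[derivable, "sbp"].astype(float)
            dbp = out.loc[derivable, "dbp"].astype(float)
            bad = ~(sbp > dbp) | ~(dbp > 0)
            if bad.any():
                raise ValidationError(
                    "non-physiological blood pressure for patient rows: "
                    f"{list(out.index[derivable][bad])}"
                )
            cols["hypotension"] = hypo.mask(derivable, (sbp < 90) | (dbp < 60))

    matrix = np.zeros((len(out), len(SYMPTOM_FIELDS)))
    for j, name in enumerate(SYMPTOM_FIELDS):
        series = cols[name]
        if series.isna().any():
            if not absent_if_missing:
                idx = list(out.index[series.isna()])[:5]
                raise ValidationError(
                    f"missing symptom flag {SYMPTOM_COLUMNS[name]!r} for rows {idx}; "
                    "use absent_if_missing=True to treat missing as absent"
                )
            series = series.fillna(0)
        vals = series.astype(float).to_numpy()
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError(
                f"symptom column {SYMPTOM_COLUMNS[name]!r} must be binary 0/1"
            )
        matrix[:, j] = vals

    score = matrix @ weights.as_vector()
    out["risk_score"] = score.astype(int)
    judgment = (
        out["clinical_judgment"].fillna(0).astype(float).astype(bool)
        if "clinical_judgment" in out.columns
        else pd.Series(False, index=out.index)
    )
    route = np.where(
        out["risk_score"] >= weights.cutoff,
        InclusionRoute.SCORE.value,
        np.where(judgment, InclusionRoute.JUDGMENT.value, InclusionRoute.NOT_INCLUDED.value),
    )
    out["inclusion_route"] = route
    out["at_risk"] = out["inclusion_route"] != InclusionRoute.NOT_INCLUDED.value
    return out
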