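"""Patient-record CSV schema, validation, and run configuration.

Two CSV tables describe a cohort: a patient table (one row per patient:
demographics, symptom flags, outcome flags) and a long-format creatinine
table (one row per measurement, keyed by ``patient_id``). Timestamps are
ISO-8601; creatinine may be given in mg/dL or micromol/L per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from .errors import ValidationError
from .kidney_function import SCR_MAX_MGDL, UMOL_PER_MGDL
from .risk_scoring import DEFAULT_CUTOFF, DEFAULT_POINTS, SYMPTOM_COLUMNS, ScoreWeights
from .synthetic import CohortConfig, SyntheticCohort

log = logging.getLogger("akdscreen")

PATIENT_REQUIRED = ["patient_id", "age", "sex", "admission_time"] + list(
    SYMPTOM_COLUMNS.values()
)
PATIENT_OPTIONAL = [
    "female",
    "sbp",
    "dbp",
    "clinical_judgment",
    "facility_type",
    "chronicity_evidence",
    "etiology",
    "died_inhospital",
    "krt_indicated",
    "krt_provided",
    "transfer_recommended",
    "transfer_occurred",
    "followup_attended",
]
SCR_REQUIRED = ["patient_id", "scr_value", "scr_time"]
SCR_OPTIONAL = ["scr_unit", "scr_source", "scr_context", "scr_value_true"]


@dataclass
class CohortData:
    """Validated patient + measurement tables for a cohort."""

    patients: pd.DataFrame
    measurements: pd.DataFrame


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run; fully serializable."""

    points: dict = field(default_factory=lambda: dict(DEFAULT_POINTS))
    cutoff: int = DEFAULT_CUTOFF
    absent_if_missing: bool = False
    egfr_variant: str = "ckd_epi_2021"
    baseline_policy: str = "combined_min"
    lookback_days: int = 365
    recovery_complete_ratio: float = 1.25
    recovery_none_ratio: float = 1.5
    recovery_none_absolute: float = 0.3
    followup_window_days: tuple[int, int] = (60, 120)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def weights(self) -> ScoreWeights:
        return ScoreWeights({k: int(v) for k, v in self.points.items()}, int(self.cutoff))

    def to_dict(self) -> dict:
        return {
            "points": dict(self.points),
            "cutoff": self.cutoff,
            "absent_if_missing": self.absent_if_missing,
            "egfr_variant": self.egfr_variant,
            "baseline_policy": self.baseline_policy,
            "lookback_days": self.lookback_days,
            "recovery_complete_ratio": self.recovery_complete_ratio,
            "recovery_none_ratio": self.recovery_none_ratio,
            "recovery_none_absolute": self.recovery_none_absolute,
            "followup_window_days": list(self.followup_window_days),
            "cohort": self.cohort.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "followup_window_days" in d:
            d["followup_window_days"] = tuple(d["followup_window_days"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PATIENT_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"patient table missing required columns: {missing}")
    known = set(PATIENT_REQUIRED) | set(PATIENT_OPTIONAL)
    unknown = [
        c
        for c in df.columns
        if c not in known and not c.startswith(("latent_", "true_"))
        and c not in ("risk_score", "at_risk", "inclusion_route")
    ]
    if unknown:
        log.warning("ignoring unknown patient columns: %s", unknown)
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate patient_id values: {sorted(set(dup))[:5]}")
    df = df.copy()
    df["admission_time"] = pd.to_datetime(df["admission_time"])
    if "female" not in df.columns:
        df["female"] = (df["sex"].astype(str).str.lower() == "female").astype(int)
    bad_sex = ~df["sex"].astype(str).str.lower().isin(["female", "male"])
    if bad_sex.any():
        raise ValidationError(
            f"invalid sex values at rows {list(df.index[bad_sex] + 2)[:5]} (expect female/male)"
        )
    return df


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCR_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"creatinine table missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in SCR_REQUIRED + SCR_OPTIONAL]
    if unknown:
        log.warning("ignoring unknown creatinine columns: %s", unknown)
    df = df.copy()
    df["scr_time"] = pd.to_datetime(df["scr_time"])
    if "scr_unit" not in df.columns:
        df["scr_unit"] = "mgdl"
    if "scr_source" not in df.columns:
        df["scr_source"] = "poc"
    if "scr_context" not in df.columns:
        df["scr_context"] = "enrol"

    umol = df["scr_unit"].astype(str).str.lower().isin(["umol", "umol/l", "µmol/l"])
    if umol.any():
        df.loc[umol, "scr_value"] = df.loc[umol, "scr_value"] / UMOL_PER_MGDL
        df.loc[umol, "scr_unit"] = "mgdl"
        log.info("converted %d creatinine rows from umol/L to mg/dL", int(umol.sum()))
    bad_unit = ~df["scr_unit"].astype(str).str.lower().eq("mgdl")
    if bad_unit.any():
        raise ValidationError(
            f"unknown creatinine units at rows {list(df.index[bad_unit] + 2)[:5]}"
        )
    bad = ~((df["scr_value"] > 0) & (df["scr_value"] <= SCR_MAX_MGDL))
    if bad.any():
        raise ValidationError(
            "creatinine values outside (0, 30] mg/dL at rows "
            f"{list(df.index[bad] + 2)[:5]}"
        )
    return df.sort_values(["patient_id", "scr_time"], kind="mergesort").reset_index(drop=True)


def read_cohort(patients_path, measurements_path=None) -> CohortData:
    """Read and validate a cohort; returns the two validated tables.

    Cross-table checks: every measurement's ``patient_id`` must exist in the
    patient table, and outcome implications (KRT provided implies indicated,
    transfer occurred implies recommended) must hold.
    """
    patients = read_patients(patients_path)
    if measurements_path is not None:
        meas = read_measurements(measurements_path)
        orphan = ~meas["patient_id"].isin(set(patients["patient_id"]))
        if orphan.any():
            raise ValidationError(
                f"measurements reference unknown patient_id: {sorted(set(meas['patient_id'][orphan]))[:5]}"
            )
    else:
        meas = pd.DataFrame(columns=SCR_REQUIRED + SCR_OPTIONAL)

    for a, b in (("krt_provided", "krt_indicated"), ("transfer_occurred", "transfer_recommended")):
        if a in patients.columns and b in patients.columns:
            viol = patients[a].fillna(0).astype(bool) & ~patients[b].fillna(0).astype(bool)
            if viol.any():
                raise ValidationError(
                    f"{a} without {b} for patients {list(patients['patient_id'][viol])[:5]}"
                )
    return CohortData(patients, meas)


def write_cohort(cohort: SyntheticCohort | CohortData, prefix: str) -> tuple[str, str]:
    """Write the two cohort tables as ``<prefix>.patients.csv`` / ``<prefix>.scr.csv``."""
    p_path, m_path = f"{prefix}.patients.csv", f"{prefix}.scr.csv"
    patients, meas = cohort.patients, cohort.measurements
    patients.to_csv(p_path, index=False)
    meas.to_csv(m_path, index=False)
    return p_path, m_path
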