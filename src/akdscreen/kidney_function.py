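"""Creatinine measurements, unit conversion, and CKD-EPI estimated GFR.

The estimated glomerular filtration rate (eGFR) is computed from serum
creatinine (SCr), age and sex with the race-free CKD-EPI equation:

    eGFR = a * min(SCr/kappa, 1)^alpha * max(SCr/kappa, 1)^beta * d^age * s

where ``kappa`` and ``alpha`` are sex-specific, ``beta`` is the common slope
for creatinine above ``kappa``, ``d`` is the per-year age decay and ``s`` the
female multiplier. The default parameter set is the 2021 race-free refit
(a=142, kappa=0.7/0.9 F/M, alpha=-0.241/-0.302, beta=-1.200, d=0.9938,
s=1.012); the 2009 equation with its race coefficient dropped is available as
the variant ``ckd_epi_2009_no_race``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, ValidationError

#: micromol/L of creatinine per mg/dL.
UMOL_PER_MGDL = 88.42

#: Sanity bound on serum creatinine in mg/dL; values above it are data errors.
SCR_MAX_MGDL = 30.0


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Source(str, enum.Enum):
    """Where a creatinine measurement was made."""

    POC = "poc"
    LABORATORY = "lab"


class Context(str, enum.Enum):
    """Clinical context of a creatinine measurement."""

    PRE_ADMISSION = "pre"
    ENROLLMENT = "enrol"
    IN_ADMISSION = "inadm"
    DISCHARGE = "disch"
    FOLLOWUP = "fup"


#: Contexts that count as "during the healthcare facility admission".
ADMISSION_CONTEXTS = frozenset(
    {Context.ENROLLMENT, Context.IN_ADMISSION, Context.DISCHARGE}
)


def convert_umol_to_mgdl(value: float) -> float:
    """Convert serum creatinine from micromol/L to mg/dL (divide by 88.42)."""
    if not value > 0:
        raise ValidationError(f"creatinine must be positive, got {value!r}")
    return value / UMOL_PER_MGDL


@dataclass(frozen=True)
class Demographics:
    """Age (years, adults only) and sex used by the eGFR equation."""

    age: int
    sex: Sex

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        if not (isinstance(self.age, (int, np.integer)) and self.age >= 18):
            raise DomainError(f"age must be an integer >= 18 years, got {self.age!r}")

    @property
    def female(self) -> bool:
        return self.sex is Sex.FEMALE


@dataclass(frozen=True)
class CreatinineMeasurement:
    """One timestamped serum creatinine value in mg/dL with its provenance."""

    value: float
    time: datetime
    source: Source = Source.POC
    context: Context = Context.ENROLLMENT

    def __post_init__(self):
        object.__setattr__(self, "source", Source(self.source))
        object.__setattr__(self, "context", Context(self.context))
        if not (0 < self.value <= SCR_MAX_MGDL):
            raise ValidationError(
                f"creatinine {self.value!r} mg/dL outside sanity range (0, {SCR_MAX_MGDL}]"
            )
        if not isinstance(self.time, datetime):
            raise ValidationError(f"measurement time must be a datetime, got {self.time!r}")


@dataclass(frozen=True)
class CreatinineSeries:
    """A patient's creatinine measurements, strictly ordered by time."""

    measurements: tuple[CreatinineMeasurement, ...]

    def __init__(self, measurements: Iterable[CreatinineMeasurement]):
        ms = tuple(sorted(measurements, key=lambda m: m.time))
        object.__setattr__(self, "measurements", ms)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def __getitem__(self, i):
        return self.measurements[i]

    def in_context(self, contexts) -> tuple[CreatinineMeasurement, ...]:
        contexts = frozenset(Context(c) for c in contexts) if not isinstance(contexts, frozenset) else contexts
        return tuple(m for m in self.measurements if m.context in contexts)


@dataclass(frozen=True)
class GfrEquationParams:
    """Constants of the CKD-EPI creatinine equation (race-free form)."""

    intercept: float = 142.0
    kappa_female: float = 0.7
    kappa_male: float = 0.9
    alpha_female: float = -0.241
    alpha_male: float = -0.302
    slope_exponent: float = -1.200
    age_decay: float = 0.9938
    female_multiplier: float = 1.012
    name: str = "ckd_epi_2021"

    @classmethod
    def ckd_epi_2021(cls) -> "GfrEquationParams":
        return cls()

    @classmethod
    def ckd_epi_2009_no_race(cls) -> "GfrEquationParams":
        """The 2009 CKD-EPI equation with the race coefficient dropped."""
        return cls(
            intercept=141.0,
            kappa_female=0.7,
            kappa_male=0.9,
            alpha_female=-0.329,
            alpha_male=-0.411,
            slope_exponent=-1.209,
            age_decay=0.993,
            female_multiplier=1.018,
            name="ckd_epi_2009_no_race",
        )

    @classmethod
    def variant(cls, name: str) -> "GfrEquationParams":
        try:
            return {"ckd_epi_2021": cls.ckd_epi_2021, "ckd_epi_2009_no_race": cls.ckd_epi_2009_no_race}[name]()
        except KeyError:
            raise ValidationError(f"unknown eGFR equation variant: {name!r}") from None


def egfr_values(
    scr,
    age,
    female,
    params: GfrEquationParams | None = None,
):
    """Vectorised CKD-EPI eGFR; ``scr``, ``age``, ``female`` broadcast together.

    ``scr`` in mg/dL, ``age`` in years, ``female`` boolean. Returns
    mL/min/1.73 m^2 as a float array (or scalar).
    """
    p = params or GfrEquationParams()
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    kappa = np.where(female, p.kappa_female, p.kappa_male)
    alpha = np.where(female, p.alpha_female, p.alpha_male)
    ratio = scr / kappa
    g = (
        p.intercept
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** p.slope_exponent
        * p.age_decay ** age
        * np.where(female, p.female_multiplier, 1.0)
    )
    return g


def egfr(scr: float, demo: Demographics, params: GfrEquationParams | None = None) -> float:
    """CKD-EPI eGFR (mL/min/1.73 m^2) for one creatinine value and patient.

    Strictly decreasing in both creatinine and age for fixed sex.
    """
    if not (0 < scr <= SCR_MAX_MGDL):
        raise ValidationError(f"creatinine {scr!r} mg/dL outside sanity range (0, {SCR_MAX_MGDL}]")
    return float(egfr_values(scr, demo.age, demo.female, params))


@dataclass(frozen=True)
class EgfrPoint:
    """An eGFR value carrying the timestamp/provenance of its measurement."""

    egfr: float
    time: datetime
    source: Source
    context: Context
    scr: float


def egfr_series(
    series: CreatinineSeries,
    demo: Demographics,
    params: GfrEquationParams | None = None,
) -> tuple[EgfrPoint, ...]:
    """Element-wise eGFR over a time-ordered creatinine series."""
    if len(series) == 0:
        raise ValidationError("cannot compute eGFR over an empty creatinine series")
    return tuple(
        EgfrPoint(egfr(m.value, demo, params), m.time, m.source, m.context, m.value)
        for m in series
    )
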