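"""Cohort tabulation and screening-score performance evaluation.

Reporting conventions are fixed so printed aggregates are reproducible:
percentages are rounded half away from zero to one decimal (so 81.25% prints
as 81.3%), and medians/IQRs use linearly interpolated (type-7) quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .kdigo import Category
from .risk_scoring import InclusionRoute


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (not banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> Optional[float]:
    """100 * numerator / denominator, rounded half away from zero to 1 decimal.

    A zero denominator yields ``None`` (rendered as an em-dash), not an
    exception.
    """
    if denominator == 0:
        return None
    if not (0 <= numerator <= denominator):
        raise ValidationError(
            f"numerator must lie in [0, denominator], got {numerator}/{denominator}"
        )
    frac = Fraction(100 * int(numerator), int(denominator))
    return float(
        (Decimal(frac.numerator) / Decimal(frac.denominator)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linearly interpolated (type-7) quartiles."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("median/IQR of an empty list is undefined")
    med, q1, q3 = np.percentile(arr, [50, 25, 75])
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class ScorePerformance:
    """Operating characteristics of the risk score against a binary label."""

    auroc: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    cutoff: int
    n_positive: int
    n_negative: int
    sweep: pd.DataFrame = field(repr=False)


def evaluate_score(
    scores: Sequence[float], labels: Sequence[bool], cutoff: int = 10
) -> ScorePerformance:
    """AUROC (ties counted 1/2) and sensitivity/specificity at ``score >= cutoff``.

    The AUROC uses the rank (Mann-Whitney) formulation, equivalent to the
    proportion of positive-negative pairs ranked concordantly with ties
    contributing one half. Requires at least one positive and one negative
    label.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC is undefined with single-class labels")

    ranks = rankdata(s)
    auroc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    positive = s >= cutoff
    sens = float((positive & y).sum() / n_pos)
    spec = float((~positive & ~y).sum() / n_neg)

    thresholds = np.arange(0, int(s.max()) + 2)
    rows = []
    for t in thresholds:
        pos_t = s >= t
        rows.append(
            {
                "threshold": int(t),
                "sensitivity": float((pos_t & y).sum() / n_pos),
                "specificity": float((~pos_t & ~y).sum() / n_neg),
            }
        )
    sweep = pd.DataFrame(rows)
    return ScorePerformance(float(auroc), sens, spec, int(cutoff), n_pos, n_neg, sweep)


@dataclass(frozen=True)
class CohortSummary:
    """Counts and rates shaped like the project's cohort table.

    Denominators follow the reporting conventions: stage percentages are of
    the AKI count, deaths and KRT-indicated of the AKD count, KRT provided of
    KRT indicated, transfer occurred of transfer recommended, and follow-up of
    discharged (surviving) AKD patients.
    """

    screened: int
    excluded: int
    included: int
    route_score: int
    route_judgment: int
    risk_score_median_iqr: Optional[tuple[float, float, float]]
    category_counts: dict[str, int]
    stage_counts: dict[int, int]
    poc_n: int
    enrollment_scr_median_iqr: Optional[tuple[float, float, float]]
    enrollment_egfr_median_iqr: Optional[tuple[float, float, float]]
    age_median_iqr: Optional[tuple[float, float, float]]
    female_n: int
    deaths_akd: int
    krt_indicated: int
    krt_provided: int
    transfer_recommended: int
    transfer_occurred: int
    followup_attended: int
    discharged_akd: int

    @property
    def n_akd(self) -> int:
        return self.category_counts.get(Category.AKD_WITH_AKI.value, 0) + self.category_counts.get(
            Category.AKD_WITHOUT_AKI.value, 0
        )

    @property
    def n_aki(self) -> int:
        return self.category_counts.get(Category.AKD_WITH_AKI.value, 0)

    def pct(self, item: str) -> Optional[float]:
        """Percentage for a named item under the table's denominator rules."""
        num_den = {
            "excluded": (self.excluded, self.screened),
            "included": (self.included, self.screened),
            "route_score": (self.route_score, self.included),
            "route_judgment": (self.route_judgment, self.included),
            "poc": (self.poc_n, self.included),
            "female": (self.female_n, self.included),
            "akd": (self.n_akd, self.included),
            "deaths_akd": (self.deaths_akd, self.n_akd),
            "krt_indicated": (self.krt_indicated, self.n_akd),
            "krt_provided": (self.krt_provided, self.krt_indicated),
            "transfer_recommended": (self.transfer_recommended, self.included),
            "transfer_occurred": (self.transfer_occurred, self.transfer_recommended),
            "followup_attended": (self.followup_attended, self.discharged_akd),
        }
        for cat in Category:
            num_den[cat.value] = (self.category_counts.get(cat.value, 0), self.included)
        for st in (1, 2, 3):
            num_den[f"stage{st}"] = (self.stage_counts.get(st, 0), self.n_aki)
        if item not in num_den:
            raise KeyError(item)
        return percentage(*num_den[item])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (block, item, n, percent) table."""
        rows = [
            ("screening", "screened", self.screened, None),
            ("screening", "excluded", self.excluded, self.pct("excluded")),
            ("screening", "included", self.included, self.pct("included")),
            ("screening", "route_score", self.route_score, self.pct("route_score")),
            ("screening", "route_judgment", self.route_judgment, self.pct("route_judgment")),
            ("demographics", "female", self.female_n, self.pct("female")),
            ("measurement", "poc", self.poc_n, self.pct("poc")),
        ]
        for cat in Category:
            rows.append(
                ("classification", cat.value, self.category_counts.get(cat.value, 0), self.pct(cat.value))
            )
        for st in (1, 2, 3):
            rows.append(
                ("classification", f"aki_stage_{st}", self.stage_counts.get(st, 0), self.pct(f"stage{st}"))
            )
        rows += [
            ("outcomes", "deaths_akd", self.deaths_akd, self.pct("deaths_akd")),
            ("outcomes", "krt_indicated", self.krt_indicated, self.pct("krt_indicated")),
            ("outcomes", "krt_provided", self.krt_provided, self.pct("krt_provided")),
            ("outcomes", "transfer_recommended", self.transfer_recommended, self.pct("transfer_recommended")),
            ("outcomes", "transfer_occurred", self.transfer_occurred, self.pct("transfer_occurred")),
            ("outcomes", "followup_attended", self.followup_attended, self.pct("followup_attended")),
        ]
        return pd.DataFrame(rows, columns=["block", "item", "n", "percent"])

    def to_text(self) -> str:
        def fmt_pct(p):
            return "—" if p is None else f"{p:.1f}"

        def fmt_mi(t, nd=1):
            if t is None:
                return "—"
            m, q1, q3 = t
            f = f"{{:.{nd}f}}"
            return f"{f.format(m)} ({f.format(q1)}-{f.format(q3)})"

        lines = ["Cohort summary", "==============", ""]
        lines.append(f"Screened: {self.screened}")
        lines.append(f"Excluded: {self.excluded} ({fmt_pct(self.pct('excluded'))}%)")
        lines.append(f"Included: {self.included} ({fmt_pct(self.pct('included'))}%)")
        lines.append(f"  via score >= cutoff: {self.route_score} ({fmt_pct(self.pct('route_score'))}%)")
        lines.append(f"  via clinical judgment: {self.route_judgment} ({fmt_pct(self.pct('route_judgment'))}%)")
        lines.append(f"Risk score (median; IQR): {fmt_mi(self.risk_score_median_iqr, 0)}")
        lines.append(f"Female: {self.female_n} ({fmt_pct(self.pct('female'))}%)")
        lines.append(f"Age (median; IQR): {fmt_mi(self.age_median_iqr, 0)}")
        lines.append(f"SCr by POC device: {self.poc_n} ({fmt_pct(self.pct('poc'))}%)")
        lines.append(f"Enrollment SCr mg/dL (median; IQR): {fmt_mi(self.enrollment_scr_median_iqr)}")
        lines.append(f"Enrollment eGFR (median; IQR): {fmt_mi(self.enrollment_egfr_median_iqr, 0)}")
        lines.append("")
        for cat in Category:
            lines.append(
                f"{cat.value}: {self.category_counts.get(cat.value, 0)} ({fmt_pct(self.pct(cat.value))}%)"
            )
        for st in (1, 2, 3):
            lines.append(
                f"  AKI stage {st}: {self.stage_counts.get(st, 0)} ({fmt_pct(self.pct(f'stage{st}'))}% of AKI)"
            )
        lines.append("")
        lines.append(f"In-hospital deaths (AKD): {self.deaths_akd} ({fmt_pct(self.pct('deaths_akd'))}%)")
        lines.append(f"KRT indicated: {self.krt_indicated} ({fmt_pct(self.pct('krt_indicated'))}% of AKD)")
        lines.append(f"KRT provided: {self.krt_provided} ({fmt_pct(self.pct('krt_provided'))}% of indicated)")
        lines.append(
            f"Transfer recommended: {self.transfer_recommended} ({fmt_pct(self.pct('transfer_recommended'))}%)"
        )
        lines.append(
            f"Transfer occurred: {self.transfer_occurred} ({fmt_pct(self.pct('transfer_occurred'))}% of recommended)"
        )
        lines.append(
            f"Followed up (of discharged AKD): {self.followup_attended} ({fmt_pct(self.pct('followup_attended'))}%)"
        )
        return "\n".join(lines)


def summarize_cohort(
    frame: pd.DataFrame,
    screened: Optional[int] = None,
    excluded: int = 0,
) -> CohortSummary:
    """Tabulate a classified cohort frame into a :class:`CohortSummary`.

    ``frame`` holds one row per included patient with at least the columns
    produced by the pipeline: ``risk_score``, ``inclusion_route``,
    ``category``, ``aki_stage``, plus (optionally) ``age``, ``female``,
    ``enrollment_scr``, ``enrollment_egfr``, ``enrollment_source`` and the
    outcome flags. ``screened``/``excluded`` describe patients upstream of
    inclusion and default to the included count / zero.
    """
    n = len(frame)
    screened = int(screened) if screened is not None else n + excluded

    def col(name, default=None):
        return frame[name] if name in frame.columns else default

    route = col("inclusion_route")
    route_score = int((route == InclusionRoute.SCORE.value).sum()) if route is not None else 0
    route_judgment = int((route == InclusionRoute.JUDGMENT.value).sum()) if route is not None else 0

    classified = frame[frame["category"].notna()] if "category" in frame.columns else frame.iloc[0:0]
    category_counts = {
        cat.value: int((classified["category"] == cat.value).sum()) for cat in Category
    } if len(classified) else {cat.value: 0 for cat in Category}
    aki = classified[classified.get("category") == Category.AKD_WITH_AKI.value] if len(classified) else classified
    stage_counts = {
        st: int((aki["aki_stage"] == st).sum()) if len(aki) else 0 for st in (1, 2, 3)
    }

    def mi(series, mask=None):
        if series is None:
            return None
        vals = series if mask is None else series[mask]
        vals = vals.dropna()
        return median_iqr(vals) if len(vals) else None

    is_akd = (
        frame["category"].isin([Category.AKD_WITH_AKI.value, Category.AKD_WITHOUT_AKI.value])
        if "category" in frame.columns
        else pd.Series(False, index=frame.index)
    )
    died = col("died_inhospital")
    died = died.fillna(False).astype(bool) if died is not None else pd.Series(False, index=frame.index)

    def flag_sum(name, mask=None):
        s = col(name)
        if s is None:
            return 0
        s = s.fillna(False).astype(bool)
        if mask is not None:
            s = s & mask
        return int(s.sum())

    src = col("enrollment_source")
    poc_n = int((src == "poc").sum()) if src is not None else 0
    female = col("female")
    female_n = int(female.fillna(False).astype(bool).sum()) if female is not None else 0

    return CohortSummary(
        screened=screened,
        excluded=int(excluded),
        included=n,
        route_score=route_score,
        route_judgment=route_judgment,
        risk_score_median_iqr=mi(col("risk_score")),
        category_counts=category_counts,
        stage_counts=stage_counts,
        poc_n=poc_n,
        enrollment_scr_median_iqr=mi(col("enrollment_scr")),
        enrollment_egfr_median_iqr=mi(col("enrollment_egfr")),
        age_median_iqr=mi(col("age")),
        female_n=female_n,
        deaths_akd=flag_sum("died_inhospital", is_akd),
        krt_indicated=flag_sum("krt_indicated", is_akd),
        krt_provided=flag_sum("krt_provided", is_akd),
        transfer_recommended=flag_sum("transfer_recommended"),
        transfer_occurred=flag_sum("transfer_occurred"),
        followup_attended=flag_sum("followup_attended", is_akd & ~died),
        discharged_akd=int((is_akd & ~died).sum()),
    )
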