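"""Ordinal deterioration grading relative to baseline, and grade tabulation.

Continuous indicators are mapped to grades 0-4 with cutoffs adapted from
CTCAE v.3: for pulmonary function tests, the percent decline from baseline in
(10%, 25%] is grade 1, (25%, 50%] grade 2, (50%, 75%] grade 3 and >75% grade
4; for LVEF the same scheme is applied to the absolute percentage-point drop
with bounds 10/20/30/50.  Intervals are left-open, right-closed exactly as
stated, so a decline of exactly 10% is still grade 0, and improvements always
map to grade 0.  RTOG clinician grades pass through unchanged.  Raw 1-4
patient-reported scores are linearly rescaled to 0-100 and categorized as
mild [0, 20], moderate (20, 40], severe >40.

The tabulation mirrors the descriptive grade table of the source analysis:
counts and column-wise percentages per indicator x grade, split by follow-up
period (<=5 years vs >5 years) and arm.  No hypothesis tests are attached to
the table; it is descriptive only.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .simulate import CONTINUOUS_INDICATORS, ORDINAL_INDICATORS, QLQ_INDICATORS

__all__ = [
    "QLQ_CATEGORIES",
    "pft_grade",
    "lvef_grade",
    "qlq_scale",
    "qlq_category",
    "category_rank",
    "rv_invert",
    "grade_cohort",
    "tabulate_grades",
    "category_odds",
]

_PFT_BOUNDS = (10.0, 25.0, 50.0, 75.0)
_LVEF_BOUNDS = (10.0, 20.0, 30.0, 50.0)

QLQ_CATEGORIES = ("mild", "moderate", "severe")


def _grade_from_bounds(decline: float, bounds: tuple[float, ...]) -> int:
    # left-open, right-closed intervals; anything <= first bound is grade 0
    grade = 0
    for b in bounds:
        if decline > b:
            grade += 1
    return grade


def pft_grade(baseline: float, value: float) -> int:
    """Grade 0-4 for a pulmonary-function measurement relative to baseline.

    Percent decline 100*(baseline - value)/baseline; declines of at most 10%
    (including any improvement) are grade 0.
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    decline = 100.0 * (baseline - value) / baseline
    return _grade_from_bounds(decline, _PFT_BOUNDS)


def lvef_grade(baseline: float, value: float, *, relative: bool = False) -> int:
    """Grade 0-4 for left ventricular ejection fraction relative to baseline.

    The default interprets the change as the absolute percentage-point drop
    ``baseline - value`` (CTCAE classifies resting ejection fraction by
    absolute change); ``relative=True`` uses percent change from baseline
    instead, for sensitivity analyses.
    """
    for name, v in (("baseline", baseline), ("value", value)):
        if not 0.0 < v <= 100.0:
            raise ValueError(f"LVEF {name} must be in (0, 100], got {v}")
    drop = baseline - value
    if relative:
        drop = 100.0 * drop / baseline
    return _grade_from_bounds(drop, _LVEF_BOUNDS)


def qlq_scale(raw_mean: float, item_range: int = 3) -> float:
    """Linear 0-100 transform of a raw QLQ symptom score.

    ``score = 100 * (raw_mean - 1) / item_range``; 4-level items have
    ``item_range = 3``.  Higher = worse symptom burden.
    """
    if item_range <= 0:
        raise ValueError("item_range must be positive")
    if not 1.0 <= raw_mean <= 1.0 + item_range:
        raise ValueError(f"raw_mean must be in [1, {1 + item_range}], got {raw_mean}")
    return 100.0 * (raw_mean - 1.0) / item_range


def qlq_category(score: float) -> str:
    """Symptom category for a 0-100 QLQ score: mild [0,20], moderate (20,40], severe >40."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score must be in [0, 100], got {score}")
    if score <= 20.0:
        return "mild"
    if score <= 40.0:
        return "moderate"
    return "severe"


def category_rank(category: str) -> int:
    """Ordinal rank of a symptom category (mild=0, moderate=1, severe=2)."""
    return QLQ_CATEGORIES.index(category)


def rv_invert(rv: float) -> float:
    """Transform residual volume to RVinv = log(1/RV) = -log(RV).

    RV increases when lung function declines; the inversion makes decreasing
    values indicate deterioration, consistent with the other pulmonary tests.
    """
    if rv <= 0:
        raise ValueError(f"RV must be positive, got {rv}")
    return -math.log(rv)


def grade_cohort(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    *,
    lvef_relative: bool = False,
) -> pd.DataFrame:
    """Grade every post-baseline measurement relative to the patient's baseline.

    Returns a long table with columns ``patient_id, arm, indicator,
    time_years, grade`` where grade is an integer 0-4 for continuous and RTOG
    indicators and a category string for the QLQ scales.  Continuous
    indicators require a baseline (t=0) record; patients lacking one are
    skipped for that indicator.  RV is reported as RVinv, graded on the
    percent *increase* of raw RV from baseline (deterioration direction).
    """
    arm_of = patients.set_index("patient_id")["arm"]
    rows = []
    for (pid, ind), grp in measurements.groupby(["patient_id", "indicator"], sort=False):
        grp = grp.sort_values("time_years")
        base_rows = grp[grp["time_years"] == 0.0]
        post = grp[grp["time_years"] > 0.0]
        if post.empty:
            continue
        arm = arm_of.get(pid)
        if ind in QLQ_INDICATORS:
            out_ind = ind.replace("_RAW", "")
            for t, v in zip(post["time_years"], post["value"]):
                rows.append((pid, arm, out_ind, t, qlq_category(qlq_scale(v))))
        elif ind in ORDINAL_INDICATORS:
            for t, v in zip(post["time_years"], post["value"]):
                rows.append((pid, arm, ind, t, int(v)))
        else:
            if base_rows.empty:
                continue
            base = float(base_rows["value"].iloc[0])
            if ind == "LVEF":
                for t, v in zip(post["time_years"], post["value"]):
                    rows.append((pid, arm, ind, t, lvef_grade(base, v, relative=lvef_relative)))
            elif ind == "RV":
                # increase-is-worse: reuse the PFT cutoffs on percent increase
                for t, v in zip(post["time_years"], post["value"]):
                    rows.append((pid, arm, "RVinv", t, pft_grade(base, 2.0 * base - v)))
            else:
                for t, v in zip(post["time_years"], post["value"]):
                    rows.append((pid, arm, ind, t, pft_grade(base, v)))
    return pd.DataFrame(rows, columns=["patient_id", "arm", "indicator", "time_years", "grade"])


def tabulate_grades(grade_records: pd.DataFrame, split: float = 5.0) -> pd.DataFrame:
    """Counts and column-wise percentages per indicator x grade x period x arm.

    ``period`` is ``<=5y`` or ``>5y`` by measurement time (with the given
    split point).  Percentages sum to 100 within each indicator x period x
    arm block, up to rounding.  Empty input yields an empty table.
    """
    if grade_records.empty:
        return pd.DataFrame(columns=["indicator", "grade", "period", "arm", "count", "percent"])
    rec = grade_records.copy()
    le = f"<={split:g}y"
    gt = f">{split:g}y"
    rec["period"] = np.where(rec["time_years"] <= split, le, gt)
    counts = (
        rec.groupby(["indicator", "period", "arm", "grade"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(["indicator", "period", "arm"])["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    return counts[["indicator", "grade", "period", "arm", "count", "percent"]]


def category_odds(percent_mild: float, percent_moderate: float, percent_severe: float) -> float:
    """Odds of moderate-severe versus mild symptoms from printed percentages.

    ``(moderate + severe) / mild`` on the percentages as printed, rounded to
    3 decimals.
    """
    if min(percent_mild, percent_moderate, percent_severe) < 0:
        raise ValueError("percentages must be non-negative")
    if percent_mild == 0:
        raise ValueError("odds undefined when the mild percentage is zero")
    return round((percent_moderate + percent_severe) / percent_mild, 3)
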