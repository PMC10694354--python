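"""Per-patient time-to-d%-alteration (TTA) and the composite first event.

The core statistic: for each patient and each continuous lung/heart
indicator, an ordinary least-squares line is fitted to that patient's
measurement series.  If the fitted slope shows a significant decline
(slope < 0 and two-sided slope p-value below ``alpha_slope``), the TTA is
the time at which the fitted line crosses the deterioration threshold
``(1 - d) * baseline``; a crossing beyond the patient's follow-up censors the
patient at follow-up, as does absence of a significant decline.  Ordinal
indicators (RTOG clinician grades, fatigue/dyspnea symptom categories)
contribute an event at the first visit whose grade exceeds the baseline
grade.  The composite toxicity event is the first occurrence across the four
component families: lung TTA (FEV1/FVC, DLCO/VA, TLC), heart TTA (LVEF),
RTOG grade increase, and fatigue-dyspnea category increase.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grading import category_rank, qlq_category, qlq_scale

logger = logging.getLogger(__name__)

__all__ = [
    "LUNG_COMPONENTS",
    "HEART_COMPONENTS",
    "TrajectoryFit",
    "TTAResult",
    "CompositeEvent",
    "fit_trajectory",
    "time_to_alteration",
    "ordinal_event_time",
    "derive_ratio_series",
    "composite_tta",
    "compute_composite_events",
    "sensitivity_sweep",
]

# Default continuous components of the composite, as derived series.
LUNG_COMPONENTS = ("FEV1/FVC", "DLCO/VA", "TLC")
HEART_COMPONENTS = ("LVEF",)
_RATIO_PARTS = {"FEV1/FVC": ("FEV1", "FVC"), "DLCO/VA": ("DLCO", "VA")}

_COMPONENT_PRECEDENCE = ("lung_tta", "heart_tta", "rtog_increase", "fatigue_dyspnea_increase")


@dataclass(frozen=True)
class TrajectoryFit:
    """OLS fit of one patient's indicator series on time."""

    slope: float
    intercept: float
    slope_p: float  # two-sided p for slope = 0; NaN when n_points == 2
    n_points: int
    residual_sd: float


@dataclass(frozen=True)
class TTAResult:
    """Threshold-crossing outcome for one patient x indicator."""

    patient_id: str
    indicator: str
    baseline_value: float
    threshold_value: float
    event: bool
    time_years: float
    censor_reason: str  # "event", "no_significant_decline", "beyond_follow_up"


@dataclass(frozen=True)
class CompositeEvent:
    """First-event composite outcome for one patient."""

    patient_id: str
    event: bool
    time_years: float
    component: str  # lung_tta / heart_tta / rtog_increase / fatigue_dyspnea_increase / censored


def fit_trajectory(times, values) -> TrajectoryFit:
    """Ordinary least squares of measurement value on time (years).

    Requires at least two distinct time points.  The slope p-value is the
    usual two-sided t-test; with exactly two points it is undefined (NaN) and
    treated downstream as not significant.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time points")
    res = stats.linregress(t, y)
    n = t.size
    fitted = res.intercept + res.slope * t
    rss = float(np.sum((y - fitted) ** 2))
    residual_sd = math.sqrt(rss / (n - 2)) if n > 2 else 0.0
    slope_p = float(res.pvalue) if n > 2 else math.nan
    return TrajectoryFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_p=slope_p,
        n_points=int(n),
        residual_sd=residual_sd,
    )


def time_to_alteration(
    fit: TrajectoryFit,
    baseline: float,
    d: float,
    follow_up: float,
    alpha_slope: float = 0.05,
    *,
    patient_id: str = "",
    indicator: str = "",
) -> TTAResult:
    """Time for the fitted trajectory to reach a d% deterioration of baseline.

    Censoring rules: no significant decline (slope >= 0, or slope p-value not
    below ``alpha_slope``) censors at follow-up; a crossing time beyond
    follow-up censors at follow-up.  A negative crossing time (the fitted
    line already below threshold at t=0, possible with noisy baselines) is an
    event at time 0, the earliest admissible event time.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"d must be in (0, 1), got {d}")
    if follow_up <= 0:
        raise ValueError(f"follow_up must be positive, got {follow_up}")
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    threshold = (1.0 - d) * baseline
    significant = fit.slope < 0 and (not math.isnan(fit.slope_p)) and fit.slope_p < alpha_slope
    # a perfectly noiseless decline (>=3 points) has residual_sd 0; linregress
    # may emit NaN rather than 0 for its p-value, so treat it as significant
    if fit.slope < 0 and fit.residual_sd == 0.0 and fit.n_points >= 3:
        significant = True
    if not significant:
        return TTAResult(patient_id, indicator, baseline, threshold, False, follow_up,
                         "no_significant_decline")
    t_star = (threshold - fit.intercept) / fit.slope
    if t_star > follow_up:
        return TTAResult(patient_id, indicator, baseline, threshold, False, follow_up,
                         "beyond_follow_up")
    return TTAResult(patient_id, indicator, baseline, threshold, True, max(t_star, 0.0), "event")


def ordinal_event_time(times, grades, baseline_grade, follow_up: float) -> tuple[bool, float]:
    """First time an ordinal grade exceeds its baseline grade.

    ``grades`` may be integers (RTOG 0-5) or ordered category ranks; an empty
    series censors at follow-up.  Only post-baseline visits (t > 0) can
    trigger an event.
    """
    if follow_up <= 0:
        raise ValueError(f"follow_up must be positive, got {follow_up}")
    for t, g in sorted(zip(times, grades)):
        if t > 0 and g > baseline_grade:
            return True, float(t)
    return False, float(follow_up)


def derive_ratio_series(
    num_times, num_values, den_times, den_values, *, label: str = "ratio"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-visit ratio of two indicator series matched by visit time.

    Visits missing either member are dropped; visits with a zero denominator
    are dropped with a logged warning.  Returns (times, ratios).
    """
    num = {float(t): float(v) for t, v in zip(num_times, num_values)}
    den = {float(t): float(v) for t, v in zip(den_times, den_values)}
    common = sorted(set(num) & set(den))
    times, ratios = [], []
    for t in common:
        if den[t] == 0.0:
            logger.warning("dropping visit t=%.3g for %s: zero denominator", t, label)
            continue
        times.append(t)
        ratios.append(num[t] / den[t])
    return np.asarray(times), np.asarray(ratios)


def composite_tta(
    patient_id: str,
    component_events: dict[str, tuple[bool, float]],
    follow_up: float,
) -> CompositeEvent:
    """Combine per-component outcomes into the first-event composite.

    ``component_events`` maps component labels (lung_tta, heart_tta,
    rtog_increase, fatigue_dyspnea_increase) to ``(event, time)``.  Ties are
    labelled by fixed component precedence; the time is unaffected.
    """
    best: tuple[float, str] | None = None
    for comp in _COMPONENT_PRECEDENCE:
        ev = component_events.get(comp)
        if ev is None or not ev[0]:
            continue
        if best is None or ev[1] < best[0]:
            best = (ev[1], comp)
    if best is None:
        return CompositeEvent(patient_id, False, float(follow_up), "censored")
    return CompositeEvent(patient_id, True, float(best[0]), best[1])


def _continuous_component_series(meas: pd.DataFrame, components) -> dict[str, tuple]:
    """Build (times, values) per derived continuous component for one patient."""
    by_ind = {
        ind: (grp["time_years"].to_numpy(), grp["value"].to_numpy())
        for ind, grp in meas.groupby("indicator", sort=False)
    }
    out = {}
    for comp in components:
        if comp in _RATIO_PARTS:
            a, b = _RATIO_PARTS[comp]
            if a in by_ind and b in by_ind:
                t, v = derive_ratio_series(*by_ind[a], *by_ind[b], label=comp)
                if t.size:
                    out[comp] = (t, v)
        elif comp in by_ind:
            out[comp] = by_ind[comp]
    return out


def _patient_tta(
    pid: str,
    meas: pd.DataFrame,
    follow_up: float,
    d: float,
    alpha_slope: float,
    lung_components=LUNG_COMPONENTS,
    heart_components=HEART_COMPONENTS,
    pro_rule: str = "category",
) -> tuple[list[TTAResult], CompositeEvent]:
    """All component TTA results and the composite event for one patient."""
    results: list[TTAResult] = []
    comp_events: dict[str, tuple[bool, float]] = {}

    def _censored(ind: str) -> TTAResult:
        return TTAResult(pid, ind, math.nan, math.nan, False, follow_up, "no_significant_decline")

    series = _continuous_component_series(
        meas, tuple(lung_components) + tuple(heart_components)
    )
    for family, comps in (("lung_tta", lung_components), ("heart_tta", heart_components)):
        family_best: tuple[bool, float] = (False, follow_up)
        for comp in comps:
            if comp not in series:
                results.append(_censored(comp))
                continue
            t, v = series[comp]
            order = np.argsort(t)
            t, v = t[order], v[order]
            if t.size < 2 or np.unique(t).size < 2:
                results.append(_censored(comp))
                continue
            baseline = float(v[t == 0.0][0]) if np.any(t == 0.0) else None
            fit = fit_trajectory(t, v)
            if baseline is None:
                baseline = fit.intercept  # fallback anchor when t=0 visit missing
            if baseline <= 0:
                results.append(_censored(comp))
                continue
            res = time_to_alteration(
                fit, baseline, d, follow_up, alpha_slope, patient_id=pid, indicator=comp
            )
            results.append(res)
            if res.event and (not family_best[0] or res.time_years < family_best[1]):
                family_best = (True, res.time_years)
        comp_events[family] = family_best

    # RTOG grade increase
    rtog_best: tuple[bool, float] = (False, follow_up)
    for ind in ("RTOG_LUNG", "RTOG_HEART"):
        grp = meas[meas["indicator"] == ind].sort_values("time_years")
        if grp.empty:
            continue
        t = grp["time_years"].to_numpy()
        g = grp["value"].to_numpy().astype(int)
        base = int(g[t == 0.0][0]) if np.any(t == 0.0) else int(g[0])
        ev, when = ordinal_event_time(t, g, base, follow_up)
        if ev and (not rtog_best[0] or when < rtog_best[1]):
            rtog_best = (True, when)
    comp_events["rtog_increase"] = rtog_best

    # fatigue/dyspnea increase (category rule by default, raw-score optional)
    pro_best: tuple[bool, float] = (False, follow_up)
    for ind in ("FATIGUE_RAW", "DYSPNEA_RAW"):
        grp = meas[meas["indicator"] == ind].sort_values("time_years")
        if grp.empty:
            continue
        t = grp["time_years"].to_numpy()
        raw = grp["value"].to_numpy(dtype=float)
        if pro_rule == "category":
            g = np.array([category_rank(qlq_category(qlq_scale(v))) for v in raw])
        elif pro_rule == "raw":
            g = raw
        else:
            raise ValueError(f"unknown pro_rule {pro_rule!r}")
        base = g[t == 0.0][0] if np.any(t == 0.0) else g[0]
        ev, when = ordinal_event_time(t, g, base, follow_up)
        if ev and (not pro_best[0] or when < pro_best[1]):
            pro_best = (True, when)
    comp_events["fatigue_dyspnea_increase"] = pro_best

    return results, composite_tta(pid, comp_events, follow_up)


def compute_composite_events(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    d: float = 0.10,
    alpha_slope: float = 0.05,
    *,
    lung_components=LUNG_COMPONENTS,
    heart_components=HEART_COMPONENTS,
    pro_rule: str = "category",
    return_components: bool = False,
):
    """Composite first-event table for a cohort (one row per patient, ITT).

    Every patient in ``patients`` appears exactly once; patients without
    usable measurements are censored at their follow-up time.  Returns a
    DataFrame with columns ``patient_id, arm, time_years, event, component``
    (and, with ``return_components=True``, also the per-indicator TTA table).
    """
    by_pid = dict(tuple(measurements.groupby("patient_id", sort=False)))
    comp_rows = []
    tta_rows = []
    for rec in patients.itertuples(index=False):
        pid = rec.patient_id
        follow_up = float(rec.follow_up_years)
        meas = by_pid.get(pid)
        if meas is None or meas.empty:
            ce = CompositeEvent(pid, False, follow_up, "censored")
            results = []
        else:
            results, ce = _patient_tta(
                pid, meas, follow_up, d, alpha_slope,
                lung_components=lung_components, heart_components=heart_components,
                pro_rule=pro_rule,
            )
        comp_rows.append((pid, rec.arm, ce.time_years, int(ce.event), ce.component))
        for r in results:
            tta_rows.append(
                (pid, r.indicator, r.baseline_value, r.threshold_value,
                 int(r.event), r.time_years, r.censor_reason)
            )
    composite = pd.DataFrame(
        comp_rows, columns=["patient_id", "arm", "time_years", "event", "component"]
    )
    if return_components:
        tta_table = pd.DataFrame(
            tta_rows,
            columns=["patient_id", "indicator", "baseline_value", "threshold_value",
                     "event", "time_years", "censor_reason"],
        )
        return composite, tta_table
    return composite


def sensitivity_sweep(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    d_list=(0.10, 0.20, 0.40, 0.60),
    alpha_slope: float = 0.05,
    tau: float | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Repeat the composite analysis across deterioration thresholds.

    For each ``d`` the composite events are recomputed and summarized:
    event counts and median event-free time per arm, log-rank statistic and
    p-value, restricted mean event-free time per arm with the between-arm
    difference and its p-value, and the arm hazard ratio with 95% CI.
    """
    from . import survival  # deferred: survival imports lifelines

    if len(set(d_list)) != len(tuple(d_list)):
        raise ValueError("sweep d values must be distinct")
    rows = []
    for d in d_list:
        comp = compute_composite_events(patients, measurements, d, alpha_slope, **kwargs)
        rows.append(survival.summarize_composite(comp, tau=tau) | {"d": d})
    out = pd.DataFrame(rows)
    return out[["d"] + [c for c in out.columns if c != "d"]]
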