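"""Time-to-event inference for derived endpoints.

Kaplan-Meier product-limit curves (Greenwood CIs), the two-group log-rank
test, restricted mean survival time (RMST) with an asymptotic between-arm
difference test, Cox proportional-hazards regression (Efron tie handling —
ties are common on a yearly visit grid), subgroup interaction scans shaped
for a forest plot, and overall/disease-free survival endpoint construction.

Estimation is delegated to lifelines; this module fixes the conventions
(tie handling, CI level, RMST horizon choice) and the result containers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "RMSTEstimate",
    "km_estimate",
    "logrank_test",
    "rmst",
    "rmst_diff",
    "default_tau",
    "median_survival",
    "cox_fit",
    "subgroup_interactions",
    "os_dfs_endpoints",
    "summarize_composite",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray       # distinct event times, increasing
    at_risk: np.ndarray     # subjects at risk just before each time
    events: np.ndarray      # events at each time
    survival: np.ndarray    # S(t) just after each time
    ci_lower: np.ndarray
    ci_upper: np.ndarray


@dataclass(frozen=True)
class RMSTEstimate:
    """Restricted mean survival time comparison at horizon tau."""

    tau: float
    rmst0: float
    se0: float
    rmst1: float
    se1: float
    diff: float     # group1 - group0
    se_diff: float
    p_value: float


def _check_table(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty event table")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t, e


def _fit_km(times, events) -> KaplanMeierFitter:
    t, e = _check_table(times, events)
    return KaplanMeierFitter().fit(t, e)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with Greenwood 95% CIs.

    Ties are handled in the standard way (events precede censorings at equal
    times).  Only distinct event times appear in the curve; with no events
    the curve is empty and S is identically 1.
    """
    kmf = _fit_km(times, events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    ts = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ts).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(ts, ci.index.to_numpy(dtype=float), ci.iloc[:, 0].to_numpy())
    hi = np.interp(ts, ci.index.to_numpy(dtype=float), ci.iloc[:, 1].to_numpy())
    return SurvivalCurve(
        times=ts,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
        survival=surv,
        ci_lower=lo,
        ci_upper=hi,
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Uses the hypergeometric variance and a 1-df chi-square reference.
    """
    t, e = _check_table(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.size}")
    if e.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    m0, m1 = g == labels[0], g == labels[1]
    res = _ll_logrank(t[m0], t[m1], e[m0], e[m1])
    return float(res.test_statistic), float(res.p_value)


def _rmst_from_km(kmf: KaplanMeierFitter, tau: float) -> tuple[float, float]:
    """Exact step-function RMST on [0, tau] and its asymptotic variance.

    The KM curve is piecewise constant, so the area is a finite rectangle
    sum.  The variance is the standard Greenwood-type expression
    ``sum_j A_j^2 d_j / (n_j (n_j - d_j))`` over event times t_j <= tau,
    where ``A_j`` is the area under S from t_j to tau.
    """
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    ts = ev.index.to_numpy(dtype=float)
    keep = ts <= tau
    ts = ts[keep]
    d = ev["observed"].to_numpy(dtype=float)[keep]
    n = ev["at_risk"].to_numpy(dtype=float)[keep]
    surv = kmf.survival_function_at_times(ts).to_numpy()  # S just after t_j
    grid = np.concatenate([[0.0], ts, [tau]])
    step_s = np.concatenate([[1.0], surv])  # S on [grid_i, grid_{i+1})
    widths = np.diff(grid)
    area = float(np.sum(step_s * widths))
    # tail areas A_j = integral of S from t_j to tau
    seg = step_s * widths
    tail = np.cumsum(seg[::-1])[::-1]  # tail[i] = area from grid[i] to tau
    A = tail[1:]  # from each event time t_j
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n - d) > 0, A**2 * d / (n * (n - d)), 0.0)
    return area, float(np.sum(terms))


def rmst(times, events, tau: float) -> float:
    """Restricted mean survival time: area under the KM curve on [0, tau]."""
    t, e = _check_table(times, events)
    if tau > t.max():
        raise ValueError(f"tau={tau} exceeds the maximal observed time {t.max():g}")
    return _rmst_from_km(_fit_km(t, e), tau)[0]


def default_tau(times, groups) -> float:
    """Default RMST horizon: the minimum across groups of the maximal observed time."""
    t = np.asarray(times, dtype=float)
    g = np.asarray(groups)
    return float(min(t[g == lbl].max() for lbl in np.unique(g)))


def rmst_diff(times, events, groups, tau: float | None = None) -> RMSTEstimate:
    """Between-group RMST difference with asymptotic normal inference.

    ``diff = RMST(group1) - RMST(group0)`` with groups ordered by label;
    per-group variances are Greenwood-based, the p-value is a two-sided
    z-test.  ``tau`` defaults to the common observable horizon.
    """
    t, e = _check_table(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.size}")
    if tau is None:
        tau = default_tau(t, g)
    if tau > min(t[g == lbl].max() for lbl in labels):
        raise ValueError(f"tau={tau} beyond the observable range of a group")
    out = []
    for lbl in labels:
        m = g == lbl
        r, var = _rmst_from_km(_fit_km(t[m], e[m]), tau)
        out.append((float(r), math.sqrt(max(var, 0.0))))
    (r0, s0), (r1, s1) = out
    diff = r1 - r0
    se = math.hypot(s0, s1)
    z = diff / se if se > 0 else math.inf * np.sign(diff) if diff else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return RMSTEstimate(float(tau), r0, s0, r1, s1, diff, se, p)


def median_survival(times, events) -> float:
    """Median of the KM curve (NaN when S never reaches 0.5)."""
    kmf = _fit_km(times, events)
    return float(kmf.median_survival_time_)


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str] | None = None, *, formula: str | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties); one row per coefficient.

    Returns a DataFrame indexed by covariate with columns ``coef, hr,
    ci_lower, ci_upper, p`` (hazard ratio and Wald 95% CI).  Categorical
    covariates may be passed through ``formula``; non-convergence raises with
    lifelines' diagnostic.
    """
    if int(df[event_col].sum()) == 0:
        raise ValueError("Cox fit requires at least one event")
    cph = CoxPHFitter()
    opts = {"fit_options": {"precision": 1e-9}}  # tight Newton tolerance
    if formula is not None:
        cph.fit(df, duration_col=duration_col, event_col=event_col, formula=formula, **opts)
    else:
        cols = [duration_col, event_col] + list(covariates or [])
        cph.fit(df[cols], duration_col=duration_col, event_col=event_col, **opts)
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    out.attrs["log_likelihood"] = float(cph.log_likelihood_)
    out.attrs["variance_matrix"] = cph.variance_matrix_
    return out


def _joint_wald(fit: pd.DataFrame, terms: list[str]) -> float:
    """Joint Wald chi-square p-value for a block of coefficients being zero."""
    beta = fit.loc[terms, "coef"].to_numpy()
    V = fit.attrs["variance_matrix"].loc[terms, terms].to_numpy()
    chi2 = float(beta @ np.linalg.solve(V, beta))
    return float(stats.chi2.sf(chi2, df=len(terms)))


def subgroup_interactions(
    df: pd.DataFrame,
    covariates: list[str],
    *,
    duration_col: str = "time_years",
    event_col: str = "event",
    arm_col: str = "arm",
    age_cut: float = 50.0,
) -> pd.DataFrame:
    """Arm hazard ratio within each subgroup level, with interaction tests.

    For each covariate the arm HR (with 95% CI) is estimated separately in
    every level, and the arm x covariate interaction is tested by a joint
    Wald test in a model with main effects and interactions.  Continuous
    covariates named ``age`` or ``weight`` are dichotomized (age at
    ``age_cut`` years, weight at its cohort median).  Levels without events
    (or single-level covariates) are skipped with a warning.  The output is
    shaped for a forest plot: one row per covariate level plus the
    interaction p-value repeated per covariate.
    """
    work = df.copy()
    arms = np.sort(work[arm_col].unique())
    if arms.size != 2:
        raise ValueError("subgroup analysis requires exactly 2 arms")
    work["_arm"] = (work[arm_col] == arms[1]).astype(float)

    rows = []
    for cov in covariates:
        col = work[cov]
        if cov == "age":
            col = np.where(col >= age_cut, f">={age_cut:g}", f"<{age_cut:g}")
        elif cov == "weight" or (col.dtype.kind == "f" and col.nunique() > 6):
            med = float(pd.Series(col).median())
            col = np.where(col >= med, f">={med:g}", f"<{med:g}")
        lev = pd.Series(col, index=work.index).astype(str)
        levels = sorted(lev.unique())
        if len(levels) < 2:
            logger.warning("covariate %s has a single level; interaction skipped", cov)
            continue

        # interaction model: arm + covariate dummies + arm:covariate dummies
        dummies = pd.get_dummies(lev, prefix=cov, drop_first=True).astype(float)
        model = pd.concat(
            [work[[duration_col, event_col, "_arm"]], dummies], axis=1
        )
        inter_terms = []
        for c in dummies.columns:
            name = f"{c}:arm"
            model[name] = model["_arm"] * model[c]
            inter_terms.append(name)
        try:
            fit = cox_fit(model, duration_col, event_col,
                          ["_arm"] + list(dummies.columns) + inter_terms)
            p_inter = _joint_wald(fit, inter_terms)
        except Exception as exc:  # noqa: BLE001 - surfaced per covariate
            logger.warning("interaction model failed for %s: %s", cov, exc)
            p_inter = math.nan

        for level in levels:
            sub = work[lev == level]
            if sub[event_col].sum() == 0 or sub["_arm"].nunique() < 2:
                logger.warning("level %s=%s skipped (no events or single arm)", cov, level)
                continue
            try:
                f = cox_fit(sub, duration_col, event_col, ["_arm"])
                hr, lo, hi, p = f.loc["_arm", ["hr", "ci_lower", "ci_upper", "p"]]
            except Exception as exc:  # noqa: BLE001
                logger.warning("subgroup fit failed for %s=%s: %s", cov, level, exc)
                continue
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "n": int(len(sub)),
                    "events": int(sub[event_col].sum()),
                    "hr": float(hr),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                    "p": float(p),
                    "interaction_p": p_inter,
                }
            )
    return pd.DataFrame(rows)


def os_dfs_endpoints(patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overall-survival and disease-free-survival event tables.

    OS: event = death from any cause, time = death time or follow-up.
    DFS: event = death or first recurrence-type event, time = the earliest.
    Returns two DataFrames with columns ``patient_id, arm, time_years, event``.
    """
    death = patients["death_time"]
    recur = patients["recurrence_time"]
    fu = patients["follow_up_years"]
    os_time = death.fillna(fu)
    os_event = death.notna().astype(int)
    dfs_time = pd.concat([death, recur], axis=1).min(axis=1).fillna(fu)
    dfs_event = (death.notna() | recur.notna()).astype(int)
    cols = {"patient_id": patients["patient_id"], "arm": patients["arm"]}
    os_df = pd.DataFrame(cols | {"time_years": os_time, "event": os_event})
    dfs_df = pd.DataFrame(cols | {"time_years": dfs_time, "event": dfs_event})
    return os_df, dfs_df


def summarize_composite(composite: pd.DataFrame, tau: float | None = None) -> dict:
    """One-line summary of a two-arm composite event table.

    Event counts and median event-free time per arm, log-rank test, RMST per
    arm with between-arm difference at horizon ``tau`` (default: common
    observable horizon), and the arm hazard ratio with 95% CI.  Group 1 is
    the lexicographically larger arm label (the experimental arm for
    CRT / H-IGRT).
    """
    t = composite["time_years"].to_numpy()
    e = composite["event"].to_numpy()
    g = composite["arm"].to_numpy()
    arms = np.sort(np.unique(g))
    out: dict = {}
    for i, arm in enumerate(arms):
        m = g == arm
        out[f"n_{i}"] = int(m.sum())
        out[f"events_{i}"] = int(e[m].sum())
        out[f"median_{i}"] = median_survival(t[m], e[m])
        out[f"arm_{i}"] = str(arm)
    if e.sum() > 0:
        chi2, p = logrank_test(t, e, g)
        out["logrank_chi2"], out["logrank_p"] = chi2, p
        est = rmst_diff(t, e, g, tau)
        out["tau"] = est.tau
        out["rmst_0"], out["rmst_1"] = est.rmst0, est.rmst1
        out["rmst_diff"], out["rmst_p"] = est.diff, est.p_value
        df = composite.assign(_arm=(composite["arm"] == arms[1]).astype(float))
        fit = cox_fit(df[["time_years", "event", "_arm"]], "time_years", "event", ["_arm"])
        out["hr"] = float(fit.loc["_arm", "hr"])
        out["hr_ci_lower"] = float(fit.loc["_arm", "ci_lower"])
        out["hr_ci_upper"] = float(fit.loc["_arm", "ci_upper"])
        out["hr_p"] = float(fit.loc["_arm", "p"])
    else:
        tau_eff = tau if tau is not None else default_tau(t, g)
        out.update(
            {"logrank_chi2": math.nan, "logrank_p": math.nan, "tau": tau_eff,
             "rmst_0": tau_eff, "rmst_1": tau_eff, "rmst_diff": 0.0, "rmst_p": math.nan,
             "hr": math.nan, "hr_ci_lower": math.nan, "hr_ci_upper": math.nan,
             "hr_p": math.nan}
        )
    return out
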