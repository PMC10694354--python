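"""Survival inference vs independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from ttakit.survival import (
    cox_fit,
    default_tau,
    km_estimate,
    logrank_test,
    os_dfs_endpoints,
    rmst,
    rmst_diff,
    subgroup_interactions,
)

# ---------------------------------------------------------------- oracles


def km_oracle(times, events):
    """Hand product-limit: S at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


def logrank_oracle(times, events, groups):
    """Direct O-E / hypergeometric-variance accumulation, two groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def rmst_oracle(times, events, tau):
    """Rectangle integration of the hand product-limit curve."""
    curve = km_oracle(times, events)
    grid = [0.0] + [t for t in sorted(curve) if t <= tau] + [tau]
    s_vals = [1.0] + [curve[t] for t in sorted(curve) if t <= tau]
    return sum(s * (b - a) for s, a, b in zip(s_vals, grid[:-1], grid[1:]))


def cox_oracle_binary(times, events, x):
    """1-D Efron partial-likelihood maximization by bounded scalar search."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)

    def neg_pl(beta):
        ll = 0.0
        for t in sorted(set(times[events == 1])):
            at_risk = times >= t
            dead = (times == t) & (events == 1)
            d = dead.sum()
            risk = np.exp(beta * x[at_risk]).sum()
            tie = np.exp(beta * x[dead]).sum()
            ll += beta * x[dead].sum()
            for j in range(d):
                ll -= math.log(risk - j / d * tie)
        return -ll

    res = minimize_scalar(neg_pl, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


# ---------------------------------------------------------------- KM


class TestKaplanMeier:
    def test_hand_product_limit_small_table(self):
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.times.tolist() == [1.0, 3.0]
        assert curve.survival[0] == pytest.approx(2 / 3)
        assert curve.survival[1] == pytest.approx(0.0)

    def test_all_censored_gives_empty_curve(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0

    def test_agrees_with_oracle_on_simulated_table(self, rng):
        t = rng.exponential(5, 200).round(2)
        c = rng.exponential(6, 200).round(2)
        obs, e = np.minimum(t, c), (t <= c).astype(int)
        curve = km_estimate(obs, e)
        oracle = km_oracle(obs, e)
        assert curve.times.size == len(oracle)
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(oracle[time], abs=1e-10)

    def test_curve_invariants(self, rng):
        t = rng.exponential(5, 100)
        e = rng.integers(0, 2, 100)
        curve = km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert (np.diff(curve.at_risk) <= 0).all()
        assert ((curve.ci_lower <= curve.survival + 1e-12)
                & (curve.survival <= curve.ci_upper + 1e-12)).all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


# ---------------------------------------------------------------- log-rank


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = [0] * 4 + [1] * 4
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_agrees_with_direct_accumulation(self, rng):
        t = rng.exponential(3, 60).round(1) + 0.1
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60)
        if e.sum() == 0:
            e[0] = 1
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(logrank_oracle(t, e, g), abs=1e-12)

    def test_invariant_under_monotone_time_transform(self, rng):
        t = rng.exponential(3, 80) + 0.05
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80)
        e[0] = 1
        chi2_a, _ = logrank_test(t, e, g)
        chi2_b, _ = logrank_test(np.log1p(t), e, g)
        assert chi2_a == pytest.approx(chi2_b, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [0, 1])

    def test_score_test_equivalence(self, rng):
        # classical identity: log-rank chi-square equals the Cox score test
        # at beta=0 on an untied two-group table
        t = np.sort(rng.uniform(0.1, 10.0, 30))  # distinct times, no ties
        e = np.ones(30, int)
        e[rng.choice(30, 8, replace=False)] = 0
        g = rng.integers(0, 2, 30)
        u, info = 0.0, 0.0
        for tt in t[e == 1]:
            at_risk = t >= tt
            n = at_risk.sum()
            n1 = (at_risk & (g == 1)).sum()
            d1 = float(g[(t == tt) & (e == 1)][0])
            u += d1 - n1 / n
            info += (n1 / n) * (1 - n1 / n)
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(u**2 / info, abs=1e-8)


# ---------------------------------------------------------------- RMST


class TestRmst:
    def test_no_events_equals_tau(self):
        assert rmst([12, 11, 13], [0, 0, 0], 10.0) == pytest.approx(10.0)

    def test_hand_rectangle_sum(self):
        # S=1 on [0,2), 0.5 on [2,4): events at 2 (1 of 2 at risk), censor at 4
        assert rmst([2, 4], [1, 0], 4.0) == pytest.approx(3.0)

    def test_agrees_with_oracle(self, rng):
        t = rng.exponential(4, 50).round(2) + 0.01
        e = rng.integers(0, 2, 50)
        tau = float(np.percentile(t, 80))
        assert rmst(t, e, tau) == pytest.approx(rmst_oracle(t, e, tau), abs=1e-10)

    def test_tau_beyond_range_rejected(self):
        with pytest.raises(ValueError):
            rmst([1, 2, 3], [1, 0, 1], 5.0)

    def test_identical_groups_zero_difference(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 0, 1, 0, 1, 0]
        g = [0] * 4 + [1] * 4
        est = rmst_diff(t, e, g, tau=4.0)
        assert est.diff == pytest.approx(0.0, abs=1e-12)

    def test_default_tau_is_common_horizon(self):
        t = [1, 5, 9, 2, 6, 7]
        g = [0, 0, 0, 1, 1, 1]
        assert default_tau(t, g) == 7.0


# ---------------------------------------------------------------- Cox


class TestCox:
    def test_binary_covariate_matches_partial_likelihood_search(self):
        df = pd.DataFrame(
            {"t": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
             "e": [1, 1, 1, 0, 1, 1],
             "x": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0]}
        )
        fit = cox_fit(df, "t", "e", ["x"])
        beta_hat = cox_oracle_binary(df["t"], df["e"], df["x"])
        assert fit.loc["x", "coef"] == pytest.approx(beta_hat, abs=1e-6)
        assert fit.loc["x", "hr"] == pytest.approx(math.exp(beta_hat), rel=1e-5)

    def test_tied_table_matches_efron_oracle(self):
        df = pd.DataFrame(
            {"t": [1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0],
             "e": [1, 1, 1, 0, 1, 1, 1, 0],
             "x": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0]}
        )
        fit = cox_fit(df, "t", "e", ["x"])
        beta_hat = cox_oracle_binary(df["t"], df["e"], df["x"])
        assert fit.loc["x", "coef"] == pytest.approx(beta_hat, abs=1e-5)

    def test_null_covariate_recovery(self, rng):
        # covariate independent of event times: HR near 1, CI covers 1 most of the time
        hrs, covered = [], 0
        reps = 60
        for _ in range(reps):
            n = 400
            t = rng.exponential(5, n)
            c = rng.exponential(8, n)
            df = pd.DataFrame(
                {"t": np.minimum(t, c), "e": (t <= c).astype(int),
                 "x": rng.integers(0, 2, n).astype(float)}
            )
            fit = cox_fit(df, "t", "e", ["x"])
            hrs.append(fit.loc["x", "hr"])
            covered += fit.loc["x", "ci_lower"] <= 1.0 <= fit.loc["x", "ci_upper"]
        assert 0.85 <= float(np.median(hrs)) <= 1.18
        assert covered / reps >= 0.90

    def test_no_events_rejected(self):
        df = pd.DataFrame({"t": [1.0, 2.0], "e": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(df, "t", "e", ["x"])


# ---------------------------------------------------------------- subgroups


class TestSubgroups:
    @staticmethod
    def _toy_table(rng, n=240, interaction=0.0):
        arm = rng.integers(0, 2, n)
        grp = rng.integers(0, 2, n)
        log_hr = -0.5 * arm + interaction * arm * grp
        t = rng.exponential(1.0 / (0.2 * np.exp(log_hr)))
        c = rng.uniform(2, 15, n)
        return pd.DataFrame(
            {"time_years": np.minimum(t, c), "event": (t <= c).astype(int),
             "arm": np.where(arm == 1, "B", "A"), "grp": np.where(grp == 1, "y", "x")}
        )

    def test_output_shape_and_levels(self, rng):
        df = self._toy_table(rng)
        out = subgroup_interactions(df, ["grp"])
        assert set(out["level"]) == {"x", "y"}
        assert out["interaction_p"].nunique() == 1
        assert ((out["ci_lower"] <= out["hr"]) & (out["hr"] <= out["ci_upper"])).all()

    def test_single_level_covariate_skipped(self, rng):
        df = self._toy_table(rng)
        df["constant"] = "same"
        out = subgroup_interactions(df, ["constant"])
        assert out.empty

    def test_planted_interaction_detected(self, rng):
        df = self._toy_table(rng, n=2000, interaction=1.2)
        out = subgroup_interactions(df, ["grp"])
        assert out["interaction_p"].iloc[0] < 0.05

    def test_age_dichotomized_at_cut(self, rng):
        df = self._toy_table(rng)
        df["age"] = rng.uniform(35, 80, len(df))
        out = subgroup_interactions(df, ["age"], age_cut=50.0)
        assert set(out["level"]) == {"<50", ">=50"}


# ---------------------------------------------------------------- OS / DFS


class TestEndpoints:
    @staticmethod
    def _patients(rows):
        return pd.DataFrame(
            rows,
            columns=["patient_id", "arm", "follow_up_years", "death_time",
                     "recurrence_time"],
        )

    def test_alive_no_recurrence(self):
        os_df, dfs_df = os_dfs_endpoints(
            self._patients([("P1", "CRT", 12.0, np.nan, np.nan)])
        )
        assert (os_df.loc[0, "time_years"], os_df.loc[0, "event"]) == (12.0, 0)
        assert (dfs_df.loc[0, "time_years"], dfs_df.loc[0, "event"]) == (12.0, 0)

    def test_death_after_recurrence(self):
        os_df, dfs_df = os_dfs_endpoints(
            self._patients([("P1", "CRT", 5.0, 5.0, 3.0)])
        )
        assert (os_df.loc[0, "time_years"], os_df.loc[0, "event"]) == (5.0, 1)
        assert (dfs_df.loc[0, "time_years"], dfs_df.loc[0, "event"]) == (3.0, 1)

    def test_death_without_recurrence_is_dfs_event(self):
        _, dfs_df = os_dfs_endpoints(self._patients([("P1", "CRT", 5.0, 5.0, np.nan)]))
        assert (dfs_df.loc[0, "time_years"], dfs_df.loc[0, "event"]) == (5.0, 1)
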