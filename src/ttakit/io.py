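"""CSV schemas, configuration, run log, and the end-to-end pipeline.

Input schemas (UTF-8 CSV, header row required):

``patients.csv``
    patient_id, arm, nodal_status, surgery, chemo, age, weight, laterality,
    nodal_irradiation, trastuzumab, histological_grade, follow_up_years,
    death_time, recurrence_time   (death/recurrence may be empty)

``measurements.csv``
    patient_id, indicator, time_years, value
    (long format: one row per patient x indicator x visit)

Rows violating the type invariants (negative times, unknown indicator codes,
out-of-range grades or scores) are rejected with their line numbers logged;
a missing required column is an error.  The analysis itself is strictly
intention-to-treat: every patient record enters every event table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import grading, survival, tta
from .simulate import ALL_INDICATORS, ORDINAL_INDICATORS, QLQ_INDICATORS

logger = logging.getLogger("ttakit")

__all__ = [
    "AnalysisConfig",
    "RunLog",
    "read_patients",
    "read_measurements",
    "write_cohort",
    "run_pipeline",
]

PATIENT_COLUMNS = [
    "patient_id", "arm", "nodal_status", "surgery", "chemo", "age", "weight",
    "laterality", "nodal_irradiation", "trastuzumab", "histological_grade",
    "follow_up_years", "death_time", "recurrence_time",
]
MEASUREMENT_COLUMNS = ["patient_id", "indicator", "time_years", "value"]


@dataclass
class AnalysisConfig:
    """Pipeline-wide analysis options.

    ``d`` is the deterioration threshold fraction (default 10%);
    ``d_sweep`` the sensitivity-sweep thresholds; ``alpha_slope`` the
    two-sided significance level for a per-patient slope to count as a
    decline; ``rmst_tau`` the RMST horizon in years (None = the common
    observable horizon); ``age_cut`` the dichotomization age for subgroup
    analysis.
    """

    d: float = 0.10
    d_sweep: tuple = (0.10, 0.20, 0.40, 0.60)
    alpha_slope: float = 0.05
    rmst_tau: float | None = None
    lvef_relative: bool = False
    pro_rule: str = "category"
    grade_split_years: float = 5.0
    age_cut: float = 50.0
    subgroup_covariates: tuple = (
        "age", "weight", "laterality", "surgery", "nodal_irradiation",
        "chemo", "trastuzumab", "histological_grade",
    )

    def __post_init__(self) -> None:
        for name, v in (("d", self.d), ("alpha_slope", self.alpha_slope)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        sweep = tuple(self.d_sweep)
        if len(set(sweep)) != len(sweep):
            raise ValueError("d_sweep values must be distinct")
        if any(not 0.0 < d < 1.0 for d in sweep):
            raise ValueError("d_sweep values must be in (0, 1)")
        self.d_sweep = sweep


class RunLog:
    """Collects stage messages and dropped-record warnings for the report."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def add(self, msg: str) -> None:
        self.lines.append(msg)
        logger.info(msg)

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_patients(path, log: RunLog | None = None) -> pd.DataFrame:
    """Read and validate the patient table; invalid rows are dropped and logged."""
    log = log or RunLog()
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "arm", "follow_up_years"], path)
    for col in PATIENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad = ~(pd.to_numeric(df["follow_up_years"], errors="coerce") > 0)
    bad |= df["patient_id"].isna()
    for idx in df.index[bad]:
        log.add(f"{path}: rejected patient row {idx + 2}: non-positive follow-up or missing id")
    df = df[~bad].copy()
    df["follow_up_years"] = df["follow_up_years"].astype(float)
    for col in ("death_time", "recurrence_time", "age", "weight"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    dup = df["patient_id"].duplicated()
    for idx in df.index[dup]:
        log.add(f"{path}: rejected duplicate patient_id at row {idx + 2}")
    return df[~dup][PATIENT_COLUMNS].reset_index(drop=True)


def read_measurements(path, log: RunLog | None = None) -> pd.DataFrame:
    """Read and validate the long-format measurement table.

    Rejected (and logged): unknown indicator codes, negative or missing
    times, non-positive continuous values, RTOG grades outside 0-5 or
    non-integer, raw QLQ scores outside [1, 4].
    """
    log = log or RunLog()
    df = pd.read_csv(path)
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    df["time_years"] = pd.to_numeric(df["time_years"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    known = df["indicator"].isin(ALL_INDICATORS)
    valid_time = df["time_years"] >= 0
    valid_value = df["value"].notna()
    is_ordinal = df["indicator"].isin(ORDINAL_INDICATORS)
    is_qlq = df["indicator"].isin(QLQ_INDICATORS)
    is_cont = known & ~is_ordinal & ~is_qlq
    valid_value &= (
        (is_cont & (df["value"] > 0))
        | (is_ordinal & (df["value"] >= 0) & (df["value"] <= 5) & (df["value"] % 1 == 0))
        | (is_qlq & (df["value"] >= 1) & (df["value"] <= 4))
    )
    ok = known & valid_time & valid_value
    for idx in df.index[~ok]:
        row = df.loc[idx]
        reason = (
            "unknown indicator" if not known[idx]
            else "invalid time" if not valid_time[idx]
            else "invalid value"
        )
        log.add(
            f"{path}: rejected measurement row {idx + 2} "
            f"({row['indicator']!r} t={row['time_years']}): {reason}"
        )
    df = df[ok].copy()
    # per patient x indicator, drop duplicate times (keep first), sort
    df = df.sort_values(["patient_id", "indicator", "time_years"], kind="stable")
    dup = df.duplicated(["patient_id", "indicator", "time_years"])
    for idx in df.index[dup]:
        log.add(f"{path}: rejected duplicate visit time at row {idx + 2}")
    return df[~dup][MEASUREMENT_COLUMNS].reset_index(drop=True)


def write_cohort(patients: pd.DataFrame, measurements: pd.DataFrame, outdir) -> tuple[Path, Path]:
    """Write the two cohort CSVs; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p_path = outdir / "patients.csv"
    m_path = outdir / "measurements.csv"
    patients.to_csv(p_path, index=False, float_format="%.10g")
    measurements.to_csv(m_path, index=False, float_format="%.10g")
    return p_path, m_path


def run_pipeline(
    config: AnalysisConfig,
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    outdir=None,
) -> dict:
    """Run grading, composite TTA, survival inference and the threshold sweep.

    Returns the report bundle as a dict of DataFrames/objects; when
    ``outdir`` is given every table is also written as TSV together with the
    run log.  The pipeline is a pure function of (config, inputs): identical
    inputs give identical tables.  Analysis is by randomized arm with no
    exclusions (ITT): every patient row appears in every event table.
    """
    log = RunLog()
    log.add(f"config: {asdict(config)}")
    log.add(f"patients: {len(patients)}; measurements: {len(measurements)}")

    # 1. descriptive grade table
    grades = grading.grade_cohort(patients, measurements, lvef_relative=config.lvef_relative)
    grade_table = grading.tabulate_grades(grades, split=config.grade_split_years)
    log.add(f"graded {len(grades)} post-baseline measurements")

    # 2. composite TTA at the primary threshold
    composite, tta_table = tta.compute_composite_events(
        patients, measurements, config.d, config.alpha_slope,
        pro_rule=config.pro_rule, return_components=True,
    )
    log.add(
        f"composite TTA at d={config.d:g}: "
        f"{int(composite['event'].sum())}/{len(composite)} events"
    )

    # 3. survival inference on the composite + OS/DFS
    summary = survival.summarize_composite(composite, tau=config.rmst_tau)
    km_rows = []
    for arm, grp in composite.groupby("arm"):
        curve = survival.km_estimate(grp["time_years"], grp["event"])
        for i in range(curve.times.size):
            km_rows.append(
                (arm, curve.times[i], curve.at_risk[i], curve.events[i],
                 curve.survival[i], curve.ci_lower[i], curve.ci_upper[i])
            )
    km_table = pd.DataFrame(
        km_rows,
        columns=["arm", "time_years", "at_risk", "events", "survival", "ci_lower", "ci_upper"],
    )
    subgroups = survival.subgroup_interactions(
        composite.merge(patients.drop(columns=["arm"]), on="patient_id"),
        list(config.subgroup_covariates),
        age_cut=config.age_cut,
    )
    os_df, dfs_df = survival.os_dfs_endpoints(patients)
    endpoint_rows = [dict(summary, endpoint="composite_tta")]
    for name, tab in (("os", os_df), ("dfs", dfs_df)):
        endpoint_rows.append(dict(survival.summarize_composite(tab), endpoint=name))
    endpoint_table = pd.DataFrame(endpoint_rows)
    endpoint_table = endpoint_table[
        ["endpoint"] + [c for c in endpoint_table.columns if c != "endpoint"]
    ]
    log.add(f"log-rank p={summary.get('logrank_p', float('nan')):.4g} on composite TTA")

    # 4. threshold sensitivity sweep
    sweep = tta.sensitivity_sweep(
        patients, measurements, config.d_sweep, config.alpha_slope,
        tau=config.rmst_tau, pro_rule=config.pro_rule,
    )
    log.add(f"sensitivity sweep over d in {tuple(config.d_sweep)}")

    bundle = {
        "grade_table": grade_table,
        "tta_results": tta_table,
        "composite_events": composite,
        "km_curves": km_table,
        "endpoint_summary": endpoint_table,
        "subgroups": subgroups,
        "sweep": sweep,
        "summary": summary,
        "log": log,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("grade_table", "tta_results", "composite_events", "km_curves",
                     "endpoint_summary", "subgroups", "sweep"):
            bundle[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                                float_format="%.10g")
        (outdir / "run_log.txt").write_text(log.text())
    return bundle
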