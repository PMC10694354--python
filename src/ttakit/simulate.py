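"""Synthetic two-arm trial cohorts with longitudinal lung-heart measurements.

The generator emulates the measurement design of a randomized adjuvant
breast-radiotherapy trial: two arms of roughly equal size, visits at baseline,
~2 months after therapy and then yearly; continuous pulmonary-function and
echocardiography indicators following patient-specific linear trajectories
with measurement noise; monotone ordinal clinician toxicity grades (RTOG
lung/heart, 0-5); raw 1-4 patient-reported fatigue/dyspnea scores with a slow
upward drift; and independent exponential dropout, death and recurrence
processes that censor follow-up.

Baseline means and SDs default to the trial's published baseline table
(e.g. control-arm FEV1 2.44 L, SD 0.56).  Decline rates, noise levels and
transition probabilities are free parameters of the generator — the source
study does not report per-arm trajectory slopes — chosen so that the control
arm deteriorates faster, producing a planted arm effect on the composite
endpoint that downstream parameter-recovery tests can detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .design import CoinState, efron_assign

__all__ = [
    "ARMS",
    "CONTINUOUS_INDICATORS",
    "ORDINAL_INDICATORS",
    "QLQ_INDICATORS",
    "SimConfig",
    "visit_schedule",
    "simulate_cohort",
]

ARMS = ("CRT", "H-IGRT")

CONTINUOUS_INDICATORS = ("FEV1", "FVC", "DLCO", "VA", "RV", "TLC", "LVEF")
ORDINAL_INDICATORS = ("RTOG_LUNG", "RTOG_HEART")
QLQ_INDICATORS = ("FATIGUE_RAW", "DYSPNEA_RAW")
ALL_INDICATORS = CONTINUOUS_INDICATORS + ORDINAL_INDICATORS + QLQ_INDICATORS

# Baseline (mean, sd) per indicator per arm; published baseline table values.
_BASELINES = {
    "FEV1": {"CRT": (2.44, 0.56), "H-IGRT": (2.65, 0.59)},   # liters
    "FVC": {"CRT": (3.26, 0.67), "H-IGRT": (3.47, 0.67)},    # liters
    "DLCO": {"CRT": (18.74, 3.98), "H-IGRT": (18.97, 3.42)}, # mL/mmHg/min
    "VA": {"CRT": (4.46, 0.68), "H-IGRT": (4.62, 0.68)},     # liters
    "RV": {"CRT": (1.90, 0.51), "H-IGRT": (1.85, 0.51)},     # liters
    "TLC": {"CRT": (5.20, 0.70), "H-IGRT": (5.36, 0.78)},    # liters
    "LVEF": {"CRT": (62.62, 4.54), "H-IGRT": (64.82, 5.92)}, # percent
    "FATIGUE_RAW": {"CRT": (1.90, 0.62), "H-IGRT": (2.06, 0.75)},
    "DYSPNEA_RAW": {"CRT": (1.33, 0.67), "H-IGRT": (1.46, 0.79)},
}

# Linear decline rates, units/year.  Negative = deterioration for all
# indicators except RV, where air trapping makes an increase the deterioration.
# Control declines faster; experimental rates ~60% of control.
_SLOPES = {
    "FEV1": {"CRT": -0.055, "H-IGRT": -0.033},
    "FVC": {"CRT": -0.030, "H-IGRT": -0.018},
    "DLCO": {"CRT": -0.45, "H-IGRT": -0.27},
    "VA": {"CRT": -0.020, "H-IGRT": -0.012},
    "RV": {"CRT": 0.020, "H-IGRT": 0.012},
    "TLC": {"CRT": -0.100, "H-IGRT": -0.060},
    "LVEF": {"CRT": -0.80, "H-IGRT": -0.50},  # percentage points/year
}

# Measurement-error SDs, roughly test-retest magnitude (~5% of baseline).
_NOISE_SD = {
    "FEV1": 0.12,
    "FVC": 0.15,
    "DLCO": 0.90,
    "VA": 0.15,
    "RV": 0.12,
    "TLC": 0.18,
    "LVEF": 2.5,
    "FATIGUE_RAW": 0.20,
    "DYSPNEA_RAW": 0.20,
}

# Stratum / covariate frequencies mirroring the published patient table.
_P_NODE_POSITIVE = 0.30
_P_MASTECTOMY = 0.37
_P_CHEMO = {"none": 0.55, "before RT": 0.11, "concomitant": 0.34}
_P_LEFT = 0.55
_P_NODAL_IRRADIATION = 0.29
_P_TRASTUZUMAB = 0.10
_P_GRADE = {1: 0.29, 2: 0.46, 3: 0.25}


def _per_arm(d: dict) -> dict:
    return {k: dict(v) for k, v in d.items()}


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_cohort`.

    All rates are per year; slopes are in indicator units per year (negative =
    deterioration except RV); ``rtog_transition_prob`` is the yearly
    probability of a one-grade RTOG increase; ``qlq_drift`` is the yearly
    mean shift of raw fatigue/dyspnea scores.
    """

    n_per_arm: int = 60
    seed: int = 0
    baseline: dict = field(default_factory=lambda: _per_arm(_BASELINES))
    decline_slope: dict = field(default_factory=lambda: _per_arm(_SLOPES))
    noise_sd: dict = field(default_factory=lambda: dict(_NOISE_SD))
    rtog_transition_prob: dict = field(
        default_factory=lambda: {"CRT": 0.05, "H-IGRT": 0.03}
    )
    qlq_drift: dict = field(default_factory=lambda: {"CRT": 0.040, "H-IGRT": 0.025})
    max_follow_up: float = 13.0
    dropout_rate: float = 0.02
    death_rate: float = 0.012
    recurrence_rate: float = 0.02
    p_bias: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.max_follow_up <= 0:
            raise ValueError("max_follow_up must be positive")
        for name in ("dropout_rate", "death_rate", "recurrence_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")
        for ind, per_arm in self.baseline.items():
            for arm, (_, sd) in per_arm.items():
                if sd < 0:
                    raise ValueError(f"baseline sd for {ind}/{arm} must be >= 0")
        for arm, p in self.rtog_transition_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rtog_transition_prob[{arm}] must be in [0, 1]")

    @classmethod
    def zero_dynamics(cls, **kwargs) -> "SimConfig":
        """A degenerate configuration with no decline, drift or noise.

        Every indicator is constant over time, so the downstream composite
        endpoint censors 100% of patients — a useful null fixture.
        """
        cfg = cls(**kwargs)
        cfg.decline_slope = {
            ind: {arm: 0.0 for arm in per_arm} for ind, per_arm in cfg.decline_slope.items()
        }
        cfg.noise_sd = {ind: 0.0 for ind in cfg.noise_sd}
        cfg.rtog_transition_prob = {arm: 0.0 for arm in cfg.rtog_transition_prob}
        cfg.qlq_drift = {arm: 0.0 for arm in cfg.qlq_drift}
        return cfg


def visit_schedule(follow_up_years: float) -> list[float]:
    """Assessment times in years from randomization, truncated at follow-up.

    Baseline (0), a single post-therapy visit at 0.25 y (the midpoint of the
    1-3 month window after a 3-7 week treatment course), then yearly visits
    1, 2, ... up to follow-up.
    """
    if follow_up_years <= 0:
        raise ValueError("follow_up_years must be positive")
    visits = [0.0, 0.25] + [float(k) for k in range(1, int(math.floor(follow_up_years)) + 1)]
    return [t for t in visits if t <= follow_up_years]


def _draw_strata(rng: np.random.Generator) -> tuple[str, str, str]:
    nodal = "N+" if rng.random() < _P_NODE_POSITIVE else "N0"
    surgery = "mastectomy" if rng.random() < _P_MASTECTOMY else "lumpectomy"
    chemo = rng.choice(list(_P_CHEMO), p=list(_P_CHEMO.values()))
    return nodal, surgery, str(chemo)


def _exp_or_inf(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else math.inf


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-arm cohort; returns ``(patients, measurements)``.

    ``patients`` has one row per patient (arm, strata, covariates, follow-up,
    death/recurrence times); ``measurements`` is long-format with one row per
    patient x indicator x visit.  Identical config + seed gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    coin = CoinState(p_bias=config.p_bias)
    n_total = 2 * config.n_per_arm

    patients = []
    meas_rows: list[tuple] = []
    for i in range(n_total):
        pid = f"P{i + 1:04d}"
        nodal, surgery, chemo = _draw_strata(rng)
        arm = ARMS[efron_assign(coin, (nodal, surgery, chemo), rng)]

        age = float(np.clip(rng.normal(56.5, 11.5), 30.0, 85.0))
        weight = float(np.clip(rng.normal(68.0, 14.0), 40.0, 130.0))
        laterality = "left" if rng.random() < _P_LEFT else "right"
        nodal_irr = rng.random() < _P_NODAL_IRRADIATION
        trastuzumab = rng.random() < _P_TRASTUZUMAB
        histo_grade = int(rng.choice(list(_P_GRADE), p=list(_P_GRADE.values())))

        death = _exp_or_inf(rng, config.death_rate)
        dropout = _exp_or_inf(rng, config.dropout_rate)
        recurrence = _exp_or_inf(rng, config.recurrence_rate)
        follow_up = min(config.max_follow_up, dropout, death)
        follow_up = max(follow_up, 1e-3)  # at least the baseline visit
        death_time = death if death <= min(config.max_follow_up, dropout) else math.nan
        recurrence_time = recurrence if recurrence <= follow_up else math.nan

        patients.append(
            {
                "patient_id": pid,
                "arm": arm,
                "nodal_status": nodal,
                "surgery": surgery,
                "chemo": chemo,
                "age": age,
                "weight": weight,
                "laterality": laterality,
                "nodal_irradiation": nodal_irr,
                "trastuzumab": trastuzumab,
                "histological_grade": histo_grade,
                "follow_up_years": follow_up,
                "death_time": death_time,
                "recurrence_time": recurrence_time,
            }
        )

        visits = np.asarray(visit_schedule(follow_up))

        # continuous indicators: patient-specific linear trajectory + noise
        for ind in CONTINUOUS_INDICATORS:
            mean, sd = config.baseline[ind][arm]
            base = max(rng.normal(mean, sd), 0.01 * mean)
            slope = config.decline_slope[ind][arm]
            noise = config.noise_sd[ind]
            eps = rng.normal(0.0, noise, size=len(visits)) if noise > 0 else np.zeros(len(visits))
            vals = np.maximum(base + slope * visits + eps, 0.01 * mean)
            if ind == "LVEF":
                vals = np.minimum(vals, 100.0)
            for t, v in zip(visits, vals):
                meas_rows.append((pid, ind, float(t), float(v)))

        # RTOG grades: monotone non-decreasing step process
        p_step = config.rtog_transition_prob[arm]
        for ind in ORDINAL_INDICATORS:
            grade = 0
            prev_t = 0.0
            for t in visits:
                dt = t - prev_t
                if dt > 0 and p_step > 0 and grade < 5:
                    if rng.random() < 1.0 - (1.0 - p_step) ** dt:
                        grade += 1
                prev_t = t
                meas_rows.append((pid, ind, float(t), float(grade)))

        # QLQ raw scores: base + drift + noise, clipped to the 1-4 scale
        drift = config.qlq_drift[arm]
        for ind in QLQ_INDICATORS:
            mean, sd = config.baseline[ind][arm]
            base = float(np.clip(rng.normal(mean, sd), 1.0, 4.0))
            noise = config.noise_sd[ind]
            eps = rng.normal(0.0, noise, size=len(visits)) if noise > 0 else np.zeros(len(visits))
            vals = np.clip(base + drift * visits + eps, 1.0, 4.0)
            for t, v in zip(visits, vals):
                meas_rows.append((pid, ind, float(t), float(v)))

    patients_df = pd.DataFrame(patients)
    measurements_df = pd.DataFrame(
        meas_rows, columns=["patient_id", "indicator", "time_years", "value"]
    )
    return patients_df, measurements_df
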