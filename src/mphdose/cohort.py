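"""Longitudinal ADHD cohort: data model, CSV I/O, eligibility, simulation.

A cohort is a pair of pandas tables. The *visit table* has one row per
patient-visit with mandatory columns ``patient_id``, ``visit_index``,
``time_months``, ``severity_score``, ``dose_mg_per_kg``, ``response`` plus
any covariate columns; the *baseline table* has one row per patient with
``patient_id``, ``baseline_severity``, ``age_months``, ``sex``,
``birth_weight_kg``.

The outcome is the dichotomized Conners' Parent Rating Scale (revised short
form, CPRS-R:S) total: a score of 40 or below no longer meets ADHD criteria
and counts as improvement (response 1).

The synthetic generator emulates the retrospective clinic cohort this
package was designed around (221 children, baseline severity ~ 51 +/- 11,
about five follow-ups spanning ~22 months) with responses drawn from the
random-intercept logistic dose model in :mod:`mphdose.glmm`, so every
downstream stage is testable without access to clinical records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ValidationError
from .glmm import ADHD_MPH_PARAMS, ModelParams, SEVERITY, TIME, inv_logit, linear_predictor

SEVERITY_MIN = 0
SEVERITY_MAX = 81
IMPROVEMENT_CUTOFF = 40  # CPRS-R:S total <= 40 means not meeting ADHD criteria
AGE_MIN_MONTHS = 36
AGE_MAX_MONTHS = 156

MANDATORY_COLUMNS = [
    "patient_id",
    "visit_index",
    "time_months",
    "severity_score",
    "dose_mg_per_kg",
    "response",
]
BASELINE_COLUMNS = ["patient_id", "baseline_severity", "age_months", "sex", "birth_weight_kg"]

#: marginal rates/moments used for covariates the dosing model does not drive
COVARIATE_DISTRIBUTIONS = {
    "sex_male_rate": 0.765,
    "age_months_mean": 82.5,
    "age_months_sd": 26.5,
    "birth_weight_kg_mean": 3.09,
    "birth_weight_kg_sd": 0.56,
    "weight_kg_mean": 30.95,
    "weight_kg_sd": 5.62,
    "weight_kg_growth_per_month": 0.15,
    "risperidone_rate": 0.25,
    "fluoxetine_rate": 0.10,
    "odd_rate": 0.195,
    "mood_disorder_rate": 0.027,
    "anxiety_disorder_rate": 0.249,
    "other_comorbidity_rate": 0.176,
}


@dataclass(frozen=True)
class VisitRecord:
    """One patient-visit observation."""

    patient_id: str
    visit_index: int
    time_months: float
    severity_score: int
    dose_mg_per_kg: float
    response: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.visit_index < 0:
            raise ValidationError(f"{self.patient_id}: visit_index must be >= 0")
        if (self.time_months == 0) != (self.visit_index == 0):
            raise ValidationError(
                f"{self.patient_id}: time_months must be 0 exactly at visit_index 0"
            )
        if not SEVERITY_MIN <= self.severity_score <= SEVERITY_MAX:
            raise ValidationError(
                f"{self.patient_id} visit {self.visit_index}: severity_score "
                f"{self.severity_score} outside [{SEVERITY_MIN}, {SEVERITY_MAX}]"
            )
        if self.dose_mg_per_kg <= 0:
            raise ValidationError(
                f"{self.patient_id} visit {self.visit_index}: dose must be > 0"
            )
        if self.response != dichotomize(self.severity_score):
            raise ValidationError(
                f"{self.patient_id} visit {self.visit_index}: response "
                f"{self.response} inconsistent with severity {self.severity_score}"
            )


@dataclass(frozen=True)
class PatientBaseline:
    """Per-patient enrollment characteristics."""

    patient_id: str
    baseline_severity: int
    age_months: float
    sex: int
    birth_weight_kg: float

    def __post_init__(self) -> None:
        if self.baseline_severity <= IMPROVEMENT_CUTOFF:
            raise ValidationError(
                f"{self.patient_id}: baseline severity must exceed {IMPROVEMENT_CUTOFF}"
            )
        if not AGE_MIN_MONTHS <= self.age_months <= AGE_MAX_MONTHS:
            raise ValidationError(
                f"{self.patient_id}: age {self.age_months} months outside "
                f"[{AGE_MIN_MONTHS}, {AGE_MAX_MONTHS}]"
            )


def dichotomize(severity_score: int) -> int:
    """Dichotomize a CPRS-R:S total: 1 (improved) iff score <= 40.

    Raises :class:`ValidationError` for scores outside [0, 81].
    """
    if not SEVERITY_MIN <= severity_score <= SEVERITY_MAX:
        raise ValidationError(
            f"severity score {severity_score} outside [{SEVERITY_MIN}, {SEVERITY_MAX}]"
        )
    return 1 if severity_score <= IMPROVEMENT_CUTOFF else 0


def apply_eligibility(visits: pd.DataFrame, baselines: pd.DataFrame):
    """Filter a cohort to the study's eligibility rules.

    Retains patients aged 3-13 years (36-156 months) at baseline, meeting
    ADHD criteria at baseline (severity > 40), and with at least one
    follow-up visit. Returns ``(visits, baselines, report)`` where
    ``report`` counts exclusions by reason; a patient violating several
    rules is counted once, under the first of age / baseline severity /
    missing follow-up.
    """
    known = set(baselines["patient_id"])
    seen = set(visits["patient_id"])
    if not seen <= known:
        missing = sorted(seen - known)[:5]
        raise ValidationError(f"patients in visit table missing from baselines: {missing}")
    counts = visits.groupby("patient_id").size()
    report = {"age": 0, "baseline_severity": 0, "no_follow_up": 0}
    keep = []
    for row in baselines.itertuples(index=False):
        if not AGE_MIN_MONTHS <= row.age_months <= AGE_MAX_MONTHS:
            report["age"] += 1
        elif row.baseline_severity <= IMPROVEMENT_CUTOFF:
            report["baseline_severity"] += 1
        elif counts.get(row.patient_id, 0) < 2:
            report["no_follow_up"] += 1
        else:
            keep.append(row.patient_id)
    keep_set = set(keep)
    visits_f = visits[visits["patient_id"].isin(keep_set)].reset_index(drop=True)
    baselines_f = baselines[baselines["patient_id"].isin(keep_set)].reset_index(drop=True)
    report["retained"] = len(keep)
    return visits_f, baselines_f, report


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic-cohort generator.

    Defaults reproduce the reference clinic cohort's size and visit
    structure; ``true_params`` is the generating dose-response model.
    """

    n_patients: int = 221
    true_params: ModelParams = ADHD_MPH_PARAMS
    baseline_severity_mean: float = 51.38
    baseline_severity_sd: float = 10.82
    followups_mean: float = 4.94
    period_months_mean: float = 22.42
    dose_policy: str = "constant-per-patient"
    dose_range_mg_per_kg: tuple = (0.1, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        lo, hi = self.dose_range_mg_per_kg
        if lo <= 0 or hi <= lo:
            raise ValidationError(f"dose range must satisfy 0 < lo < hi, got {(lo, hi)}")
        if self.dose_policy not in ("constant-per-patient", "random-walk", "adaptive"):
            raise ValidationError(f"unknown dose_policy '{self.dose_policy}'")
        # visit gaps are uniform on [1, 2 * period / followups] months
        if 2.0 * self.period_months_mean / self.followups_mean <= 1.0:
            raise ValidationError(
                "period_months_mean / followups_mean must exceed 0.5 months"
            )
        if self.true_params.sigma2 < 0:
            raise ValidationError("sigma2 must be >= 0")


def _truncated_severity(rng, mean, sd):
    """Baseline severity drawn from N(mean, sd^2) truncated to (40, 81]."""
    a = (IMPROVEMENT_CUTOFF - mean) / sd
    b = (SEVERITY_MAX - mean) / sd
    x = truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd)
    return int(np.clip(round(x), IMPROVEMENT_CUTOFF + 1, SEVERITY_MAX))


def _synthesize_score(rng, y):
    """Display-level CPRS score consistent with the binary outcome."""
    return int(rng.integers(20, 41)) if y == 1 else int(rng.integers(41, 71))


def generate_cohort(config: CohortConfig):
    """Simulate a longitudinal cohort from the dose-response model.

    For each patient: a random intercept b ~ N(0, sigma^2); a truncated-
    normal baseline severity; 1 + Poisson(followups_mean - 1) follow-ups at
    strictly increasing times (uniform gaps whose mean matches the
    configured treatment period); doses from ``dose_policy`` within
    ``dose_range_mg_per_kg``; and responses Y ~ Bernoulli(inv_logit(eta))
    with eta from :func:`mphdose.glmm.linear_predictor` using the baseline
    severity as the severity covariate. Per-patient RNG substreams are keyed
    by (seed, patient counter), so output is reproducible and independent of
    patient order.

    Returns ``(visits, baselines)`` DataFrames.
    """
    cd = COVARIATE_DISTRIBUTIONS
    params = config.true_params
    lo, hi = config.dose_range_mg_per_kg
    log_lo, log_hi = math.log(lo), math.log(hi)
    b_sd = math.sqrt(params.sigma2)
    mean_gap = config.period_months_mean / config.followups_mean
    visit_rows = []
    base_rows = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"P{i:04d}"
        b_i = rng.normal(0.0, b_sd) if b_sd > 0 else 0.0
        severity0 = _truncated_severity(rng, config.baseline_severity_mean, config.baseline_severity_sd)
        sex = int(rng.uniform() < cd["sex_male_rate"])
        age = float(np.clip(round(rng.normal(cd["age_months_mean"], cd["age_months_sd"])),
                            AGE_MIN_MONTHS, AGE_MAX_MONTHS))
        bw = float(np.clip(rng.normal(cd["birth_weight_kg_mean"], cd["birth_weight_kg_sd"]), 1.5, 5.5))
        weight0 = float(max(rng.normal(cd["weight_kg_mean"], cd["weight_kg_sd"]), 10.0))
        flags = {
            name: int(rng.uniform() < cd[f"{name}_rate"])
            for name in ("risperidone", "fluoxetine", "odd", "mood_disorder",
                         "anxiety_disorder", "other_comorbidity")
        }
        n_follow = 1 + int(rng.poisson(max(config.followups_mean - 1.0, 0.0)))
        gaps = rng.uniform(1.0, 2.0 * mean_gap, size=n_follow)
        times = np.concatenate([[0.0], np.cumsum(gaps)])

        if config.dose_policy == "constant-per-patient":
            doses = np.full(n_follow + 1, math.exp(rng.uniform(log_lo, log_hi)))
        elif config.dose_policy == "random-walk":
            d0 = math.exp(rng.uniform(log_lo, log_hi))
            steps = rng.normal(0.0, 0.1, size=n_follow)
            doses = np.clip(d0 * np.exp(np.concatenate([[0.0], np.cumsum(steps)])), lo, hi)
        else:  # adaptive: naive titration against the last response
            doses = np.empty(n_follow + 1)
            doses[0] = math.exp(0.5 * (log_lo + log_hi))

        base_rows.append(
            {"patient_id": pid, "baseline_severity": severity0, "age_months": age,
             "sex": sex, "birth_weight_kg": bw}
        )
        for j, t in enumerate(times):
            dose = float(doses[j])
            cov = {TIME: float(t), SEVERITY: float(severity0), "sex": sex,
                   "age_months": age, "birth_weight_kg": bw,
                   "weight_kg": weight0 + cd["weight_kg_growth_per_month"] * float(t),
                   **flags}
            eta = linear_predictor(params, cov, dose, b_i)
            y = int(rng.uniform() < inv_logit(eta))
            if config.dose_policy == "adaptive" and j < n_follow:
                doses[j + 1] = float(np.clip(dose * (1.25 if y == 0 else 1 / 1.1), lo, hi))
            score = severity0 if (j == 0 and y == 0) else _synthesize_score(rng, y)
            visit_rows.append(
                {"patient_id": pid, "visit_index": j, "time_months": float(t),
                 "severity_score": score, "dose_mg_per_kg": dose, "response": y,
                 **cov}
            )
    visits = pd.DataFrame(visit_rows)
    baselines = pd.DataFrame(base_rows)
    return visits, baselines


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_cohort_csv(path, validate: bool = True) -> pd.DataFrame:
    """Read a visit table from CSV (UTF-8, ``#`` comment lines allowed).

    Rows are returned sorted by ``(patient_id, visit_index)``. Missing
    mandatory columns and non-numeric cells raise :class:`ValidationError`
    naming the offender.
    """
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing mandatory column '{col}'")
    for col in df.columns:
        if col == "patient_id":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise ValidationError(f"non-numeric value in column '{col}' at line {row}")
        df[col] = coerced
    df = df.sort_values(["patient_id", "visit_index"], kind="mergesort").reset_index(drop=True)
    if validate:
        _validate_visits(df)
    return df


def _validate_visits(df: pd.DataFrame) -> None:
    resp = np.asarray(df["response"], dtype=float)
    if not np.all(np.isin(resp, (0.0, 1.0))):
        raise ValidationError("response must be binary 0/1")
    if np.any(np.asarray(df["dose_mg_per_kg"], dtype=float) <= 0):
        raise ValidationError("all doses must be > 0 mg/kg")
    sev = np.asarray(df["severity_score"], dtype=float)
    if np.any((sev < SEVERITY_MIN) | (sev > SEVERITY_MAX)):
        raise ValidationError(f"severity_score outside [{SEVERITY_MIN}, {SEVERITY_MAX}]")
    expected = (sev <= IMPROVEMENT_CUTOFF).astype(float)
    mismatch = np.flatnonzero(expected != resp)
    if mismatch.size:
        r = df.iloc[int(mismatch[0])]
        raise ValidationError(
            f"response inconsistent with severity for patient {r['patient_id']} "
            f"visit {int(r['visit_index'])}"
        )


def write_cohort_csv(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a visit (or baseline) table to UTF-8, newline-terminated CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False)
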