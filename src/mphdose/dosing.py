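"""Dose individualization by inverting the fitted mixed logit model.

The recommendation procedure has two steps. First, a target improvement
probability p0 is fixed — by default the 90th percentile of the fitted
last-visit improvement probabilities across the cohort, each evaluated at
that patient's empirical-Bayes random intercept. Second, the fitted model
is solved for the dose that attains p0 for a given patient:

    D = exp{ (logit(p0) - beta0 - X beta - b_hat) / d }

with b_hat = 0 for a brand-new patient and, at every later visit, b_hat
re-predicted from the patient's accumulated responses. Because the model is
log-linear in dose, the inversion is exact: plugging the recommended dose
back into the model returns exactly p0.

Raw inversions are clipped to a configurable safety range (default
0.01-2.0 mg/kg) because the exponential is unbounded; recommendations
retain the pre-clip value and a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .eb import PatientHistory, predict_b
from .glmm import (
    DEFAULT_N_NODES,
    FitResult,
    ModelParams,
    SEVERITY,
    TIME,
    inv_logit,
    linear_predictor,
    logit,
)

#: default safety range for recommended doses, mg/kg
DEFAULT_DOSE_CLIP = (0.01, 2.0)
DEFAULT_PERCENTILE = 90.0


@dataclass(frozen=True)
class DoseTarget:
    """Target improvement probability p0 and its logit."""

    p0: float
    logit_p0: float
    source: str = "explicit"

    @classmethod
    def from_p0(cls, p0: float, source: str = "explicit") -> "DoseTarget":
        if not 0.0 < p0 < 1.0:
            raise ValidationError(f"p0 must be in (0, 1), got {p0}")
        return cls(p0=float(p0), logit_p0=logit(p0), source=source)

    @classmethod
    def from_logit(cls, logit_p0: float, source: str = "explicit") -> "DoseTarget":
        return cls(p0=float(inv_logit(logit_p0)), logit_p0=float(logit_p0), source=source)


@dataclass(frozen=True)
class DoseRecommendation:
    """A recommended dose together with the inputs that produced it."""

    dose_mg_per_kg: float
    b_hat_used: float
    logit_p0_used: float
    severity_used: float
    severity_mode: str
    time_months: float
    clipped: bool = False
    dose_unclipped: float | None = None

    def to_dict(self) -> dict:
        return {
            "dose_mg_per_kg": self.dose_mg_per_kg,
            "b_hat_used": self.b_hat_used,
            "logit_p0_used": self.logit_p0_used,
            "severity_used": self.severity_used,
            "severity_mode": self.severity_mode,
            "time_months": self.time_months,
            "clipped": self.clipped,
            "dose_unclipped": self.dose_unclipped,
        }


def compute_target_p0(
    fit: FitResult,
    cohort: pd.DataFrame,
    percentile: float = DEFAULT_PERCENTILE,
    eb_method: str = "mode",
    n_nodes: int = DEFAULT_N_NODES,
) -> DoseTarget:
    """Construct p0 as a percentile of fitted last-visit probabilities.

    For every patient the improvement probability at their last recorded
    visit is evaluated with that patient's empirical-Bayes b-hat (predicted
    from all of their visits); p0 is the requested percentile (linear
    interpolation between order statistics) of those probabilities.
    """
    if not 0.0 < percentile < 100.0:
        raise ValidationError(f"percentile must be in (0, 100), got {percentile}")
    if cohort.empty:
        raise ValidationError("cohort is empty")
    params = fit.params
    cov_names = list(params.beta)
    probs = []
    for _, patient in cohort.groupby("patient_id", sort=False):
        history = PatientHistory.from_frame(patient, cov_names)
        b_hat, _ = predict_b(params, history, method=eb_method, n_nodes=n_nodes)
        last = patient.sort_values("time_months").iloc[-1]
        cov = {n: (float(last["time_months"]) if n == TIME else float(last[n])) for n in cov_names}
        eta = linear_predictor(params, cov, float(last["dose_mg_per_kg"]), b_hat)
        probs.append(inv_logit(eta))
    p0 = float(np.percentile(np.asarray(probs), percentile))
    return DoseTarget.from_p0(p0, source="percentile_from_fit")


def _invert(
    params: ModelParams,
    covariates: Mapping[str, float],
    b_hat: float,
    target: DoseTarget,
    clip_range,
) -> tuple:
    if params.d == 0:
        raise DomainError("log-dose coefficient d = 0: the model cannot be inverted for dose")
    eta_at_unit_dose = linear_predictor(params, covariates, 1.0, b_hat)
    dose = math.exp((target.logit_p0 - eta_at_unit_dose) / params.d)
    if clip_range is None:
        return dose, False, None
    lo, hi = clip_range
    if lo <= dose <= hi:
        return dose, False, None
    return float(np.clip(dose, lo, hi)), True, dose


def initial_dose(
    params: ModelParams,
    baseline_severity: float,
    other_covariates: Mapping[str, float] | None = None,
    target: DoseTarget = None,
    clip_range=DEFAULT_DOSE_CLIP,
) -> DoseRecommendation:
    """Recommended dose for a brand-new patient (b-hat = 0, time 0)."""
    if not 0 <= baseline_severity <= 81:
        raise ValidationError(f"baseline severity {baseline_severity} outside [0, 81]")
    cov = dict(other_covariates or {})
    cov[SEVERITY] = float(baseline_severity)
    if TIME in params.beta:
        cov.setdefault(TIME, 0.0)
    dose, clipped, raw = _invert(params, cov, 0.0, target, clip_range)
    return DoseRecommendation(
        dose_mg_per_kg=dose,
        b_hat_used=0.0,
        logit_p0_used=target.logit_p0,
        severity_used=float(baseline_severity),
        severity_mode="baseline",
        time_months=0.0,
        clipped=clipped,
        dose_unclipped=raw,
    )


def followup_dose(
    params: ModelParams,
    severity: float,
    time_months: float,
    b_hat: float,
    target: DoseTarget,
    severity_mode: str = "current",
    other_covariates: Mapping[str, float] | None = None,
    clip_range=DEFAULT_DOSE_CLIP,
) -> DoseRecommendation:
    """Recommended dose at a follow-up visit given the current b-hat.

    ``severity`` is the score selected by ``severity_mode`` ("current":
    this visit's CPRS-R:S total, the default; "baseline": the enrollment
    score — both are accepted because the reference publication's worked
    examples are consistent only with the current score while its formula
    text names the baseline score).
    """
    if time_months < 0:
        raise ValidationError(f"time_months must be >= 0, got {time_months}")
    if severity_mode not in ("current", "baseline"):
        raise ValidationError(f"unknown severity_mode '{severity_mode}'")
    cov = dict(other_covariates or {})
    cov[SEVERITY] = float(severity)
    if TIME in params.beta:
        cov[TIME] = float(time_months)
    dose, clipped, raw = _invert(params, cov, b_hat, target, clip_range)
    return DoseRecommendation(
        dose_mg_per_kg=dose,
        b_hat_used=float(b_hat),
        logit_p0_used=target.logit_p0,
        severity_used=float(severity),
        severity_mode=severity_mode,
        time_months=float(time_months),
        clipped=clipped,
        dose_unclipped=raw,
    )


def recommend_trajectory(
    params: ModelParams,
    target: DoseTarget,
    patient_stream: pd.DataFrame,
    severity_mode: str = "current",
    b_hat_overrides: Sequence[float] | None = None,
    eb_method: str = "mode",
    n_nodes: int = DEFAULT_N_NODES,
    clip_range=DEFAULT_DOSE_CLIP,
):
    """Sequential recommendations over an observed visit stream.

    ``patient_stream`` has one row per visit, ordered in time, with columns
    ``time_months``, ``severity_score``, ``response`` and optionally
    ``dose_mg_per_kg`` (the administered dose; when absent, the previous
    recommendation is assumed administered) plus covariate columns required
    by the model. The first visit uses b-hat = 0; visit n > 1 re-predicts
    b-hat from all prior visits. ``b_hat_overrides`` replaces computed
    b-hat values where not None (e.g. to replay published worked examples).

    Returns ``(recommendations, b_hats)``.
    """
    times = np.asarray(patient_stream["time_months"], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("patient stream times must be strictly increasing")
    rows = patient_stream.to_dict("records")
    extra_names = [n for n in params.beta if n not in (SEVERITY, TIME)]
    baseline_severity = float(rows[0]["severity_score"])
    history = PatientHistory()
    recs, b_hats = [], []
    for n, row in enumerate(rows):
        severity = baseline_severity if severity_mode == "baseline" else float(row["severity_score"])
        if b_hat_overrides is not None and b_hat_overrides[n] is not None:
            b_hat = float(b_hat_overrides[n])
        elif n == 0:
            b_hat = 0.0
        else:
            b_hat, _ = predict_b(params, history, method=eb_method, n_nodes=n_nodes)
        other = {}
        for name in extra_names:
            if name not in row:
                raise ValidationError(f"stream rows lack covariate '{name}'")
            other[name] = float(row[name])
        rec = followup_dose(
            params,
            severity,
            float(row["time_months"]),
            b_hat,
            target,
            severity_mode=severity_mode,
            other_covariates=other,
            clip_range=clip_range,
        )
        recs.append(rec)
        b_hats.append(b_hat)
        administered = row.get("dose_mg_per_kg")
        if administered is None or (isinstance(administered, float) and math.isnan(administered)):
            administered = rec.dose_mg_per_kg
        cov = {SEVERITY: severity, **other}
        if TIME in params.beta:
            cov[TIME] = float(row["time_months"])
        history = history.appended(
            float(row["time_months"]), float(administered), int(row["response"]), cov
        )
    return recs, b_hats


def dose_response_curves(
    params: ModelParams,
    target: DoseTarget,
    severity_grid: Sequence[float],
    time_grid: Sequence[float],
    other_covariates: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Dose at b-hat = 0 over a (severity, time) grid, for plotting.

    Closed form: one extra month scales the dose by exp(-beta_time/d), one
    severity point by exp(-beta_severity/d); under the reference fit the
    dose is increasing in severity and decreasing in treatment time. No
    safety clipping is applied so the log-linear structure stays exact.
    """
    severity_grid = list(severity_grid)
    time_grid = list(time_grid)
    if not severity_grid or not time_grid:
        raise ValidationError("severity and time grids must be non-empty")
    rows = []
    for sev in severity_grid:
        for t in time_grid:
            rec = followup_dose(
                params, sev, t, 0.0, target,
                other_covariates=other_covariates, clip_range=None,
            )
            rows.append(
                {"severity": float(sev), "time_months": float(t),
                 "dose_mg_per_kg": rec.dose_mg_per_kg}
            )
    return pd.DataFrame(rows)
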