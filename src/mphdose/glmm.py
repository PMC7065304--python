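"""Random-intercept logistic regression with a log-dose term.

The model for the binary improvement indicator ``Y_ij`` of patient *i* at
visit *j* is

    logit P(Y_ij = 1) = beta0 + X_ij beta + b_i + d * ln(D_ij),
    b_i ~ Normal(0, sigma^2)

where ``D_ij`` is the administered methylphenidate dose in mg/kg, ``X_ij``
holds the fixed covariates (months on treatment, baseline CPRS-R:S severity
centered at a stored constant, and any extra clinical covariates), and
``b_i`` is a patient-level random intercept capturing unobserved
heterogeneity in treatment response.

The marginal log-likelihood integrates the random intercept out of each
patient's Bernoulli likelihood by adaptive Gauss-Hermite quadrature: the
quadrature nodes are recentered at the patient's posterior mode of ``b_i``
and rescaled by the posterior curvature there, so a modest number of nodes
(default 15) integrates the near-Gaussian posteriors essentially exactly.
Maximum likelihood is taken over ``(beta0, beta, d, ln sigma)``; optimizing
``ln sigma`` keeps the variance positive without an active constraint.
Standard errors come from the inverse of a central-difference Hessian of the
negative log-likelihood; confidence intervals and p-values are Wald.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .errors import ConvergenceError, DomainError, ValidationError

INTERCEPT = "intercept"
LOG_DOSE = "log_dose"
SEVERITY = "severity"
TIME = "time_months"

DEFAULT_N_NODES = 15
#: convergence declared when the loglik gradient infinity-norm is below this
GRAD_TOL = 1e-5
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelParams:
    """Population parameters of the random-intercept logistic dose model.

    Parameters
    ----------
    beta0
        Fixed intercept on the logit scale.
    beta
        Named fixed-effect coefficients. The key ``"severity"`` is special:
        its covariate enters as ``score - severity_center``.
    d
        Coefficient of the natural log of the dose in mg/kg.
    sigma2
        Variance of the patient-level random intercept; must be >= 0.
    severity_center
        Centering constant for the severity covariate (the cohort mean
        baseline CPRS-R:S score in the reference model).
    """

    beta0: float
    beta: Mapping[str, float]
    d: float
    sigma2: float
    severity_center: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValidationError(f"sigma2 must be >= 0, got {self.sigma2}")
        object.__setattr__(self, "beta", dict(self.beta))


#: Published estimates of the multivariable random-intercept model for the
#: retrospective ADHD/methylphenidate cohort that motivates this package.
#: Used both as the reference model for dose recommendation examples and as
#: the default ground truth of the synthetic-cohort generator.
ADHD_MPH_PARAMS = ModelParams(
    beta0=1.9377,
    beta={TIME: 0.0800, SEVERITY: -0.0512},
    d=0.8610,
    sigma2=1.452,
    severity_center=51.3817,
)


def inv_logit(eta):
    """Numerically stable inverse logit 1/(1+exp(-eta))."""
    return expit(eta)


def logit(p):
    """Log-odds ln(p/(1-p))."""
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def linear_predictor(
    params: ModelParams,
    covariates: Mapping[str, float],
    dose: float,
    b: float = 0.0,
) -> float:
    """Evaluate eta = beta0 + X beta + b + d ln(dose) for one visit.

    ``covariates`` must contain every name appearing in ``params.beta``;
    the severity covariate is centered at ``params.severity_center``.
    """
    if dose <= 0:
        raise DomainError(f"dose must be > 0 mg/kg, got {dose}")
    eta = params.beta0 + b + params.d * math.log(dose)
    for name, coef in params.beta.items():
        if name not in covariates:
            raise ValidationError(f"covariate '{name}' required by the model is missing")
        x = float(covariates[name])
        if name == SEVERITY:
            x -= params.severity_center
        eta += coef * x
    return float(eta)


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def _build_design(
    cohort: pd.DataFrame,
    covariate_names: Sequence[str],
    include_dose: bool,
    severity_center: float,
):
    """Return (X, y, patient_codes, coefficient_names) for a visit table."""
    if "response" not in cohort.columns:
        raise ValidationError("cohort is missing mandatory column 'response'")
    y = np.asarray(cohort["response"], dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("response must be binary 0/1")
    n = len(cohort)
    names = [INTERCEPT]
    cols = [np.ones(n)]
    for name in covariate_names:
        if name == LOG_DOSE:
            continue  # handled by include_dose below
        if name not in cohort.columns:
            raise ValidationError(f"covariate column '{name}' not found in cohort")
        v = np.asarray(cohort[name], dtype=float)
        if name == SEVERITY:
            v = v - severity_center
        names.append(name)
        cols.append(v)
    if include_dose:
        dvals = np.asarray(cohort["dose_mg_per_kg"], dtype=float)
        if np.any(dvals <= 0) or np.any(~np.isfinite(dvals)):
            raise DomainError("all doses must be finite and > 0 mg/kg")
        names.append(LOG_DOSE)
        cols.append(np.log(dvals))
    X = np.column_stack(cols)
    codes = pd.factorize(cohort["patient_id"])[0]
    return X, y, codes, names


# ---------------------------------------------------------------------------
# marginal likelihood by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _bernoulli_loglik_sums(eta, y, codes, n_pat):
    """Per-patient sums of Bernoulli log-likelihoods at linear predictor eta."""
    ll = y * eta - np.logaddexp(0.0, eta)
    return np.bincount(codes, weights=ll, minlength=n_pat)


def _posterior_modes(eta_fix, y, codes, n_pat, sigma2, b0=None, tol=1e-12, max_iter=100):
    """Vectorized safeguarded Newton for each patient's posterior mode of b.

    Maximizes sum_j [y eta - log(1+e^eta)] - b^2/(2 sigma2), a strictly
    concave scalar problem per patient; steps are halved until the penalized
    log-posterior does not decrease (beyond rounding). Returns
    (modes, curvatures) with curvature the negative second derivative at the
    mode. ``b0`` warm-starts the iteration.
    """
    b = np.zeros(n_pat) if b0 is None else np.array(b0, dtype=float)

    def objective(bv):
        return (
            _bernoulli_loglik_sums(eta_fix + bv[codes], y, codes, n_pat)
            - bv * bv / (2.0 * sigma2)
        )

    f = objective(b)
    for _ in range(max_iter):
        eta = eta_fix + b[codes]
        p = expit(eta)
        g = np.bincount(codes, weights=y - p, minlength=n_pat) - b / sigma2
        if np.max(np.abs(g)) < tol:
            break
        h = np.bincount(codes, weights=p * (1.0 - p), minlength=n_pat) + 1.0 / sigma2
        step = g / h
        f_new = objective(b + step)
        for _ in range(40):
            bad = f_new < f - 1e-10
            if not np.any(bad):
                break
            step = np.where(bad, 0.5 * step, step)
            f_new = objective(b + step)
        b = b + step
        f = f_new
    eta = eta_fix + b[codes]
    p = expit(eta)
    curv = np.bincount(codes, weights=p * (1.0 - p), minlength=n_pat) + 1.0 / sigma2
    return b, curv


_HERMGAUSS_CACHE: dict = {}


def _hermgauss(n_nodes):
    if n_nodes not in _HERMGAUSS_CACHE:
        _HERMGAUSS_CACHE[n_nodes] = hermgauss(n_nodes)
    return _HERMGAUSS_CACHE[n_nodes]


def _agq_loglik(w, sigma2, X, y, codes, n_pat, n_nodes, b0=None):
    """Adaptive GH approximation to the marginal log-likelihood."""
    eta_fix = X @ w
    if sigma2 == 0.0:
        return float(np.sum(y * eta_fix - np.logaddexp(0.0, eta_fix)))
    mode, curv = _posterior_modes(eta_fix, y, codes, n_pat, sigma2, b0=b0)
    if b0 is not None:
        b0[:] = mode  # warm-start the next evaluation
    z, gw = _hermgauss(n_nodes)
    s = 1.0 / np.sqrt(curv)
    log_terms = np.empty((n_pat, n_nodes))
    sqrt2 = math.sqrt(2.0)
    log_norm_const = -_LOG_SQRT_2PI - 0.5 * math.log(sigma2)
    for q in range(n_nodes):
        bq = mode + sqrt2 * s * z[q]
        ll = _bernoulli_loglik_sums(eta_fix + bq[codes], y, codes, n_pat)
        log_prior = log_norm_const - bq * bq / (2.0 * sigma2)
        log_terms[:, q] = math.log(gw[q]) + z[q] ** 2 + ll + log_prior
    per_patient = logsumexp(log_terms, axis=1) + np.log(sqrt2 * s)
    return float(np.sum(per_patient))


def marginal_loglik(
    params: ModelParams, cohort: pd.DataFrame, n_nodes: int = DEFAULT_N_NODES
) -> float:
    """Marginal log-likelihood of a visit table under ``params``.

    With ``sigma2 == 0`` this collapses exactly to the independent-Bernoulli
    (plain logistic) log-likelihood.
    """
    if n_nodes < 1:
        raise ValidationError(f"n_nodes must be >= 1, got {n_nodes}")
    names = list(params.beta)
    X, y, codes, _ = _build_design(cohort, names, True, params.severity_center)
    w = np.array([params.beta0, *params.beta.values(), params.d])
    n_pat = int(codes.max()) + 1 if len(codes) else 0
    return _agq_loglik(w, params.sigma2, X, y, codes, n_pat, n_nodes)


# ---------------------------------------------------------------------------
# numerical derivatives (central differences)
# ---------------------------------------------------------------------------

def _cd_gradient(f, x, rel_step=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def _cd_hessian(f, x, rel_step=1e-4):
    x = np.asarray(x, dtype=float)
    k = x.size
    hs = np.array([rel_step * max(1.0, abs(xi)) for xi in x])
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = hs[i]
        for j in range(i, k):
            ej = np.zeros(k)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of the random-intercept logistic dose model.

    Coefficient-indexed mappings use the names ``"intercept"``, the covariate
    names, ``"log_dose"`` (when the dose term is included) and ``"sigma2"``.
    ``exp`` of each coefficient CI equals the odds-ratio CI entrywise.
    """

    params: ModelParams
    coefficients: dict
    standard_errors: dict
    ci95: dict
    odds_ratios: dict
    p_values: dict
    sigma2_se: float
    sigma2_ci95: tuple
    loglik: float
    n_patients: int
    n_obs: int
    converged: bool
    n_quad_nodes: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "odds_ratios": {k: list(v) for k, v in self.odds_ratios.items()},
            "p_values": self.p_values,
            "sigma2": self.params.sigma2,
            "sigma2_se": self.sigma2_se,
            "sigma2_ci95": list(self.sigma2_ci95),
            "severity_center": self.params.severity_center,
            "loglik": self.loglik,
            "n_patients": self.n_patients,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_quad_nodes": self.n_quad_nodes,
            "message": self.message,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "FitResult":
        coefs = dict(data["coefficients"])
        beta = {
            k: v for k, v in coefs.items() if k not in (INTERCEPT, LOG_DOSE)
        }
        params = ModelParams(
            beta0=coefs.get(INTERCEPT, 0.0),
            beta=beta,
            d=coefs.get(LOG_DOSE, 0.0),
            sigma2=data["sigma2"],
            severity_center=data.get("severity_center", 0.0),
        )
        return cls(
            params=params,
            coefficients=coefs,
            standard_errors=dict(data.get("standard_errors", {})),
            ci95={k: tuple(v) for k, v in data.get("ci95", {}).items()},
            odds_ratios={k: tuple(v) for k, v in data.get("odds_ratios", {}).items()},
            p_values=dict(data.get("p_values", {})),
            sigma2_se=data.get("sigma2_se", float("nan")),
            sigma2_ci95=tuple(data.get("sigma2_ci95", (float("nan"),) * 2)),
            loglik=data.get("loglik", float("nan")),
            n_patients=data.get("n_patients", 0),
            n_obs=data.get("n_obs", 0),
            converged=data.get("converged", False),
            n_quad_nodes=data.get("n_quad_nodes", DEFAULT_N_NODES),
            message=data.get("message", ""),
        )


def _default_severity_center(cohort: pd.DataFrame) -> float:
    """Mean baseline (first-visit) severity covariate over patients."""
    ordered = cohort.sort_values(["patient_id", "visit_index"])
    firsts = ordered.groupby("patient_id", sort=False).head(1)
    return float(np.mean(np.asarray(firsts[SEVERITY], dtype=float)))


def fit(
    cohort: pd.DataFrame,
    covariate_names: Sequence[str],
    n_nodes: int = DEFAULT_N_NODES,
    include_dose: bool = True,
    severity_center: float | None = None,
) -> FitResult:
    """Fit the random-intercept logistic model by adaptive-GH ML.

    Parameters
    ----------
    cohort
        Visit table with mandatory columns ``patient_id``, ``response``,
        ``dose_mg_per_kg`` (if ``include_dose``) and one column per entry of
        ``covariate_names``.
    covariate_names
        Fixed covariates besides the dose term. ``"severity"`` is centered
        at ``severity_center`` (default: sample mean of first-visit values).
    n_nodes
        Gauss-Hermite nodes for the adaptive quadrature.
    include_dose
        Whether to include the ``d * ln(dose)`` term.

    Non-convergence is reported through ``converged=False`` and ``message``,
    never as a silently wrong answer.
    """
    covariate_names = [c for c in covariate_names if c != LOG_DOSE]
    if severity_center is None:
        if SEVERITY in covariate_names and SEVERITY in cohort.columns:
            severity_center = _default_severity_center(cohort)
        else:
            severity_center = 0.0
    X, y, codes, names = _build_design(cohort, covariate_names, include_dose, severity_center)
    n_pat = int(codes.max()) + 1 if len(codes) else 0
    if n_pat < 2:
        raise ValidationError("fitting requires at least 2 patients")
    k = X.shape[1]

    warm = np.zeros(n_pat)

    def negll(theta):
        sigma2 = math.exp(2.0 * theta[-1])
        return -_agq_loglik(theta[:-1], sigma2, X, y, codes, n_pat, n_nodes, b0=warm)

    ybar = min(max(float(np.mean(y)), 1e-3), 1 - 1e-3)
    theta0 = np.zeros(k + 1)
    theta0[0] = math.log(ybar / (1.0 - ybar))
    bounds = [(None, None)] * k + [(-20.0, 10.0)]
    res = minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        jac="3-point",
        bounds=bounds,
        options={"maxiter": 1000, "maxfun": 100000, "ftol": 1e-12, "gtol": 1e-7},
    )
    theta = res.x
    fval = float(res.fun)
    if not theta[-1] <= bounds[-1][0] + 1e-8:
        # Newton polish with central-difference derivatives: quasi-Newton
        # line searches stall once loglik changes drop below rounding noise,
        # while Newton steps still contract the gradient quadratically
        for _ in range(5):
            grad = _cd_gradient(negll, theta)
            if float(np.max(np.abs(grad))) < 0.5 * GRAD_TOL:
                break
            H = _cd_hessian(negll, theta)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            cand = theta - step
            fcand = negll(cand)
            if not np.isfinite(fcand) or fcand > fval + 1e-8:
                break
            theta, fval = cand, fcand
    grad = _cd_gradient(negll, theta)
    grad_norm = float(np.max(np.abs(grad)))
    at_bound = theta[-1] <= bounds[-1][0] + 1e-8
    # at the lower variance bound (sigma ~ 0) the lnsigma gradient need not vanish
    grad_check = float(np.max(np.abs(grad[:-1]))) if at_bound else grad_norm
    converged = grad_check < GRAD_TOL
    message = res.message if isinstance(res.message, str) else str(res.message)
    if not converged:
        message += f" [gradient inf-norm {grad_norm:.2e} above {GRAD_TOL:g}]"

    H = _cd_hessian(negll, theta)
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k + 1, k + 1), np.nan)
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan
    se = np.sqrt(diag)

    ln_sigma = float(theta[-1])
    sigma2 = math.exp(2.0 * ln_sigma)
    se_ln_sigma = float(se[-1])
    zcrit = float(norm.ppf(0.975))
    sigma2_ci = (
        math.exp(2.0 * (ln_sigma - zcrit * se_ln_sigma)),
        math.exp(2.0 * (ln_sigma + zcrit * se_ln_sigma)),
    )
    sigma2_se = 2.0 * sigma2 * se_ln_sigma

    coefficients, standard_errors, ci95, odds_ratios, p_values = {}, {}, {}, {}, {}
    for idx, name in enumerate(names):
        est = float(theta[idx])
        s = float(se[idx])
        lo, hi = est - zcrit * s, est + zcrit * s
        coefficients[name] = est
        standard_errors[name] = s
        ci95[name] = (lo, hi)
        odds_ratios[name] = (math.exp(est), math.exp(lo), math.exp(hi))
        z = est / s if s > 0 else np.inf * np.sign(est)
        p_values[name] = float(2.0 * norm.sf(abs(z)))

    beta = {nm: coefficients[nm] for nm in names if nm not in (INTERCEPT, LOG_DOSE)}
    params = ModelParams(
        beta0=coefficients[INTERCEPT],
        beta=beta,
        d=coefficients.get(LOG_DOSE, 0.0),
        sigma2=sigma2,
        severity_center=severity_center,
    )
    return FitResult(
        params=params,
        coefficients=coefficients,
        standard_errors=standard_errors,
        ci95=ci95,
        odds_ratios=odds_ratios,
        p_values=p_values,
        sigma2_se=sigma2_se,
        sigma2_ci95=sigma2_ci,
        loglik=-float(fval),
        n_patients=n_pat,
        n_obs=len(y),
        converged=bool(converged),
        n_quad_nodes=n_nodes,
        message=message,
    )



# ---------------------------------------------------------------------------
# univariable -> multivariable screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Outcome of the univariable screen and the multivariable refit."""

    selected: list
    table: pd.DataFrame
    multivariable: FitResult | None


def univariable_screen(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    alpha: float = 0.05,
    n_nodes: int = DEFAULT_N_NODES,
) -> ScreenResult:
    """Screen candidate covariates one at a time, then refit jointly.

    Each candidate is fitted alone in a random-intercept logistic model (the
    candidate ``"log_dose"`` means the dose term alone); candidates with a
    Wald p-value below ``alpha`` are carried into a multivariable
    random-intercept model.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    rows = []
    selected = []
    for cand in candidates:
        is_dose = cand == LOG_DOSE
        r = fit(
            cohort,
            [] if is_dose else [cand],
            n_nodes=n_nodes,
            include_dose=is_dose,
        )
        key = LOG_DOSE if is_dose else cand
        orr, lo, hi = r.odds_ratios[key]
        p = r.p_values[key]
        rows.append(
            {
                "candidate": cand,
                "coefficient": r.coefficients[key],
                "odds_ratio": orr,
                "or_ci_low": lo,
                "or_ci_high": hi,
                "p_value": p,
                "converged": r.converged,
            }
        )
        if p < alpha:
            selected.append(cand)
    multivariable = None
    if selected:
        multivariable = fit(
            cohort,
            [c for c in selected if c != LOG_DOSE],
            n_nodes=n_nodes,
            include_dose=LOG_DOSE in selected,
        )
    return ScreenResult(selected=selected, table=pd.DataFrame(rows), multivariable=multivariable)
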