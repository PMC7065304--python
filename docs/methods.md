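# Methods

## Model

Longitudinal visits of child *i* carry a binary improvement indicator
`Y_ij` (CPRS-R:S total ≤ 40), the administered methylphenidate dose
`D_ij` (mg/kg), months on treatment `t_ij`, and baseline severity `s_i`.
The population model is a generalized linear mixed model with logit link,

    logit P(Y_ij = 1) = β₀ + β_t·t_ij + β_s·(s_i − c) + b_i + d·ln D_ij,
    b_i ~ N(0, σ²) independent across children,

with `c` a severity centering constant stored with every fit (default: the
sample mean of first-visit severity), so that `β₀` is interpretable as the
log-odds of improvement for an average-severity child at treatment start on
1 mg/kg. Responses are conditionally independent given `b_i`. The reference
parameter set shipped as `ADHD_MPH_PARAMS` (β₀ = 1.9377, β_t = 0.0800,
β_s = −0.0512, d = 0.8610, σ² = 1.452, c = 51.3817) is the fitted
multivariable model of the retrospective clinic cohort this package was
designed around; it doubles as the simulation ground truth.

## Marginal likelihood and fitting

Each patient contributes `∫ Π_j Bernoulli(Y_ij | expit(η_ij(b))) φ(b; 0, σ²) db`.
The integral is evaluated by adaptive Gauss–Hermite quadrature: the
integrand's mode `b̂_i` is found by a vectorized, step-halving-safeguarded
Newton iteration (the penalized problem is strictly concave; curvature is
bounded below by 1/σ², so convergence is fast and global), and the standard
Gauss–Hermite rule is recentered at `b̂_i` and rescaled by
`(−∂²/∂b² log posterior)^(−1/2)`. Fifteen nodes are the default: on toy
cohorts the 15-node rule agrees with a 20 000-point trapezoid integration
to ~1e−8 and the error keeps falling through 25 nodes. With σ² = 0 the
code returns the plain Bernoulli log-likelihood exactly rather than
quadrature's limit of it.

Maximization is over `(β₀, β, d, ln σ)`; optimizing `ln σ` keeps the
variance positive without an active constraint (a floor at `ln σ = −20`
catches the boundary case σ² → 0). The optimizer is L-BFGS-B with
three-point finite-difference gradients, followed by a short Newton polish
using central-difference gradients and Hessians: quasi-Newton line searches
stall once log-likelihood *changes* sink below floating-point noise, while
Newton steps still contract the gradient quadratically. A fit is declared
converged when the gradient infinity-norm is below 1e−5 (excluding the
`ln σ` component when it sits at the floor). Posterior modes are
warm-started across likelihood evaluations; this only changes the starting
point of an iteration run to a 1e−12 gradient tolerance, so the likelihood
remains a well-defined function of the parameters.

Standard errors come from the pseudo-inverse of the central-difference
Hessian of the negative log-likelihood; confidence intervals and p-values
are Wald; odds-ratio intervals are the exponentials of the coefficient
intervals. The variance CI is Wald on the `ln σ²` scale, which is the
standard transformation-based interval; the asymmetric variance interval
reported for the original cohort was produced by an unstated method, so
exact reproduction of its shape is out of scope. The univariable screen
refits one candidate at a time under the same random-intercept structure
and forwards candidates with p < α (default 0.05) to a joint fit.

Cross-validation of the fitter: on a common synthetic cohort,
`lme4::glmer` with `nAGQ = 25` agrees with this implementation to ~1e−5 in
every coefficient, the variance, and the log-likelihood (test suite,
`TestAgainstLme4`); the σ² = 0 limit agrees with an ordinary logistic
regression.

## Empirical-Bayes prediction

A patient's accumulated visits give a posterior over their `b`. The
default predictor is the posterior mode (safeguarded scalar Newton from 0,
gradient tolerance 1e−10, ≤ 100 iterations), matching the behavior of the
mixed-model software family the procedure mirrors; a Gauss–Hermite
posterior mean (`method="gh_mean"`) is provided because "adaptive
Gauss–Hermite prediction" is ambiguous between the two. On worked-example
histories the two agree within 0.03. A patient with no history gets
`b̂ = 0` exactly. The prediction shrinks toward 0 relative to the
per-patient MLE, increasingly so for short histories.

## Dose recommendation

`logit(p₀)` is taken from the fit (90th percentile, linear interpolation
between order statistics, of last-visit fitted probabilities evaluated at
each patient's own `b̂`) or supplied explicitly. The dose solving
`η(D) = logit(p₀)` is `exp{[logit(p₀) − η(1 mg/kg)]/d}`; the identity
`expit(η(D_rec)) = p₀` holds to machine precision and is enforced by test.

Two documented quirks of the reference analysis are surfaced rather than
hidden:

- **Severity convention.** The published follow-up formula names *baseline*
  severity, but the published worked-example doses are arithmetically
  consistent only with the *current* visit's score. `severity_mode`
  defaults to `"current"`; `"baseline"` is one flag away, and every
  recommendation records which was used.
- **Target magnitude.** The published `p₀ = 0.9866` (logit 4.2990) implies
  ~15.5 mg/kg for an average patient at treatment start — two orders of
  magnitude above pediatric practice — while the worked examples imply
  `logit(p₀) ≈ 0.622`. The default pipeline computes `p₀` from the fit;
  replication passes the explicit logit. Because the raw inversion is an
  unbounded exponential, recommendations are clipped to a configurable
  [0.01, 2.0] mg/kg safety range, with the pre-clip value retained and a
  `clipped` flag set.

Sequential recommendation replays a visit stream: visit 1 uses `b̂ = 0`;
visit *n* re-predicts `b̂` from all earlier visits, taking the administered
dose to be the recorded one when present and the previous recommendation
otherwise. Explicit `b̂` overrides allow replaying published examples
exactly; with the published coefficient set, the printed example doses are
reproduced within 0.2% (one printed first-visit dose, 0.6023 mg/kg, is
inconsistent with every other row under any common target and is treated
as an upstream typo).

## Synthetic cohort generator

The generator emulates the reference cohort's design: 221 children;
baseline severity ~ N(51.38, 10.82²) truncated to scores 41–81; number of
follow-ups 1 + Poisson(3.94) (mean 4.94 visits); visit gaps uniform on
[1, 2·22.42/4.94] months, cumulated, so the mean treatment span matches
~22.4 months; responses drawn from the model above with the reference
parameters as truth. Doses are the one design quantity with no published
analogue (administered doses were never reported): the default policy
holds each child's dose constant, drawn log-uniformly from 0.1–1.5 mg/kg,
a range bracketing the published recommendations and the pediatric
literature; random-walk and naive-titration policies exist for sensitivity
work. Demographic covariates (sex, age, birth weight, weight, co-medication
and comorbidity flags) are drawn marginally at published cohort rates and
carry no effect on the response unless the generating parameter set says
so — which is what makes them usable as null covariates in screening
calibration.

Per-patient RNG substreams are keyed by `(seed, patient index)`, so output
is bit-reproducible and insensitive to patient order. The visit-level
severity score is synthesized for display consistency only (uniform 20–40
if improved, 41–70 if not); the generating model uses the binary outcome
and the baseline score.

What the generator does **not** emulate: dose-outcome feedback in
historical prescribing (doses are exogenous under the default policy),
severity trajectories within patients, missing visits, measurement error
in the CPRS score, and informative dropout. Passing recovery tests
therefore demonstrates correctness of the estimator under the stated
sampling design, not robustness to those real-data features.

## Problem sizes and tolerances

Parameter-recovery checks use 20 replicates of the full 221-patient
design and require mean estimates of the log-dose coefficient, time
coefficient and random-intercept variance within 2 Monte-Carlo standard
errors of truth (each replicate fits in well under a second). Screening
calibration uses 200 replicates at 100 patients and checks the null
selection rate against the 95% binomial band around α = 0.05. Quadrature
accuracy is asserted at 1e−8 against dense trapezoid integration;
inversion identities at 1e−12; analytic constants at the published print
precision (4 decimals).

## Known limitations

- Only random intercepts: no random slopes in time or dose.
- Wald inference throughout; no profile or bootstrap intervals.
- The screen is the reference p < 0.05 procedure, not a model-selection
  recommendation.
- Dose recommendations are purely statistical: no pharmacokinetics,
  adverse-event constraints, or formulation rounding.
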