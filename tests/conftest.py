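import math

import numpy as np
import pandas as pd
import pytest

import mphdose as m

#: printed rows of the worked hypothetical-patient examples:
#: (patient, current CPRS score, months on treatment, b_hat, published dose)
WORKED_EXAMPLES = [
    ("p1", 45, 1, -0.1647, 0.1638),
    ("p1", 42, 2, -0.1651, 0.1247),
    ("p1", 39, 4, -0.1690, 0.0871),
    ("p2", 67, 1, -0.1497, 0.6023),  # not reproducible; probable typo upstream
    ("p2", 65, 2, -0.1449, 0.4781),
    ("p2", 39, 5, -0.1456, 0.0773),
    ("p2", 30, 6, -0.1439, 0.0412),
]


@pytest.fixture(scope="session")
def ref_params():
    """Reference multivariable model estimates (also simulation truth)."""
    return m.ADHD_MPH_PARAMS


def make_toy_cohort():
    """Three patients, two visits each, hand-written values."""
    data = [
        ("A", [(0, 55, 0.3, 0), (2, 55, 0.4, 1)]),
        ("B", [(0, 48, 0.8, 1), (3, 48, 0.8, 1)]),
        ("C", [(0, 62, 0.15, 0), (4, 62, 0.2, 0)]),
    ]
    rows = []
    for pid, visits in data:
        for j, (t, sev, dose, y) in enumerate(visits):
            rows.append(
                dict(
                    patient_id=pid,
                    visit_index=j,
                    time_months=t,
                    severity_score=35 if y else 41,
                    dose_mg_per_kg=dose,
                    response=y,
                    severity=sev,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def toy_cohort():
    return make_toy_cohort()


def brute_force_loglik(params, cohort, n_grid=20000, half_width_sd=10.0):
    """Trapezoid-rule marginal log-likelihood, independent of the GH path."""
    sig = math.sqrt(params.sigma2)
    bs = np.linspace(-half_width_sd * sig, half_width_sd * sig, n_grid)
    phi = np.exp(-bs**2 / (2 * params.sigma2)) / math.sqrt(2 * math.pi * params.sigma2)
    total = 0.0
    for _, g in cohort.groupby("patient_id"):
        lik = np.ones_like(bs)
        for r in g.itertuples():
            eta = (
                m.linear_predictor(
                    params,
                    {"time_months": r.time_months, "severity": r.severity},
                    r.dose_mg_per_kg,
                    0.0,
                )
                + bs
            )
            p = 1.0 / (1.0 + np.exp(-eta))
            lik *= p if r.response == 1 else 1.0 - p
        total += math.log(np.trapezoid(lik * phi, bs))
    return total


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort reused by several slow tests."""
    visits, baselines = m.generate_cohort(m.CohortConfig(n_patients=60, seed=42))
    return visits, baselines
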