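import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, truncnorm

import mphdose as m
from mphdose.errors import ValidationError


class TestDichotomize:
    @pytest.mark.parametrize(
        "score,expected", [(40, 1), (41, 0), (0, 1), (81, 0), (20, 1), (70, 0)]
    )
    def test_cutoff(self, score, expected):
        assert m.dichotomize(score) == expected

    @pytest.mark.parametrize("score", [-1, 82, 1000])
    def test_out_of_range(self, score):
        with pytest.raises(ValidationError):
            m.dichotomize(score)

    @given(st.integers(0, 80))
    @settings(deadline=None)
    def test_step_function(self, score):
        """Monotone non-increasing with its unique jump between 40 and 41."""
        assert m.dichotomize(score) >= m.dichotomize(score + 1)
        if m.dichotomize(score) != m.dichotomize(score + 1):
            assert score == 40


class TestEligibility:
    @staticmethod
    def _tables():
        visits = pd.DataFrame(
            {
                "patient_id": ["a", "a", "b", "b", "c"],
                "visit_index": [0, 1, 0, 1, 0],
                "time_months": [0.0, 3.0, 0.0, 2.0, 0.0],
                "severity_score": [50, 38, 55, 44, 60],
                "dose_mg_per_kg": [0.3] * 5,
                "response": [0, 1, 0, 0, 0],
            }
        )
        baselines = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "baseline_severity": [50, 38, 60],
                "age_months": [30, 80, 90],
                "sex": [1, 0, 1],
                "birth_weight_kg": [3.1, 2.9, 3.4],
            }
        )
        return visits, baselines

    def test_each_rule_excludes(self):
        """One patient per violated rule: too young, not meeting criteria, no follow-up."""
        visits, baselines = self._tables()
        vf, bf, report = m.apply_eligibility(visits, baselines)
        assert len(bf) == 0 and len(vf) == 0
        assert report == {"age": 1, "baseline_severity": 1, "no_follow_up": 1, "retained": 0}

    def test_retains_eligible(self):
        visits, baselines = self._tables()
        baselines.loc[0, "age_months"] = 48  # patient 'a' now eligible
        vf, bf, report = m.apply_eligibility(visits, baselines)
        assert list(bf["patient_id"]) == ["a"]
        assert report["retained"] == 1 and report["age"] == 0

    def test_unknown_patient_errors(self):
        visits, baselines = self._tables()
        visits.loc[0, "patient_id"] = "ghost"
        with pytest.raises(ValidationError, match="ghost"):
            m.apply_eligibility(visits, baselines)


class TestGenerator:
    def test_minimal_structure(self):
        """One patient, one follow-up: exactly two rows, time 0 then > 0."""
        visits, baselines = m.generate_cohort(
            m.CohortConfig(n_patients=1, followups_mean=1.0, seed=3)
        )
        assert len(visits) == 2
        assert visits["time_months"].iloc[0] == 0.0
        assert visits["time_months"].iloc[1] > 0.0
        assert len(baselines) == 1
        assert (baselines["baseline_severity"] > 40).all()

    def test_seed_reproducibility(self):
        cfg = m.CohortConfig(n_patients=12, seed=5)
        v1, b1 = m.generate_cohort(cfg)
        v2, b2 = m.generate_cohort(cfg)
        pd.testing.assert_frame_equal(v1, v2)
        pd.testing.assert_frame_equal(b1, b2)
        v3, _ = m.generate_cohort(m.CohortConfig(n_patients=12, seed=6))
        assert not v1.equals(v3)

    def test_invalid_configs(self):
        with pytest.raises(ValidationError):
            m.CohortConfig(n_patients=0)
        with pytest.raises(ValidationError):
            m.CohortConfig(dose_range_mg_per_kg=(0.0, 1.0))
        with pytest.raises(ValidationError):
            m.CohortConfig(dose_policy="homeopathic")

    def test_sigma0_marginal_rate(self):
        """With no random effect, no covariates and d=0 the improvement
        fraction is a plain Bernoulli rate at inv_logit(beta0)."""
        params = m.ModelParams(beta0=0.5, beta={}, d=0.0, sigma2=0.0)
        visits, _ = m.generate_cohort(
            m.CohortConfig(n_patients=400, true_params=params, seed=11)
        )
        rate = visits["response"].mean()
        expected = m.inv_logit(0.5)
        se = math.sqrt(expected * (1 - expected) / len(visits))
        assert abs(rate - expected) < 4 * se

    def test_sigma0_within_patient_homogeneity(self):
        """sigma2=0 makes responses exchangeable across patients: a
        patient-by-response contingency table shows no heterogeneity."""
        params = m.ModelParams(beta0=0.3, beta={}, d=0.0, sigma2=0.0)
        visits, _ = m.generate_cohort(
            m.CohortConfig(n_patients=200, true_params=params, followups_mean=6.0, seed=13)
        )
        table = pd.crosstab(visits["patient_id"], visits["response"])
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_patient_level_logit_variance_matches_sigma2(self):
        """Long follow-up, intercept-only model: the variance of per-patient
        empirical logits recovers the random-intercept variance."""
        sigma2 = 1.452
        params = m.ModelParams(beta0=0.0, beta={}, d=0.0, sigma2=sigma2)
        n_patients, n_seeds = 300, 5

        def logit_variance(pbar, sizes):
            pbar = np.clip(pbar, 1.0 / sizes, 1.0 - 1.0 / sizes)
            return np.var(np.log(pbar / (1.0 - pbar)), ddof=1)

        observed, size_sets = [], []
        for seed in range(n_seeds):
            visits, _ = m.generate_cohort(
                m.CohortConfig(n_patients=n_patients, true_params=params,
                               followups_mean=150.0, period_months_mean=450.0, seed=seed)
            )
            g = visits.groupby("patient_id")["response"].agg(["mean", "size"])
            sizes = g["size"].to_numpy()
            observed.append(logit_variance(g["mean"].to_numpy(), sizes))
            size_sets.append(sizes)
        # Monte-Carlo oracle: same statistic under b ~ N(0, sigma2) with
        # conditionally binomial counts, built directly from numpy draws
        rng = np.random.default_rng(99)
        replicated = []
        for _ in range(200):
            stats = []
            for sizes in size_sets:
                b = rng.normal(0.0, math.sqrt(sigma2), size=len(sizes))
                p = 1.0 / (1.0 + np.exp(-b))
                stats.append(logit_variance(rng.binomial(sizes, p) / sizes, sizes))
            replicated.append(np.mean(stats))
        lo, hi = np.quantile(replicated, [0.005, 0.995])
        assert lo <= np.mean(observed) <= hi
        assert abs(np.median(replicated) - sigma2) < 0.5  # statistic tracks sigma2

    def test_baseline_severity_mean(self):
        """Configured far from the truncation boundary, the generated mean
        matches within one standard error of the mean."""
        cfg = dict(n_patients=221, baseline_severity_mean=60.0, baseline_severity_sd=5.0)
        means = [
            m.generate_cohort(m.CohortConfig(seed=s, **cfg))[1]["baseline_severity"].mean()
            for s in range(10)
        ]
        assert abs(np.mean(means) - 60.0) < 5.0 / math.sqrt(221)

    def test_truncated_severity_support(self):
        _, baselines = m.generate_cohort(m.CohortConfig(n_patients=100, seed=19))
        assert baselines["baseline_severity"].between(41, 81).all()

    def test_response_consistent_with_score(self):
        visits, _ = m.generate_cohort(m.CohortConfig(n_patients=50, seed=23))
        assert (
            (visits["severity_score"] <= 40).astype(int) == visits["response"]
        ).all()
        assert (visits["dose_mg_per_kg"] > 0).all()


class TestRecords:
    def test_visit_record_validation(self):
        rec = m.VisitRecord("p", 1, 2.0, 35, 0.3, 1)
        assert rec.response == 1
        with pytest.raises(ValidationError, match="p"):
            m.VisitRecord("p", 1, 2.0, 35, 0.3, 0)  # response contradicts score
        with pytest.raises(ValidationError):
            m.VisitRecord("p", 0, 1.0, 35, 0.3, 1)  # nonzero time at baseline
        with pytest.raises(ValidationError):
            m.VisitRecord("p", 1, 2.0, 35, -0.3, 1)

    def test_baseline_record_validation(self):
        m.PatientBaseline("p", 55, 80.0, 1, 3.2)
        with pytest.raises(ValidationError):
            m.PatientBaseline("p", 40, 80.0, 1, 3.2)
        with pytest.raises(ValidationError):
            m.PatientBaseline("p", 55, 30.0, 1, 3.2)


class TestCsvIO:
    def test_roundtrip(self, tmp_path):
        visits, _ = m.generate_cohort(m.CohortConfig(n_patients=3, seed=2))
        path = tmp_path / "visits.csv"
        m.write_cohort_csv(visits, path, header_comment="roundtrip test")
        back = m.read_cohort_csv(path)
        pd.testing.assert_frame_equal(back, visits.reset_index(drop=True), check_exact=False, rtol=1e-12)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,visit_index,time_months,severity_score,response\np,0,0,50,0\n")
        with pytest.raises(ValidationError, match="dose_mg_per_kg"):
            m.read_cohort_csv(path)

    def test_non_numeric_cell_locates_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,visit_index,time_months,severity_score,dose_mg_per_kg,response\n"
            "p,0,0,50,0.3,0\n"
            "p,1,2,oops,0.3,0\n"
        )
        with pytest.raises(ValidationError, match="severity_score.*line 3"):
            m.read_cohort_csv(path)

    def test_worked_example_history_dichotomizes(self, tmp_path):
        """A four-visit history with scores 67, 65, 39, 30 reads back with
        responses 0, 0, 1, 1."""
        scores = [67, 65, 39, 30]
        lines = ["patient_id,visit_index,time_months,severity_score,dose_mg_per_kg,response"]
        for j, (s, t) in enumerate(zip(scores, [0, 1, 5, 6])):
            lines.append(f"hx,{j},{t},{s},0.3,{m.dichotomize(s)}")
        path = tmp_path / "hx.csv"
        path.write_text("\n".join(lines) + "\n")
        df = m.read_cohort_csv(path)
        assert list(df["response"]) == [0, 0, 1, 1]

    def test_inconsistent_response_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,visit_index,time_months,severity_score,dose_mg_per_kg,response\n"
            "p,0,0,50,0.3,1\n"
        )
        with pytest.raises(ValidationError, match="inconsistent"):
            m.read_cohort_csv(path)
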