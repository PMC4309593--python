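"""Logistic ORs, Kaplan-Meier/log-rank, Cox HRs, prevalent/incident split."""

import numpy as np
import pandas as pd
import pytest

from founderhap.assoc import (
    cox_hr,
    cox_score_statistic,
    km_logrank,
    logistic_assoc,
    prevalent_incident_split,
)
from founderhap.synthio import PhenoSpec, PhenotypeSpec, simulate_phenotypes


class TestLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        # 2x2 table: exposed 30 cases / 70 controls, unexposed 55 / 445
        dosage = np.array([1.0] * 100 + [0.0] * 500)
        case = np.array([1] * 30 + [0] * 70 + [1] * 55 + [0] * 445)
        est = logistic_assoc(dosage, case)
        expect = (30 * 445) / (70 * 55)
        assert est.w == pytest.approx(expect, abs=1e-8)

    def test_one_sided_p_orientation(self):
        dosage = np.array([1.0] * 100 + [0.0] * 500)
        case = np.array([1] * 30 + [0] * 70 + [1] * 55 + [0] * 445)
        est = logistic_assoc(dosage, case)
        assert est.p_one_sided < 0.5  # risk-increasing direction

    def test_all_controls_errors(self):
        with pytest.raises(ValueError):
            logistic_assoc(np.array([0.0, 1.0]), np.array([0, 0]))

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        n, reps, alpha = 2500, 400, 0.05
        hits = 0
        for rep in range(reps):
            dosage = (rng.random(n) < 0.05).astype(float)
            case = (rng.random(n) < 0.15).astype(int)
            if case.min() == case.max():
                continue
            est = logistic_assoc(dosage, case)
            hits += est.p_one_sided < alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(hits / reps - alpha) < 2.576 * se + 1e-9

    def test_covariate_rescaling_leaves_dosage_effect(self):
        rng = np.random.default_rng(2)
        n = 4000
        dosage = (rng.random(n) < 0.1).astype(float)
        age = rng.normal(60, 8, n)
        lin = -2 + 0.6 * dosage + 0.02 * (age - 60)
        case = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        a = logistic_assoc(dosage, case, pd.DataFrame({"age": age}))
        b = logistic_assoc(dosage, case, pd.DataFrame({"age": (age - 60) / 8}))
        assert a.beta == pytest.approx(b.beta, abs=1e-6)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        ages = np.array([2.0, 3.0, 3.0, 5.0, 8.0])
        events = np.array([1, 1, 0, 1, 0])
        curves, chi2, p = km_logrank(ages, events, np.zeros(5, dtype=int))
        assert chi2 is None and p is None
        c = curves["0"]
        # S(2) = 4/5; S(3) = 4/5 * 3/4 = 3/5; S(5) = 3/5 * 1/2 = 3/10
        by_age = dict(zip(c.age, 1.0 - c.risk))
        assert by_age[2.0] == pytest.approx(4 / 5)
        assert by_age[3.0] == pytest.approx(3 / 5)
        assert by_age[5.0] == pytest.approx(3 / 10)

    def test_identical_groups_logrank_null(self):
        ages = np.tile(np.array([2.0, 3.0, 5.0, 7.0, 11.0]), 2)
        events = np.tile(np.array([1, 0, 1, 1, 0]), 2)
        group = np.repeat([0, 1], 5)
        _, chi2, p = km_logrank(ages, events, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_censoring_reduces_to_empirical_cdf(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(40, 90, 200)
        events = np.ones(200, dtype=int)
        curves, _, _ = km_logrank(ages, events, np.zeros(200, dtype=int))
        assert curves["0"].risk[-1] == pytest.approx(1.0)
        mid = np.searchsorted(curves["0"].age, 65.0)
        assert curves["0"].risk[mid] == pytest.approx((ages <= curves["0"].age[mid]).mean())

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            km_logrank(np.array([1.0, 2.0]), np.array([0, 0]), np.array([0, 1]))


class TestCox:
    def test_score_statistic_equals_logrank_without_ties(self):
        rng = np.random.default_rng(11)
        n = 300
        group = (rng.random(n) < 0.3).astype(int)
        onset = rng.exponential(30, n) / np.exp(0.5 * group)
        censor = rng.uniform(10, 60, n)
        ages = np.minimum(onset, censor) + rng.uniform(0, 1e-6, n)  # break ties
        events = (onset <= censor).astype(int)
        _, chi2, _ = km_logrank(ages, events, group)
        score = cox_score_statistic(ages, events, group)
        assert score == pytest.approx(chi2, rel=1e-6)

    def test_hr_agrees_with_independent_implementation(self):
        import statsmodels.duration.hazard_regression as hz

        rng = np.random.default_rng(4)
        n = 2000
        dosage = (rng.random(n) < 0.1).astype(float)
        onset = rng.exponential(40, n) / np.exp(np.log(2.0) * dosage)
        censor = rng.uniform(10, 80, n)
        ages = np.minimum(onset, censor)
        events = (onset <= censor).astype(int)
        est = cox_hr(ages, events, dosage)
        ph = hz.PHReg(ages, dosage[:, None], status=events, ties="efron").fit()
        assert est.beta == pytest.approx(float(ph.params[0]), abs=1e-4)

    def test_null_hr_ci_coverage(self):
        rng = np.random.default_rng(6)
        cover, reps = 0, 60
        for rep in range(reps):
            n = 1500
            dosage = (rng.random(n) < 0.1).astype(float)
            onset = rng.exponential(40, n)
            censor = rng.uniform(10, 80, n)
            ages = np.minimum(onset, censor)
            events = (onset <= censor).astype(int)
            est = cox_hr(ages, events, dosage)
            cover += est.ci_low <= 1.0 <= est.ci_high
        assert cover / reps >= 0.90


class TestPrevalentIncidentSplit:
    def _table(self, ages, events, survey):
        return pd.DataFrame({"age": ages, "event": events, "survey_age": survey})

    def test_no_events_before_survey(self):
        tbl = self._table([70.0, 75.0], [1, 0], [60.0, 60.0])
        prev, inc = prevalent_incident_split(tbl, "age", "event")
        assert len(inc) == 2
        assert prev["event"].sum() == 0

    def test_all_events_before_survey(self):
        tbl = self._table([50.0, 55.0], [1, 1], [60.0, 60.0])
        prev, inc = prevalent_incident_split(tbl, "age", "event")
        assert prev["event"].sum() == 2
        assert inc["event"].sum() == 0

    def test_no_survivor_bias_gives_compatible_hazard_ratios(self):
        reps, agree = 30, 0
        for rep in range(reps):
            ph = simulate_phenotypes(
                (np.random.default_rng(rep).random(12_000) < 0.3).astype(float),
                None,
                PhenoSpec([PhenotypeSpec("pc", "survival", hazard_ratio=2.0,
                                         shape=4.0, scale=100.0,
                                         censor_mean=80, censor_sd=6)],
                          survey_age_range=(60.0, 70.0), seed=900 + rep),
            )
            prev, inc = prevalent_incident_split(ph, "pc_age", "pc_event")
            if prev["pc_event"].sum() < 20 or inc["pc_event"].sum() < 20:
                continue
            a = cox_hr(prev["pc_age"], prev["pc_event"], prev["dosage"])
            b = cox_hr(inc["pc_age"], inc["pc_event"], inc["dosage"])
            joint_se = np.hypot(a.se_beta, b.se_beta)
            agree += abs(a.beta - b.beta) <= 1.96 * joint_se
        assert agree / reps >= 0.90
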