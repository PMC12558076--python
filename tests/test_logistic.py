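import math

import numpy as np
import pandas as pd
import pytest

from lesionkinetics.cohort import (
    location_distribution,
    logistic_progression,
    symptom_onset_rate,
)
from lesionkinetics.volumetry import ValidationError
from tests.conftest import make_table2_cohort


class TestLogisticProgression:
    def test_listwise_deletion_count(self, table2_cohort):
        patients, growth = table2_cohort
        fit = logistic_progression(patients, growth)
        assert fit.n_used == 42
        assert fit.n_excluded == {"missing covariate": 2}
        assert fit.n_used + fit.n_excluded_total == len(patients)

    def test_terms_and_reference_levels(self, table2_cohort):
        patients, growth = table2_cohort
        fit = logistic_progression(patients, growth)
        assert set(fit.terms) == {
            "const",
            "age",
            "sex_female",
            "u5hiaa",
            "ki67",
            "grade_2",
            "grade_3",
        }
        for term in fit.terms:
            if fit.identifiable[term]:
                assert 0 < fit.ci_low[term] <= fit.odds_ratios[term] <= fit.ci_high[term]

    def test_separated_level_reported_not_crashed(self, table2_cohort):
        # the lone grade-3 patient never progressed: quasi-complete separation
        patients, growth = table2_cohort
        fit = logistic_progression(patients, growth)
        assert fit.identifiable["grade_3"] is False
        assert fit.ci_low["grade_3"] == 0.0
        assert math.isinf(fit.ci_high["grade_3"])
        assert fit.odds_ratios["grade_3"] == 0.0

    def test_constant_outcome_flagged_non_identifiable(self, table2_cohort):
        patients, growth = table2_cohort
        growth = growth.assign(progressed=0)
        fit = logistic_progression(patients, growth)
        assert fit.converged is False
        assert not any(fit.identifiable.values())

    def test_missing_growth_estimate_counted(self, table2_cohort):
        patients, growth = table2_cohort
        fit = logistic_progression(patients, growth.iloc[3:])
        assert fit.n_excluded["no growth estimate"] == 3
        assert fit.n_used + fit.n_excluded_total == len(patients)

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(42)
        n = 2000
        patients = pd.DataFrame(
            {
                "patient_id": [str(i) for i in range(n)],
                "age": rng.normal(70, 8, n),
                "sex": rng.choice(["female", "male"], n),
                "u5hiaa": rng.lognormal(5, 1, n),
                "ki67": rng.uniform(1, 20, n),
                "grade": rng.choice([1, 2], n),
            }
        )
        growth = pd.DataFrame(
            {"patient_id": patients["patient_id"], "progressed": rng.integers(0, 2, n)}
        )
        fit = logistic_progression(patients, growth)
        for term in ("age", "sex_female", "ki67", "grade_2"):
            assert fit.ci_low[term] < 1.0 < fit.ci_high[term]

    def test_recovers_generative_odds_ratios(self):
        # true model: logit p = -0.3 + 0.8*x1 - 0.5*x2; Wald 95% CIs should
        # cover the generative odds ratios in at least 90% of replicates
        coverage = []
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            n = 2000
            x1 = rng.normal(0, 1, n)
            x2 = rng.integers(0, 2, n)
            logits = -0.3 + 0.8 * x1 - 0.5 * x2
            y = rng.random(n) < 1 / (1 + np.exp(-logits))
            patients = pd.DataFrame(
                {
                    "patient_id": [str(i) for i in range(n)],
                    "age": x1,
                    "sex": np.where(x2 == 1, "female", "male"),
                }
            )
            growth = pd.DataFrame(
                {"patient_id": patients["patient_id"], "progressed": y.astype(int)}
            )
            fit = logistic_progression(patients, growth, covariates=("age", "sex"))
            for truth, term in ((math.exp(0.8), "age"), (math.exp(-0.5), "sex_female")):
                coverage.append(fit.ci_low[term] <= truth <= fit.ci_high[term])
        assert np.mean(coverage) >= 0.90


class TestLocationDistribution:
    def test_reference_counts(self):
        levels = (
            ["I"] * 13 + ["II"] * 12 + ["III_down"] * 16 + ["III_up"] * 2 + ["IV"]
        )
        patients = pd.DataFrame(
            {
                "patient_id": [str(i) for i in range(44)],
                "symptomatic_at_dx": 0,
                "mlnm_level": levels,
            }
        )
        table = location_distribution(patients)
        assert table["asymptomatic_n"].sum() == 44
        row = table.set_index("mlnm_level").loc["III_down"]
        assert row["asymptomatic_n"] == 16
        assert row["asymptomatic_pct"] == 36

    def test_counts_conserved_by_group(self):
        rng = np.random.default_rng(5)
        patients = pd.DataFrame(
            {
                "patient_id": [str(i) for i in range(30)],
                "symptomatic_at_dx": rng.integers(0, 2, 30),
                "mlnm_level": rng.choice(["I", "II", "III_down", "III_up", "IV"], 30),
            }
        )
        table = location_distribution(patients)
        n_sym = int(patients["symptomatic_at_dx"].sum())
        assert table["symptomatic_n"].sum() == n_sym
        assert table["asymptomatic_n"].sum() == 30 - n_sym

    def test_empty_group_blank_percentages(self):
        patients = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "symptomatic_at_dx": 0,
                "mlnm_level": ["I", "II"],
            }
        )
        table = location_distribution(patients)
        assert table["symptomatic_n"].sum() == 0
        assert table["symptomatic_pct"].isna().all()

    def test_unknown_level_rejected(self):
        patients = pd.DataFrame(
            {
                "patient_id": ["a"],
                "symptomatic_at_dx": 0,
                "mlnm_level": ["V"],
            }
        )
        with pytest.raises(ValidationError, match="V"):
            location_distribution(patients)


class TestSymptomOnsetRate:
    @staticmethod
    def _cohort(n, events, symptomatic=0):
        return pd.DataFrame(
            {
                "patient_id": [str(i) for i in range(n)],
                "symptomatic_at_dx": symptomatic,
                "symptom_surgery_event": [1] * events + [0] * (n - events),
            }
        )

    def test_reference_nine_percent(self):
        assert symptom_onset_rate(self._cohort(44, 4)) == (4, 44, 9)

    def test_zero_events(self):
        assert symptom_onset_rate(self._cohort(10, 0)) == (0, 10, 0)

    def test_all_events(self):
        assert symptom_onset_rate(self._cohort(7, 7)) == (7, 7, 100)

    def test_symptomatic_patients_excluded(self):
        cohort = pd.concat(
            [self._cohort(10, 1), self._cohort(5, 5, symptomatic=1)],
            ignore_index=True,
        )
        assert symptom_onset_rate(cohort) == (1, 10, 10)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            symptom_onset_rate(self._cohort(3, 0, symptomatic=1))
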