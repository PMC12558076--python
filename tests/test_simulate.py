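import math

import numpy as np
import pandas as pd
import pytest

from lesionkinetics.simulate import (
    SimulationConfig,
    _pipeline_tgr,
    generate_cohort,
    load_config,
    recovery_report,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert cfg.n_asymptomatic == 44
        assert math.isclose(sum(cfg.location_probs.values()), 1.0)

    def test_rejects_bad_location_probs(self):
        with pytest.raises(ValueError):
            SimulationConfig(location_probs={"I": 0.5, "II": 0.5})
        with pytest.raises(ValueError):
            SimulationConfig(
                location_probs={"I": 0.9, "II": 0.2, "III_down": 0.0, "III_up": 0.0, "IV": -0.1}
            )

    def test_rejects_negative_counts_and_sds(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_asymptomatic=0)
        with pytest.raises(ValueError):
            SimulationConfig(growth_sd=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(prrt_fraction=1.5)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=123)
        l1, p1 = generate_cohort(cfg)
        l2, p2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(l1, l2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_seed_changes_output(self):
        l1, _ = generate_cohort(SimulationConfig(seed=1))
        l2, _ = generate_cohort(SimulationConfig(seed=2))
        assert not l1.equals(l2)

    def test_group_sizes(self):
        _, patients = generate_cohort(SimulationConfig(seed=4, n_asymptomatic=44, n_symptomatic=10))
        assert (patients["symptomatic_at_dx"] == 0).sum() == 44
        assert (patients["symptomatic_at_dx"] == 1).sum() == 10

    def test_two_scans_per_patient(self):
        lesions, patients = generate_cohort(SimulationConfig(seed=4))
        counts = lesions.groupby("patient_id").size()
        assert (counts == 2).all()
        assert set(lesions["patient_id"]) == set(patients["patient_id"])

    def test_noise_free_degenerate_growth_gives_exact_tgr(self):
        cfg = SimulationConfig(
            seed=9,
            diameter_noise_sd=0.0,
            growth_mean=math.log(1.02),
            growth_sd=0.0,
            prrt_fraction=0.0,
        )
        lesions, _ = generate_cohort(cfg)
        tgr = _pipeline_tgr(lesions)
        assert np.allclose(tgr.to_numpy(), 2.0, atol=1e-9)

    def test_missingness_rates_applied(self):
        cfg = SimulationConfig(
            seed=3, n_asymptomatic=500, missing_5hiaa_rate=0.2, missing_ki67_rate=0.1
        )
        _, patients = generate_cohort(cfg)
        frac_5hiaa = patients["u5hiaa"].isna().mean()
        frac_ki67 = patients["ki67"].isna().mean()
        assert 0.12 < frac_5hiaa < 0.28
        assert 0.05 < frac_ki67 < 0.16
        # grade missing exactly where ki67 is missing
        assert patients["grade"].isna().equals(patients["ki67"].isna())

    def test_location_frequencies_near_config(self):
        cfg = SimulationConfig(seed=6, n_asymptomatic=2000, n_symptomatic=1)
        _, patients = generate_cohort(cfg)
        freqs = patients["mlnm_level"].value_counts(normalize=True)
        for level, p in cfg.location_probs.items():
            assert freqs.get(level, 0.0) == pytest.approx(p, abs=0.04)

    def test_median_interval_near_config(self):
        cfg = SimulationConfig(seed=8, n_asymptomatic=3000, n_symptomatic=1)
        lesions, _ = generate_cohort(cfg)
        dates = pd.to_datetime(lesions["scan_date"])
        spans = dates.groupby(lesions["patient_id"]).agg(lambda s: (s.max() - s.min()).days)
        median_months = spans.median() / 30.4375
        assert median_months == pytest.approx(29.0, rel=0.1)

    def test_event_rate_calibration(self):
        # with degenerate growth and no death censoring, the ten-year symptom
        # fraction converges to 1 - exp(-120 * lambda_effective)
        cfg = SimulationConfig(
            seed=13,
            n_asymptomatic=10_000,
            n_symptomatic=0,
            growth_sd=0.0,
            prrt_fraction=0.0,
            death_hazard=0.0,
        )
        _, patients = generate_cohort(cfg)
        lam = cfg.symptom_hazard_base * math.exp(
            cfg.symptom_hazard_growth_coef * cfg.growth_mean
        )
        expected = 1.0 - math.exp(-120.0 * lam)
        observed = patients["symptom_surgery_event"].mean()
        assert observed == pytest.approx(expected, abs=0.01)

    def test_prrt_shifts_growth_downward(self):
        cfg = SimulationConfig(seed=21, n_asymptomatic=2000, n_symptomatic=0,
                               prrt_growth_shift=-0.02)
        lesions, patients = generate_cohort(cfg)
        tgr = _pipeline_tgr(lesions)
        treated = set(patients.loc[patients["prrt_treated"] == 1, "patient_id"])
        t_med = tgr[tgr.index.isin(treated)].median()
        u_med = tgr[~tgr.index.isin(treated)].median()
        assert t_med < u_med


class TestRecoveryReport:
    def test_symmetric_null_recovers_zero(self):
        cfg = SimulationConfig(seed=31, growth_mean=0.0, prrt_growth_shift=0.0)
        report = recovery_report(cfg, 30)
        row = report.set_index("parameter").loc["median_tgr_pct_per_month"]
        assert row["truth"] == pytest.approx(0.0)
        assert abs(row["error"]) < 0.3

    def test_negative_growth_target(self):
        cfg = SimulationConfig(
            seed=17, growth_mean=-0.006, prrt_growth_shift=0.0,
            n_asymptomatic=44, n_symptomatic=10,
        )
        report = recovery_report(cfg, 50)
        row = report.set_index("parameter").loc["median_tgr_pct_per_month"]
        assert row["truth"] == pytest.approx(100 * math.expm1(-0.006))
        assert abs(row["error"]) < 0.3

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError):
            recovery_report(SimulationConfig(), 0)


class TestLoadConfig:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text(
            "n_asymptomatic = 20\n"
            "growth_mean = -0.004   # per month\n"
            "\n"
            "location_probs.I = 0.2\n"
            "location_probs.II = 0.2\n"
            "location_probs.III_down = 0.4\n"
            "location_probs.III_up = 0.1\n"
            "location_probs.IV = 0.1\n"
        )
        cfg = load_config(path, seed=5)
        assert cfg.n_asymptomatic == 20
        assert cfg.growth_mean == -0.004
        assert cfg.seed == 5
        assert cfg.location_probs["III_down"] == 0.4

    def test_invalid_value_rejected(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text("n_asymptomatic = -3\n")
        with pytest.raises(ValueError):
            load_config(path)
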