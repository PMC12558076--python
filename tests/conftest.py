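import numpy as np
import pandas as pd
import pytest

from lesionkinetics.cohort import MLNM_LEVELS


def make_table2_cohort(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """44-patient toy cohort with the reference missingness pattern.

    One patient lacks urinary 5-HIAA; one lacks both Ki-67 and grade. All
    other covariates are complete and varied, and every patient has a
    growth estimate, so listwise deletion removes exactly two records.
    Returns (patients, growth).
    """
    rng = np.random.default_rng(seed)
    n = 44
    patients = pd.DataFrame(
        {
            "patient_id": [f"T{i:03d}" for i in range(n)],
            "age": rng.integers(50, 85, n).astype(float),
            "sex": rng.choice(["female", "male"], n),
            "symptomatic_at_dx": 0,
            "grade": rng.choice([1, 2], n, p=[0.45, 0.55]).astype(object),
            "ki67": np.round(rng.uniform(1, 15, n), 1).astype(object),
            "u5hiaa": np.round(rng.uniform(50, 1200, n), 1).astype(object),
            "carcinoid_heart": rng.integers(0, 2, n),
            "liver_mets": 1,
            "peritoneal_mets": rng.integers(0, 2, n),
            "extraabdominal_mets": rng.integers(0, 2, n),
            "prrt_treated": rng.integers(0, 2, n),
            "mlnm_level": rng.choice(MLNM_LEVELS, n),
            "t_symptom_surgery_months": np.round(rng.uniform(1, 120, n), 1),
            "symptom_surgery_event": 0,
            "t_death_months": np.round(rng.uniform(1, 120, n), 1),
            "death_event": rng.integers(0, 2, n),
        }
    )
    patients.loc[0, "u5hiaa"] = pd.NA
    patients.loc[1, ["ki67", "grade"]] = pd.NA
    # one grade-3 patient who never progressed, mirroring a separated level
    patients.loc[2, "grade"] = 3

    progressed = rng.integers(0, 2, n)
    progressed[2] = 0
    growth = pd.DataFrame(
        {"patient_id": patients["patient_id"], "progressed": progressed}
    )
    return patients, growth


@pytest.fixture
def table2_cohort():
    return make_table2_cohort()


@pytest.fixture
def default_cohort():
    from lesionkinetics.simulate import SimulationConfig, generate_cohort

    return generate_cohort(SimulationConfig(seed=11))
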