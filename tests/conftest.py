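import numpy as np
import pandas as pd
import pytest

from neodose.simulate import GeneratorConfig


def make_weights(pairs):
    """Weight table from (hours, grams) pairs."""
    return pd.DataFrame(
        {"time_min": [h * 60.0 for h, _ in pairs], "weight_g": [g for _, g in pairs]}
    )


def make_oral_admins(doses_mg, hours, drug="propranolol", visit_id="V1"):
    return pd.DataFrame(
        {
            "visit_id": visit_id,
            "drug": drug,
            "route": "oral",
            "time_min": [h * 60.0 for h in hours],
            "mass_mg": list(doses_mg),
            "rate_mg_min": np.nan,
        }
    )


def make_iv_admins(rates_mg_min, hours, drug="esmolol", visit_id="V1"):
    return pd.DataFrame(
        {
            "visit_id": visit_id,
            "drug": drug,
            "route": "IV",
            "time_min": [h * 60.0 for h in hours],
            "mass_mg": np.nan,
            "rate_mg_min": list(rates_mg_min),
        }
    )


def clean_config(**kw) -> GeneratorConfig:
    """Generator config with exclusion spikes off (pure archetype cohort)."""
    base = dict(
        exclusion_spike_probs={"term_ga": 0.0, "iv_propranolol": 0.0, "hemangioma": 0.0},
        missing_dx_prob=0.0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


def propranolol_only(**kw) -> GeneratorConfig:
    return clean_config(
        drug_mix={"propranolol": 1.0, "captopril": 0.0, "esmolol": 0.0}, **kw
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic mixed-drug cohort used across tests."""
    from neodose.simulate import generate_cohort

    cfg = clean_config(n_patients=40, seed=123)
    return generate_cohort(cfg)


def make_visit_row(
    visit_id="V1",
    patient_id="P1",
    ga=30.0,
    pma=40.0,
    age_discharge=70,
    dx="",
    sex="Female",
    race="White",
    ethnicity="Non-Hispanic/Latino",
    birthweight=1500.0,
    dx_missing=False,
):
    return {
        "patient_id": patient_id,
        "visit_id": visit_id,
        "admit_time": "2020-01-01T00:00",
        "sex": sex,
        "race": race,
        "ethnicity": ethnicity,
        "ga_birth_weeks": ga,
        "birthweight_g": birthweight,
        "age_discharge_days": age_discharge,
        "pma_discharge_weeks": pma,
        "dx_codes": dx,
        "dx_missing": dx_missing,
    }
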