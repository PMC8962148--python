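import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ehrlife as el

settings.register_profile("fixed", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("fixed")

_DEFAULTS = {
    "birth_date": "1970-01-01",
    "registration_date": "1995-01-01",
    "uts_date": "2000-01-01",
    "transfer_out_date": None,
    "last_collection_date": "2019-09-29",
    "death_date": None,
    "exposed": False,
    "first_diagnosis_date": None,
    "first_diagnosis_sysdate": None,
    "true_exposed": None,
}

_DATE_COLS = [c for c in _DEFAULTS if c.endswith("date")]


def make_patients(*rows: dict) -> pd.DataFrame:
    """Build a valid patient table from per-row overrides of sane defaults."""
    records = []
    for i, row in enumerate(rows):
        rec = dict(_DEFAULTS, patient_id=i, **row)
        if rec["true_exposed"] is None:
            rec["true_exposed"] = rec["exposed"]
        records.append(rec)
    df = pd.DataFrame(records)
    for col in _DATE_COLS:
        df[col] = pd.to_datetime(df[col])
    df["exposed"] = df["exposed"].astype(bool)
    df["true_exposed"] = df["true_exposed"].astype(bool)
    return df[list(el.synthetic_ehr.PATIENT_COLUMNS)]


@pytest.fixture
def patients_factory():
    return make_patients


@pytest.fixture(scope="session")
def default_settings() -> el.AnalysisSettings:
    return el.AnalysisSettings()


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 20k-patient cohort under the default bias scenario (session-cached)."""
    return el.generate_cohort(el.ScenarioConfig(n_patients=20_000, seed=1))


@pytest.fixture(scope="session")
def zero_delay_config() -> el.ScenarioConfig:
    """Diagnosis recorded exactly at eligibility, clean system dates."""
    return el.ScenarioConfig(
        n_patients=20_000,
        seed=2,
        diagnosis_delay_distribution={"family": "fixed", "delay_years": 0.0},
        backdating_probability=0.0,
        sysdate_overwrite_probability=0.0,
        sysdate_post_exit_probability=0.0,
    )
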