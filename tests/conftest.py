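import numpy as np
import pandas as pd
import pytest

from hcepi.catalog import default_catalog
from hcepi.registry import default_registry
from hcepi.simulate import SimulationConfig, make_fixture, simulate_cohort


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed cohort with corruption enabled (shared, read-only)."""
    return simulate_cohort(SimulationConfig(n_participants=800, seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Mixed cohort with all corruption disabled."""
    cfg = SimulationConfig(
        n_participants=600,
        seed=7,
        atc_mismatch_rate=0.0,
        bad_dosage_rate=0.0,
        bad_age_rate=0.0,
        bad_bmi_rate=0.0,
        non_hc_rate=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def five_users():
    return make_fixture("mixed_five_users")


def purchases_frame(rows):
    """Build a purchase table from (pid, date, atc, dosage[, label]) tuples."""
    recs = []
    for i, row in enumerate(rows):
        pid, date, atc, dosage = row[:4]
        label = row[4] if len(row) > 4 else None
        recs.append(
            {
                "purchase_id": i,
                "participant_id": pid,
                "purchase_date": pd.Timestamp(date),
                "prescribed_atc": atc,
                "purchased_atc": atc,
                "dosage": float(dosage),
                "package_content": 21,
                "iud_dose_label": label,
            }
        )
    return pd.DataFrame(recs)


def diagnoses_frame(rows):
    df = pd.DataFrame(rows, columns=["participant_id", "date", "icd10"])
    df["date"] = pd.to_datetime(df["date"])
    return df
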