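import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import pedrx


@pytest.fixture(scope="session")
def kb_records():
    return pedrx.default_label_kb()


@pytest.fixture(scope="session")
def labels(kb_records):
    return pedrx.build_effective_labels(kb_records)


@pytest.fixture(scope="session")
def category_map():
    return pedrx.default_category_map()


@pytest.fixture(scope="session")
def small_scenario():
    return pedrx.default_scenario(n_patients=1500, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    """A small simulated cohort shared across tests (read-only)."""
    return pedrx.generate_dataset(small_scenario)


@pytest.fixture()
def tiny_claims():
    """Three hand-written claims tables: two patients, three prescriptions."""
    patients = pd.DataFrame(
        {
            "patient_id": ["A", "B"],
            "birth_date": [pd.Timestamp("2000-06-01").date(), pd.Timestamp("2006-02-15").date()],
            "gender": ["male", "female"],
        }
    )
    prescriptions = pd.DataFrame(
        {
            "rx_id": ["r1", "r2", "r3"],
            "patient_id": ["A", "A", "B"],
            "atc_code": ["R03AC02", "R03BB04", "R03AC04"],
            "dispense_date": [
                pd.Timestamp("2008-05-10").date(),
                pd.Timestamp("2008-07-01").date(),
                pd.Timestamp("2008-05-20").date(),
            ],
        }
    )
    diagnoses = pd.DataFrame(
        {
            "patient_id": ["A", "A", "B"],
            "icd_code": ["J45.9", "J20.9", "J45.0"],
            "year": [2008, 2008, 2008],
            "quarter": [2, 3, 2],
        }
    )
    return pedrx.ClaimsDataset(patients, prescriptions, diagnoses)
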