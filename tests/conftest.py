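import sys
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracle.py importable

from phenodq.ehr_model import Cohort, DEFAULT_STUDY_WINDOW, EVENT_COLUMNS
from phenodq.phenotype_engine import load_all_definitions
from phenodq.synthetic_cohort import default_profile, generate_cohort


def make_events(rows):
    """Build a valid events table from (pid, dtype, code, date, ...) tuples."""
    systems = {"DX": "ICD10", "RX": "RXNORM", "LAB": "LOINC"}
    recs = []
    for r in rows:
        pid, dtype, code, d = r[:4]
        setting = r[4] if len(r) > 4 else ("outpatient" if dtype == "DX" else "")
        value = r[5] if len(r) > 5 else np.nan
        unit = r[6] if len(r) > 6 else ""
        recs.append({
            "patient_id": pid, "data_type": dtype, "code_system": systems[dtype],
            "code": code, "event_date": pd.Timestamp(d), "setting": setting,
            "value": float(value) if value == value else np.nan, "unit": unit,
        })
    ev = pd.DataFrame(recs, columns=EVENT_COLUMNS)
    if not len(ev):
        ev = pd.DataFrame(columns=EVENT_COLUMNS)
    ev["event_id"] = np.arange(len(ev), dtype=np.int64)
    return ev


def make_cohort(patient_ids, event_rows, window=DEFAULT_STUDY_WINDOW):
    patients = pd.DataFrame({
        "patient_id": list(patient_ids),
        "birth_year": 1960,
        "sex": "female", "race": "white", "ethnicity": "non_hispanic",
        "state": "MD", "inpatient_visits": 0, "ed_visits": 0,
    })
    return Cohort(patients, make_events(event_rows), window)


@pytest.fixture(scope="session")
def definitions():
    return load_all_definitions()


@pytest.fixture(scope="session")
def defn_by_name(definitions):
    return {d.name: d for d in definitions}


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient synthetic cohort for perturbation-grid assertions."""
    return generate_cohort(default_profile(400), seed=11)


@pytest.fixture(scope="session")
def mid_cohort():
    """20k-patient cohort: large enough that all 7 strata populate."""
    return generate_cohort(default_profile(20_000), seed=7)
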