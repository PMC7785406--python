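import math

import numpy as np
import pandas as pd
import pytest

from hfsymptoms import Cohort, SimConfig, generate_cohort
from hfsymptoms.cohort import PATIENT_COLUMNS, SYMPTOMS, VISIT_COLUMNS

DEFAULT_VITALS = {
    "sbp_mmhg": 120.0,
    "dbp_mmhg": 70.0,
    "hr_bpm": 70.0,
    "weight_kg": 80.0,
    "bnp_pg_ml": 500.0,
}


def make_cohort(visit_specs, patient_specs):
    """Build a cohort from terse specs.

    visit_specs: list of (patient_id, day, {symptom: score, vital: value}).
    patient_specs: list of (patient_id, hospitalized, admission_day or None)
    or (patient_id, hospitalized, admission_day, excluded_intervals_text).
    """
    vrows = []
    for pid, day, values in visit_specs:
        row = {"patient_id": pid, "day": day, **DEFAULT_VITALS}
        for s in SYMPTOMS:
            row[s] = 1
        row.update(values)
        vrows.append(row)
    prows = []
    for spec in patient_specs:
        pid, hosp, adm = spec[:3]
        excl = spec[3] if len(spec) > 3 else ""
        prows.append(
            {
                "patient_id": pid,
                "hospitalized": hosp,
                "admission_day": float(adm) if adm is not None else math.nan,
                "excluded_intervals": excl,
            }
        )
    visits = pd.DataFrame(vrows, columns=list(VISIT_COLUMNS))
    patients = pd.DataFrame(prows, columns=list(PATIENT_COLUMNS))
    patients["admission_day"] = patients["admission_day"].astype("Float64")
    return Cohort(visits=visits, patients=patients)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SimConfig(seed=123))


@pytest.fixture
def degenerate_cohort():
    """Hospitalized patients always score 5, others always 1."""
    visits = []
    patients = []
    for i in range(4):
        pid = f"E{i}"
        patients.append((pid, 1, 20))
        for day in (14, 17):
            visits.append((pid, day, {s: 5 for s in SYMPTOMS}))
    for i in range(6):
        pid = f"N{i}"
        patients.append((pid, 0, None))
        for day in (0, 3, 7, 10):
            visits.append((pid, day, {s: 1 for s in SYMPTOMS}))
    return make_cohort(visits, patients)


@pytest.fixture
def tiny_cohort():
    """6 patients x 3 visits, mixed scores; every visit day is eligible."""
    rng = np.random.default_rng(42)
    visits, patients = [], []
    for i in range(3):
        pid = f"E{i}"
        patients.append((pid, 1, 7))
        for day in (0, 3, 6):  # all within 7 days of admission on day 7
            visits.append(
                (pid, day, {s: int(rng.integers(2, 6)) for s in SYMPTOMS})
            )
    for i in range(3):
        pid = f"N{i}"
        patients.append((pid, 0, None))
        for day in (0, 3, 6):
            visits.append(
                (pid, day, {s: int(rng.integers(1, 5)) for s in SYMPTOMS})
            )
    return make_cohort(visits, patients)
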