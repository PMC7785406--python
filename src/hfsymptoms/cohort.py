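"""Longitudinal heart-failure cohort containers and CSV I/O.

A cohort is a pair of tables. The visit table has one row per
patient-visit with objective vitals (systolic/diastolic blood pressure,
heart rate, weight, B-type natriuretic peptide) and four respiratory
symptoms (dyspnea, orthopnea, bendopnea, paroxysmal nocturnal dyspnea)
each self-scored on a 5-point Likert scale (1 = no symptoms, 5 = severe).
The patient table has one row per patient with the heart-failure
hospitalization flag, the admission day when hospitalized, and optional
non-target admission intervals (e.g. an infection admission without
congestion) that must be cleared around when building feature windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Symptom column names, in canonical order.
SYMPTOMS = ("dyspnea", "orthopnea", "bendopnea", "pnd")

#: Objective vital column names (units embedded in the name).
VITALS = ("sbp_mmhg", "dbp_mmhg", "hr_bpm", "weight_kg", "bnp_pg_ml")

#: Friendly aliases accepted wherever a vital name is expected.
VITAL_ALIASES = {
    "sbp": "sbp_mmhg",
    "systolic": "sbp_mmhg",
    "dbp": "dbp_mmhg",
    "diastolic": "dbp_mmhg",
    "hr": "hr_bpm",
    "heart_rate": "hr_bpm",
    "weight": "weight_kg",
    "bnp": "bnp_pg_ml",
}

VISIT_COLUMNS = ("patient_id", "day") + VITALS + SYMPTOMS
PATIENT_COLUMNS = ("patient_id", "hospitalized", "admission_day", "excluded_intervals")


class CohortValidationError(ValueError):
    """A cohort table violates the schema or an invariant."""


def resolve_vital(name: str) -> str:
    key = VITAL_ALIASES.get(name, name)
    if key not in VITALS:
        valid = sorted(set(VITALS) | set(VITAL_ALIASES))
        raise KeyError(f"unknown vital {name!r}; valid names: {', '.join(valid)}")
    return key


def resolve_symptom(name: str) -> str:
    if name not in SYMPTOMS:
        raise KeyError(f"unknown symptom {name!r}; valid names: {', '.join(SYMPTOMS)}")
    return name


def parse_intervals(text: str | float | None) -> list[tuple[int, int]]:
    """Parse ``"10-12;20-22"`` into ``[(10, 12), (20, 22)]``; blank -> []."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    out = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        start, _, end = chunk.partition("-")
        s, e = int(start), int(end)
        if e < s:
            raise CohortValidationError(f"excluded interval {chunk!r} has end < start")
        out.append((s, e))
    return out


def format_intervals(intervals: list[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


@dataclass
class Cohort:
    """A validated pair of (visits, patients) tables.

    ``visits`` columns: ``patient_id, day, sbp_mmhg, dbp_mmhg, hr_bpm,
    weight_kg, bnp_pg_ml, dyspnea, orthopnea, bendopnea, pnd``.
    ``patients`` columns: ``patient_id, hospitalized, admission_day,
    excluded_intervals``.
    """

    visits: pd.DataFrame
    patients: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------
    def validate(self) -> None:
        for col in VISIT_COLUMNS:
            if col not in self.visits.columns:
                raise CohortValidationError(f"visits table missing column {col!r}")
        for col in PATIENT_COLUMNS:
            if col not in self.patients.columns:
                raise CohortValidationError(f"patients table missing column {col!r}")
        if self.patients["patient_id"].duplicated().any():
            dup = self.patients.loc[self.patients["patient_id"].duplicated(), "patient_id"]
            raise CohortValidationError(f"duplicate patient id {dup.iloc[0]!r}")

        known = set(self.patients["patient_id"])
        for idx, row in self.visits.iterrows():
            if row["patient_id"] not in known:
                raise CohortValidationError(
                    f"visit row {idx}: patient_id {row['patient_id']!r} not in patients table"
                )
            for sym in SYMPTOMS:
                score = row[sym]
                if not (float(score).is_integer() and 1 <= score <= 5):
                    raise CohortValidationError(
                        f"visit row {idx}: {sym}={score!r} outside ordinal range 1-5"
                    )
            for vital in VITALS:
                if not row[vital] > 0:
                    raise CohortValidationError(
                        f"visit row {idx}: {vital}={row[vital]!r} not strictly positive"
                    )
        dup_days = self.visits.duplicated(subset=["patient_id", "day"])
        if dup_days.any():
            idx = dup_days.idxmax()
            raise CohortValidationError(
                f"visit row {idx}: duplicate day for patient "
                f"{self.visits.loc[idx, 'patient_id']!r}"
            )

        for idx, row in self.patients.iterrows():
            hosp = int(row["hospitalized"])
            if hosp not in (0, 1):
                raise CohortValidationError(
                    f"patient row {idx}: hospitalized={row['hospitalized']!r} not 0/1"
                )
            adm = row["admission_day"]
            has_adm = pd.notna(adm) and adm != ""
            if hosp and not has_adm:
                raise CohortValidationError(
                    f"patient row {idx}: hospitalized=1 but admission_day blank"
                )
            if not hosp and has_adm:
                raise CohortValidationError(
                    f"patient row {idx}: admission_day set but hospitalized=0"
                )
            parse_intervals(row["excluded_intervals"])  # raises on malformed text

        # normalized, sorted representation
        self.visits = (
            self.visits.sort_values(["patient_id", "day"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.patients = (
            self.patients.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
        )

    # -- convenience ---------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_events(self) -> int:
        return int(self.patients["hospitalized"].sum())

    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    def patient_row(self, patient_id: str) -> pd.Series:
        match = self.patients[self.patients["patient_id"] == patient_id]
        if match.empty:
            raise KeyError(f"no patient {patient_id!r}")
        return match.iloc[0]

    def patient_visits(self, patient_id: str) -> pd.DataFrame:
        return self.visits[self.visits["patient_id"] == patient_id]

    def labels(self) -> dict[str, int]:
        return dict(
            zip(self.patients["patient_id"], self.patients["hospitalized"].astype(int))
        )


def write_cohort(cohort: Cohort, visit_path, patient_path) -> None:
    """Write the two cohort CSVs; round-trips exactly through read_cohort."""
    visits = cohort.visits.loc[:, list(VISIT_COLUMNS)].copy()
    for sym in SYMPTOMS:
        visits[sym] = visits[sym].astype(int)
    visits["day"] = visits["day"].astype(int)
    visits.to_csv(visit_path, index=False)

    patients = cohort.patients.loc[:, list(PATIENT_COLUMNS)].copy()
    patients["hospitalized"] = patients["hospitalized"].astype(int)
    patients["admission_day"] = [
        "" if pd.isna(v) else str(int(v)) for v in patients["admission_day"]
    ]
    patients["excluded_intervals"] = patients["excluded_intervals"].fillna("")
    patients.to_csv(patient_path, index=False)


def read_cohort(visit_path, patient_path) -> Cohort:
    """Read and validate the two cohort CSVs written by :func:`write_cohort`."""
    visits = pd.read_csv(visit_path)
    patients = pd.read_csv(
        patient_path,
        dtype={"excluded_intervals": "string"},
        keep_default_na=True,
    )
    if "patient_id" in visits.columns:
        visits["patient_id"] = visits["patient_id"].astype(str)
    if "patient_id" in patients.columns:
        patients["patient_id"] = patients["patient_id"].astype(str)
    if "admission_day" in patients.columns:
        patients["admission_day"] = pd.to_numeric(
            patients["admission_day"], errors="coerce"
        ).astype("Float64")
    if "excluded_intervals" in patients.columns:
        patients["excluded_intervals"] = (
            patients["excluded_intervals"].fillna("").astype(str)
        )
    return Cohort(visits=visits, patients=patients)
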