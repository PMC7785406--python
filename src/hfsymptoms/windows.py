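"""Eligibility windows and windowed feature summaries.

For a hospitalized patient, the window of interest is the 7 days strictly
before admission (``admission_day - day`` in ``(0, 7]``); for everyone
else it is the whole observation period, with at least 7 whole days of
clearance before and after any non-target admission interval. Objective
vitals are summarized by mean, sample standard deviation and OLS slope
against study day; ordinal symptom scores by median and range. Group
contrasts use the Wilcoxon rank-sum test (exact when both groups have
n <= 10 and no ties, otherwise midrank normal approximation with tie
and continuity corrections) and the two-sided Fisher exact test for
2x2 counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, parse_intervals, resolve_symptom, resolve_vital
from .simulate import PRE_ADMISSION_DAYS

logger = logging.getLogger(__name__)

CLEARANCE_DAYS = 7


@dataclass(frozen=True)
class EligibilityWindow:
    """The visit days a patient contributes to the analysis."""

    patient_id: str
    days: tuple[int, ...]
    basis: str  # "pre_admission" | "full_period"

    @property
    def empty(self) -> bool:
        return len(self.days) == 0


def eligible_window(patient: pd.Series, visits: pd.DataFrame) -> EligibilityWindow:
    """Compute one patient's eligibility window.

    ``patient`` is a row of the patients table; ``visits`` the full visit
    table (rows for other patients are ignored). A hospitalized patient
    with no visit inside the pre-admission week yields an *empty* window
    rather than an error; callers skip and log such patients.
    """
    pid = patient["patient_id"]
    days = sorted(int(d) for d in visits.loc[visits["patient_id"] == pid, "day"])
    if int(patient["hospitalized"]):
        adm = int(patient["admission_day"])
        keep = [d for d in days if 0 < adm - d <= PRE_ADMISSION_DAYS]
        return EligibilityWindow(pid, tuple(keep), "pre_admission")
    intervals = parse_intervals(patient["excluded_intervals"])
    keep = [
        d
        for d in days
        if all(d <= s - CLEARANCE_DAYS or d >= e + CLEARANCE_DAYS for s, e in intervals)
    ]
    return EligibilityWindow(pid, tuple(keep), "full_period")


def eligible_windows(cohort: Cohort) -> dict[str, EligibilityWindow]:
    """Windows for every patient, skipping (and logging) empty ones."""
    out: dict[str, EligibilityWindow] = {}
    for _, patient in cohort.patients.iterrows():
        win = eligible_window(patient, cohort.visits)
        if win.empty:
            logger.warning("patient %s has an empty eligibility window; skipped", win.patient_id)
            continue
        out[win.patient_id] = win
    return out


@dataclass(frozen=True)
class WindowSummary:
    """Windowed summary of one measure for one patient.

    ``mean``/``sd``/``slope`` are populated for vitals, ``median``/
    ``range`` for symptoms; ``slope`` is None with fewer than 2 visits.
    """

    measure: str
    n_visits: int
    mean: float | None = None
    sd: float | None = None
    slope: float | None = None
    median: float | None = None
    range: float | None = None


def _window_values(window: EligibilityWindow, visits: pd.DataFrame, column: str):
    sub = visits[
        (visits["patient_id"] == window.patient_id) & (visits["day"].isin(window.days))
    ].sort_values("day")
    if sub.empty:
        raise ValueError(f"patient {window.patient_id}: no visits in window")
    return sub["day"].to_numpy(dtype=float), sub[column].to_numpy(dtype=float)


def summarize_objective(
    window: EligibilityWindow, visits: pd.DataFrame, measure: str
) -> WindowSummary:
    """Mean, sample SD (n-1; 0 when n=1) and OLS slope of a vital."""
    column = resolve_vital(measure)
    days, values = _window_values(window, visits, column)
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    slope = None
    if n >= 2 and len(np.unique(days)) >= 2:
        slope = float(np.polyfit(days, values, 1)[0])
    return WindowSummary(
        measure=column, n_visits=n, mean=float(np.mean(values)), sd=sd, slope=slope
    )


def summarize_symptom(
    window: EligibilityWindow, visits: pd.DataFrame, symptom: str
) -> WindowSummary:
    """Median (mean-of-middle-two for even n) and max-minus-min range."""
    column = resolve_symptom(symptom)
    _, values = _window_values(window, visits, column)
    return WindowSummary(
        measure=column,
        n_visits=len(values),
        median=float(np.median(values)),
        range=float(np.max(values) - np.min(values)),
    )


class GroupTestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


def compare_groups_continuous(
    values_a: Iterable[float], values_b: Iterable[float]
) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Exact enumeration when both samples have n <= 10 and there are no
    ties; otherwise the midrank normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 10 and b.size <= 10 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return GroupTestResult(float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return GroupTestResult(float(res.statistic), min(float(res.pvalue), 1.0), "asymptotic")


def compare_groups_categorical(table) -> GroupTestResult:
    """Two-sided Fisher exact test on a 2x2 count table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    arr = arr.astype(int)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return GroupTestResult(float(odds), float(p), "fisher_exact")


# measure -> (summary kind, statistics reported in the group table)
OBJECTIVE_STATS = ("mean", "sd", "slope")
SYMPTOM_STATS = ("median", "range")


def patient_summary_table(cohort: Cohort) -> pd.DataFrame:
    """Per-patient windowed summaries for every vital and symptom.

    One row per (patient, measure, statistic); the backbone of the
    group-contrast table.
    """
    from .cohort import SYMPTOMS, VITALS

    windows = eligible_windows(cohort)
    labels = cohort.labels()
    rows = []
    for pid, win in windows.items():
        for vital in VITALS:
            s = summarize_objective(win, cohort.visits, vital)
            for stat in OBJECTIVE_STATS:
                rows.append(
                    {
                        "patient_id": pid,
                        "hospitalized": labels[pid],
                        "measure": vital,
                        "statistic": stat,
                        "value": getattr(s, stat),
                        "n_visits": s.n_visits,
                    }
                )
        for sym in SYMPTOMS:
            s = summarize_symptom(win, cohort.visits, sym)
            for stat in SYMPTOM_STATS:
                rows.append(
                    {
                        "patient_id": pid,
                        "hospitalized": labels[pid],
                        "measure": sym,
                        "statistic": stat,
                        "value": getattr(s, "range" if stat == "range" else stat),
                        "n_visits": s.n_visits,
                    }
                )
    return pd.DataFrame(rows)


def group_contrast_table(cohort: Cohort) -> pd.DataFrame:
    """Group medians/IQRs of per-patient summaries with rank-sum p-values.

    Columns: ``group, measure, statistic, median, q1, q3, p_value``. With
    a single group the p-value column is NaN.
    """
    per_patient = patient_summary_table(cohort)
    out = []
    for (measure, stat), chunk in per_patient.groupby(["measure", "statistic"], sort=False):
        chunk = chunk.dropna(subset=["value"])
        hosp = chunk.loc[chunk["hospitalized"] == 1, "value"].to_numpy()
        nohosp = chunk.loc[chunk["hospitalized"] == 0, "value"].to_numpy()
        p = math.nan
        if hosp.size and nohosp.size:
            p = compare_groups_continuous(hosp, nohosp).pvalue
        for group, values in (("not_hospitalized", nohosp), ("hospitalized", hosp)):
            if values.size == 0:
                continue
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            out.append(
                {
                    "group": group,
                    "measure": measure,
                    "statistic": stat,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "p_value": p,
                }
            )
    return pd.DataFrame(out, columns=["group", "measure", "statistic", "median", "q1", "q3", "p_value"])
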