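"""Synthetic longitudinal heart-failure cohort generator.

Emulates a small telemonitoring pilot: ~29 patients visited twice weekly
over 30 days, about a third of whom are hospitalized for decompensated
heart failure during the study. Symptom scores arise from a latent
severity Gaussian cut at fixed ordinal thresholds, so the generative
optimum of any score cutoff is known exactly — downstream cutoff-recovery
tests can be scored against the truth. Hospitalized patients switch from
the non-event to the event severity regime in the 7 days before
admission; B-type natriuretic peptide additionally trends upward over
that window. Vitals combine a per-patient baseline offset (between-patient
spread) with per-visit noise (within-patient variability); BNP is
log-normal to stay positive, the remaining vitals Gaussian truncated at
zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import SYMPTOMS, Cohort, format_intervals

DEFAULT_VISIT_DAYS = (0, 3, 7, 10, 14, 17, 21, 24, 28)

#: Days before admission during which a hospitalized patient's visits are
#: drawn from the event regime (and over which features are later pooled).
PRE_ADMISSION_DAYS = 7

_DEFAULT_VISIT_NOISE = MappingProxyType(
    {"sbp": 12.8, "dbp": 6.0, "hr": 7.5, "weight": 1.0, "bnp_log": 0.2}
)
_DEFAULT_PATIENT_SPREAD = MappingProxyType(
    {"sbp": 8.0, "dbp": 5.0, "hr": 6.0, "weight": 12.0, "bnp_log": 0.6}
)


class ConfigurationError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic cohort.

    Defaults reproduce the pilot-study conditions: 29 patients, 10/29
    event fraction, twice-weekly visits over 30 days, group contrasts of
    roughly 4-vs-2 in symptom medians, 80-vs-67 bpm in heart rate and
    1113-vs-546 pg/mL in BNP with a ~20 pg/mL/day pre-admission rise.

    The latent severity scale is anchored to the score scale: thresholds
    (1.5, 2.5, 3.5, 4.5) make a latent value of k map to score round(k).
    With event mean 3.9 and non-event mean 2.0 (sd 0.7) the Youden-optimal
    score cutoff is 3 (latent boundary 2.5 is closest to the equal-density
    point 2.95), mirroring the dyspnea cutoff the analysis should find.
    """

    n_patients: int = 29
    event_fraction: float = 10 / 29
    study_days: int = 30
    visit_days: tuple[int, ...] = DEFAULT_VISIT_DAYS
    latent_mean_event: float = 3.9
    latent_mean_nonevent: float = 2.0
    latent_sd: float = 0.7
    ordinal_thresholds: tuple[float, float, float, float] = (1.5, 2.5, 3.5, 4.5)
    hr_mean_event: float = 80.4
    hr_mean_nonevent: float = 67.4
    bnp_mean_event: float = 1112.5
    bnp_mean_nonevent: float = 545.6
    bnp_preadmission_slope: float = 19.65
    weight_mean: float = 87.0
    sbp_mean: float = 121.8
    dbp_mean: float = 72.0
    vital_noise_sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_VISIT_NOISE))
    between_patient_sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_PATIENT_SPREAD))
    n_nontarget_admissions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if not 0.0 <= self.event_fraction <= 1.0:
            raise ConfigurationError("event_fraction must lie in [0, 1]")
        if self.study_days < 1:
            raise ConfigurationError("study_days must be positive")
        days = tuple(self.visit_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("visit_days must be strictly increasing")
        if days and (days[0] < 0 or days[-1] > self.study_days):
            raise ConfigurationError("visit_days must lie within [0, study_days]")
        th = tuple(self.ordinal_thresholds)
        if len(th) != 4 or any(b <= a for a, b in zip(th, th[1:])):
            raise ConfigurationError("ordinal_thresholds must be 4 strictly ascending reals")
        if self.latent_sd <= 0:
            raise ConfigurationError("latent_sd must be positive")
        for key, val in {**self.vital_noise_sds, **self.between_patient_sds}.items():
            if val < 0:
                raise ConfigurationError(f"noise sd {key!r} must be non-negative")
        object.__setattr__(self, "visit_days", days)
        object.__setattr__(self, "ordinal_thresholds", th)

    @property
    def n_events(self) -> int:
        return int(round(self.n_patients * self.event_fraction))

    def admission_candidates(self) -> list[int]:
        """Admission days in the second half of the study leaving >=2
        visits inside the pre-admission window."""
        lo = max(1, self.study_days // 2 - 1)
        hi = max(lo, self.study_days - 2)
        out = []
        for day in range(lo, hi + 1):
            pre = [d for d in self.visit_days if 0 < day - d <= PRE_ADMISSION_DAYS]
            if len(pre) >= 2:
                out.append(day)
        return out

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Load a config from a JSON or YAML mirror of the field names."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        for key in ("visit_days", "ordinal_thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "event_fraction": self.event_fraction,
            "study_days": self.study_days,
            "visit_days": list(self.visit_days),
            "latent_mean_event": self.latent_mean_event,
            "latent_mean_nonevent": self.latent_mean_nonevent,
            "latent_sd": self.latent_sd,
            "ordinal_thresholds": list(self.ordinal_thresholds),
            "hr_mean_event": self.hr_mean_event,
            "hr_mean_nonevent": self.hr_mean_nonevent,
            "bnp_mean_event": self.bnp_mean_event,
            "bnp_mean_nonevent": self.bnp_mean_nonevent,
            "bnp_preadmission_slope": self.bnp_preadmission_slope,
            "weight_mean": self.weight_mean,
            "sbp_mean": self.sbp_mean,
            "dbp_mean": self.dbp_mean,
            "vital_noise_sds": dict(self.vital_noise_sds),
            "between_patient_sds": dict(self.between_patient_sds),
            "n_nontarget_admissions": self.n_nontarget_admissions,
            "seed": self.seed,
        }

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


#: Fixed non-target admission interval (e.g. an infection without
#: congestion) assigned to up to ``n_nontarget_admissions`` non-event
#: patients; clearance logic downstream must skirt it by 7 days each side.
NONTARGET_INTERVAL = (12, 13)


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw one synthetic cohort; identical config (incl. seed) gives an
    identical cohort."""
    n_events = config.n_events
    if n_events > 0 and not config.admission_candidates():
        raise ConfigurationError(
            "visit schedule too sparse: no admission day in the second half of "
            f"the study has >=2 visits within the preceding {PRE_ADMISSION_DAYS} days"
        )

    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_patients)))
    ids = [f"P{i + 1:0{width}d}" for i in range(config.n_patients)]
    event_ids = set(rng.choice(ids, size=n_events, replace=False)) if n_events else set()
    noneventers = [pid for pid in ids if pid not in event_ids]
    nontarget = set(noneventers[: max(0, config.n_nontarget_admissions)])

    candidates = config.admission_candidates()
    noise = config.vital_noise_sds
    spread = config.between_patient_sds

    visit_rows: list[dict] = []
    patient_rows: list[dict] = []
    for pid in ids:
        is_event = pid in event_ids
        admission = int(rng.choice(candidates)) if is_event else None
        intervals = [NONTARGET_INTERVAL] if pid in nontarget else []

        days = np.array(
            [
                d
                for d in config.visit_days
                if (admission is None or d < admission)
                and not any(s <= d <= e for s, e in intervals)
            ],
            dtype=int,
        )
        n = len(days)
        if is_event:
            in_window = (admission - days > 0) & (admission - days <= PRE_ADMISSION_DAYS)
        else:
            in_window = np.zeros(n, dtype=bool)

        # per-patient baseline offsets
        off = {k: rng.normal(0.0, spread[k]) for k in ("sbp", "dbp", "hr", "weight", "bnp_log")}

        hr_mean = np.where(in_window, config.hr_mean_event, config.hr_mean_nonevent)
        hr = hr_mean + off["hr"] + rng.normal(0.0, noise["hr"], n)
        sbp = config.sbp_mean + off["sbp"] + rng.normal(0.0, noise["sbp"], n)
        dbp = config.dbp_mean + off["dbp"] + rng.normal(0.0, noise["dbp"], n)
        weight = config.weight_mean + off["weight"] + rng.normal(0.0, noise["weight"], n)

        bnp_med = np.full(n, float(config.bnp_mean_nonevent))
        if is_event:
            # center the linear rise on the middle of the pre-admission
            # window so the window average matches bnp_mean_event
            center = admission - PRE_ADMISSION_DAYS / 2
            trend = config.bnp_mean_event + config.bnp_preadmission_slope * (days - center)
            bnp_med = np.where(in_window, np.maximum(trend, 1.0), bnp_med)
        bnp = bnp_med * np.exp(off["bnp_log"] + rng.normal(0.0, noise["bnp_log"], n))

        scores = {}
        for sym in SYMPTOMS:
            mean = np.where(in_window, config.latent_mean_event, config.latent_mean_nonevent)
            latent = rng.normal(mean, config.latent_sd)
            scores[sym] = 1 + np.searchsorted(
                np.asarray(config.ordinal_thresholds), latent, side="left"
            )

        floor = 1e-3  # truncation at zero for the Gaussian vitals
        for i in range(n):
            visit_rows.append(
                {
                    "patient_id": pid,
                    "day": int(days[i]),
                    "sbp_mmhg": max(sbp[i], floor),
                    "dbp_mmhg": max(dbp[i], floor),
                    "hr_bpm": max(hr[i], floor),
                    "weight_kg": max(weight[i], floor),
                    "bnp_pg_ml": max(bnp[i], floor),
                    **{sym: int(scores[sym][i]) for sym in SYMPTOMS},
                }
            )
        patient_rows.append(
            {
                "patient_id": pid,
                "hospitalized": int(is_event),
                "admission_day": float(admission) if is_event else math.nan,
                "excluded_intervals": format_intervals(intervals),
            }
        )

    from .cohort import VISIT_COLUMNS, PATIENT_COLUMNS

    visits = pd.DataFrame(visit_rows, columns=list(VISIT_COLUMNS))
    patients = pd.DataFrame(patient_rows, columns=list(PATIENT_COLUMNS))
    patients["admission_day"] = patients["admission_day"].astype("Float64")
    return Cohort(visits=visits, patients=patients)
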