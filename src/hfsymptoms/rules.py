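"""Symptom-combination decision rules and their resampled evaluation.

A rule is a non-empty subset of the four respiratory symptoms with one
severity cutoff per symptom and a temporal mode. Under ``single_day`` the
rule fires for a patient when, on the randomly sampled day, *every*
symptom in the subset is at or above its cutoff. The two-day modes look
at a random pair of consecutive visits (both inside the eligibility
window): ``either_of_two`` requires each symptom to be severe on at
least one of the days, ``both_of_two`` on both, and ``increase`` requires
each symptom's score to be strictly greater on the later day (no cutoff
involved). Predicates are evaluated per symptom and conjoined.

Evaluation repeats the random-day draw (default 1000 iterations) and
averages sensitivity, specificity, Youden index and the binary-rule AUC
(= (sens + spec) / 2) over iterations, with 2.5/97.5 percentile bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np

from .cohort import SYMPTOMS, Cohort, resolve_symptom
from .cutoffs import DaySample, sample_random_days
from .windows import EligibilityWindow, eligible_windows

TEMPORAL_MODES = ("single_day", "either_of_two", "both_of_two", "increase")

#: Default per-symptom cutoffs used when a caller supplies none; these are
#: the values the source study reports for its own cohort and serve here
#: only as conventional rule parameters.
DEFAULT_CUTOFFS = {"dyspnea": 3, "orthopnea": 2, "bendopnea": 4, "pnd": 4}


@dataclass(frozen=True)
class RuleSpec:
    """A symptom-combination decision rule."""

    symptoms: tuple[str, ...]
    cutoffs: tuple[tuple[str, int], ...]
    temporal_mode: str = "single_day"

    def __post_init__(self) -> None:
        syms = tuple(resolve_symptom(s) for s in self.symptoms)
        if not syms or len(set(syms)) != len(syms):
            raise ValueError("symptoms must be a non-empty set without repeats")
        cut = dict(self.cutoffs)
        if self.temporal_mode not in TEMPORAL_MODES:
            raise ValueError(f"temporal_mode must be one of {TEMPORAL_MODES}")
        if self.temporal_mode != "increase":
            for s in syms:
                if s not in cut:
                    raise ValueError(f"no cutoff given for symptom {s!r}")
                if cut[s] not in (2, 3, 4, 5):
                    raise ValueError(f"cutoff for {s!r} must be in {{2..5}}")
        object.__setattr__(self, "symptoms", syms)
        object.__setattr__(
            self, "cutoffs", tuple((s, int(cut[s])) for s in syms if s in cut)
        )

    @classmethod
    def make(
        cls,
        symptoms,
        cutoffs: Mapping[str, int] | None = None,
        temporal_mode: str = "single_day",
    ) -> "RuleSpec":
        cutoffs = DEFAULT_CUTOFFS if cutoffs is None else dict(cutoffs)
        syms = tuple(symptoms)
        return cls(
            symptoms=syms,
            cutoffs=tuple((s, cutoffs[s]) for s in syms if s in cutoffs),
            temporal_mode=temporal_mode,
        )

    @property
    def cutoff_map(self) -> dict[str, int]:
        return dict(self.cutoffs)

    @property
    def name(self) -> str:
        return "+".join(self.symptoms)


def enumerate_rules(
    symptoms=SYMPTOMS,
    min_size: int = 2,
    max_size: int = 3,
    cutoffs: Mapping[str, int] | None = None,
    temporal_mode: str = "single_day",
) -> list[RuleSpec]:
    """All symptom subsets with sizes in [min_size, max_size].

    With the four symptoms and the default 2-3 size range this yields the
    study's "10 possible combinations" (6 pairs + 4 triples). Order is
    deterministic: by subset size, then lexicographic by symptom name.
    """
    symptoms = tuple(symptoms)
    if not 1 <= min_size <= max_size <= len(symptoms):
        raise ValueError("need 1 <= min_size <= max_size <= number of symptoms")
    out = []
    for size in range(min_size, max_size + 1):
        for combo in combinations(sorted(symptoms), size):
            out.append(RuleSpec.make(combo, cutoffs=cutoffs, temporal_mode=temporal_mode))
    return out


# ---------------------------------------------------------------------------
# rule application


def apply_rule_single_day(
    rule: RuleSpec, sample: DaySample, cohort: Cohort
) -> dict[str, bool]:
    """Positive iff every symptom in the rule meets its cutoff on the
    sampled day."""
    if rule.temporal_mode != "single_day":
        raise ValueError("rule is not a single_day rule")
    cut = rule.cutoff_map
    preds: dict[str, bool] = {}
    for pid, day in sample.assignments.items():
        row = cohort.visits[
            (cohort.visits["patient_id"] == pid) & (cohort.visits["day"] == day)
        ]
        if row.empty:
            raise ValueError(f"patient {pid} has no visit on sampled day {day}")
        preds[pid] = all(int(row.iloc[0][s]) >= cut[s] for s in rule.symptoms)
    return preds


def consecutive_pairs(window: EligibilityWindow, visit_days) -> list[tuple[int, int]]:
    """Adjacent visit pairs (in the patient's full schedule) with both
    days inside the window."""
    days = sorted(int(d) for d in visit_days)
    inside = set(window.days)
    return [
        (a, b) for a, b in zip(days, days[1:]) if a in inside and b in inside
    ]


def sample_consecutive_pairs(
    cohort: Cohort,
    rng: np.random.Generator,
    windows: Mapping[str, EligibilityWindow] | None = None,
) -> tuple[dict[str, tuple[int, int]], tuple[str, ...]]:
    """Uniformly draw one eligible consecutive visit pair per patient.

    Returns (pairs, omitted): patients with no adjacent pair fully inside
    their eligibility window are omitted and listed.
    """
    if windows is None:
        windows = eligible_windows(cohort)
    pairs: dict[str, tuple[int, int]] = {}
    omitted: list[str] = []
    pids = sorted(windows)
    u = rng.random(len(pids))
    for i, pid in enumerate(pids):
        cand = consecutive_pairs(windows[pid], cohort.patient_visits(pid)["day"])
        if not cand:
            omitted.append(pid)
            continue
        pairs[pid] = cand[int(u[i] * len(cand))]
    omitted.extend(sorted(set(cohort.patient_ids()) - set(pids)))
    if not pairs:
        raise ValueError("no patient has an eligible consecutive visit pair")
    return pairs, tuple(sorted(omitted))


def apply_rule_two_day(
    rule: RuleSpec, pairs: Mapping[str, tuple[int, int]], cohort: Cohort
) -> dict[str, bool]:
    """Evaluate a two-day rule on sampled consecutive visit pairs."""
    mode = rule.temporal_mode
    if mode not in ("either_of_two", "both_of_two", "increase"):
        raise ValueError("rule is not a two-day rule")
    cut = rule.cutoff_map
    preds: dict[str, bool] = {}
    for pid, (d1, d2) in pairs.items():
        visits = cohort.patient_visits(pid).set_index("day")
        try:
            row1, row2 = visits.loc[d1], visits.loc[d2]
        except KeyError as err:
            raise ValueError(f"patient {pid} has no visit on sampled day {err}") from None
        ok = True
        for s in rule.symptoms:
            s1, s2 = int(row1[s]), int(row2[s])
            if mode == "either_of_two":
                ok = s1 >= cut[s] or s2 >= cut[s]
            elif mode == "both_of_two":
                ok = s1 >= cut[s] and s2 >= cut[s]
            else:  # increase: strictly greater on the later day, no cutoff
                ok = s2 > s1
            if not ok:
                break
        preds[pid] = ok
    return preds


# ---------------------------------------------------------------------------
# resampled evaluation


@dataclass
class RuleEvaluationResults:
    """Resampled performance of one rule under one temporal mode."""

    rule: RuleSpec
    n_iterations: int
    n_skipped: int
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_patients_used: np.ndarray

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    @property
    def auc(self) -> np.ndarray:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def sensitivity_mean(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def specificity_mean(self) -> float:
        return float(np.mean(self.specificity))

    @property
    def youden_mean(self) -> float:
        return float(np.mean(self.youden))

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc))

    def metric_summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in ("sensitivity", "specificity", "youden", "auc"):
            arr = getattr(self, name)
            out[name] = {
                "mean": float(np.mean(arr)),
                "p2.5": float(np.percentile(arr, 2.5)),
                "p97.5": float(np.percentile(arr, 97.5)),
            }
        return out

    def summary(self) -> str:
        m = self.metric_summary()
        lines = [
            f"Rule {self.rule.name} [{self.rule.temporal_mode}]",
            "  cutoffs           "
            + (
                ", ".join(f"{s}>={c}" for s, c in self.rule.cutoffs)
                if self.rule.temporal_mode != "increase"
                else "(severity increase, no cutoff)"
            ),
            f"  iterations        {self.n_iterations} ({self.n_skipped} skipped)",
        ]
        for name in ("sensitivity", "specificity", "youden", "auc"):
            s = m[name]
            lines.append(
                f"  {name:<12} mean {s['mean']:.3f}  95% band [{s['p2.5']:.3f}, {s['p97.5']:.3f}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule.name,
            "temporal_mode": self.rule.temporal_mode,
            "cutoffs": dict(self.rule.cutoffs),
            "n_iterations": int(self.n_iterations),
            "n_skipped": int(self.n_skipped),
            "metrics": self.metric_summary(),
            "mean_patients_used": float(np.mean(self.n_patients_used)),
        }


class SymptomRuleModel:
    """Monte-Carlo evaluation of one decision rule on a cohort."""

    def __init__(self, cohort: Cohort, rule: RuleSpec) -> None:
        self.cohort = cohort
        self.rule = rule
        self.windows = eligible_windows(cohort)
        self._labels = cohort.labels()
        # Precomputed per-patient lookups so each iteration touches no
        # DataFrame. RNG consumption matches sample_random_days /
        # sample_consecutive_pairs exactly (one uniform per patient, in
        # sorted-id order), so a fit with n_iterations=1 reproduces the
        # public sampling functions driven by the same substream.
        self._pids = sorted(self.windows)
        self._scores: dict[str, dict[int, dict[str, int]]] = {}
        self._pairs: dict[str, list[tuple[int, int]]] = {}
        for pid in self._pids:
            visits = cohort.patient_visits(pid)
            by_day = {
                int(row["day"]): {s: int(row[s]) for s in SYMPTOMS}
                for _, row in visits.iterrows()
            }
            self._scores[pid] = by_day
            self._pairs[pid] = consecutive_pairs(self.windows[pid], visits["day"])

    def _predicate(self, pid: str, rng_value: float) -> bool | None:
        """Rule prediction for one patient, or None if the patient has no
        eligible pair (two-day modes only)."""
        mode = self.rule.temporal_mode
        cut = self.rule.cutoff_map
        win = self.windows[pid].days
        if mode == "single_day":
            day = win[int(rng_value * len(win))]
            scores = self._scores[pid][day]
            return all(scores[s] >= cut[s] for s in self.rule.symptoms)
        cand = self._pairs[pid]
        if not cand:
            return None
        d1, d2 = cand[int(rng_value * len(cand))]
        s1, s2 = self._scores[pid][d1], self._scores[pid][d2]
        for s in self.rule.symptoms:
            if mode == "either_of_two":
                ok = s1[s] >= cut[s] or s2[s] >= cut[s]
            elif mode == "both_of_two":
                ok = s1[s] >= cut[s] and s2[s] >= cut[s]
            else:
                ok = s2[s] > s1[s]
            if not ok:
                return False
        return True

    def _iteration(self, rng: np.random.Generator):
        u = rng.random(len(self._pids))
        ys, yhats = [], []
        for i, pid in enumerate(self._pids):
            pred = self._predicate(pid, u[i])
            if pred is None:
                continue
            ys.append(self._labels[pid])
            yhats.append(pred)
        y = np.asarray(ys, dtype=int)
        yhat = np.asarray(yhats, dtype=bool)
        if y.size == 0 or y.sum() == 0 or y.sum() == y.size:
            return None
        sens = float(yhat[y == 1].mean())
        spec = float((~yhat[y == 0]).mean())
        return sens, spec, y.size

    def fit(self, n_iterations: int = 1000, seed: int | None = None) -> RuleEvaluationResults:
        """Average sensitivity/specificity over seeded random-day draws.

        Iterations in which patient omissions empty one of the groups are
        skipped and counted; more than 50% skipped is an error.
        """
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        children = np.random.SeedSequence(seed).spawn(n_iterations)
        sens, spec, used = [], [], []
        skipped = 0
        for child in children:
            out = self._iteration(np.random.default_rng(child))
            if out is None:
                skipped += 1
                continue
            sens.append(out[0])
            spec.append(out[1])
            used.append(out[2])
        if skipped > n_iterations / 2:
            raise RuntimeError(
                f"{skipped}/{n_iterations} iterations skipped: a group was "
                "emptied by patient omissions in most iterations"
            )
        return RuleEvaluationResults(
            rule=self.rule,
            n_iterations=n_iterations,
            n_skipped=skipped,
            sensitivity=np.asarray(sens),
            specificity=np.asarray(spec),
            n_patients_used=np.asarray(used, dtype=int),
        )


def evaluate_rule(
    rule: RuleSpec,
    cohort: Cohort,
    n_iterations: int = 1000,
    seed: int | None = None,
) -> RuleEvaluationResults:
    """Convenience wrapper: build the model and fit it."""
    return SymptomRuleModel(cohort, rule).fit(n_iterations=n_iterations, seed=seed)


def rank_rules(evaluations: list[RuleEvaluationResults]) -> list[RuleEvaluationResults]:
    """Sort descending by mean Youden index, then mean AUC, then name."""
    if not evaluations:
        raise ValueError("need at least one evaluation")
    return sorted(
        evaluations,
        key=lambda e: (-e.youden_mean, -e.auc_mean, e.rule.name, e.rule.temporal_mode),
    )
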