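"""Random-day resampling selection of Youden-optimal symptom cutoffs.

The study design asks, for each respiratory symptom, which Likert
severity cutoff best separates patients who will shortly be hospitalized
for heart failure from those who will not. Because each patient
contributes many visits but only one label, one visit day per patient is
drawn at random — uniformly from the 7 days before admission for
hospitalized patients and from the whole (cleared) observation period
for the rest — and the Youden index of every candidate cutoff in
{2, 3, 4, 5} is computed on that cross-section. Repeating this (by
default) 1000 times with fresh random days yields a win count per
cutoff: the modal per-iteration winner is the chosen cutoff. Ties, both
per iteration and modal, break toward the lower cutoff, which favors
sensitivity in a screening setting.

The per-iteration winner is judged on the Youden index; for a single
binary cutoff rule the AUC equals (YI + 1) / 2, a strictly increasing
transform, so ranking by AUC would pick the same winner. The ordinal
(multi-threshold) AUC of the raw scores is recorded per iteration as a
descriptive companion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort, resolve_symptom
from .metrics import confusion_at_cutoff, roc_auc
from .windows import EligibilityWindow, eligible_windows

CUTOFF_GRID = (2, 3, 4, 5)


@dataclass(frozen=True)
class DaySample:
    """One random visit day per patient (patients with empty windows omitted)."""

    assignments: Mapping[str, int]
    iteration: int | None = None
    seed_state: tuple | None = None
    omitted: tuple[str, ...] = ()


def sample_random_days(
    cohort: Cohort,
    rng: np.random.Generator,
    windows: Mapping[str, EligibilityWindow] | None = None,
    iteration: int | None = None,
) -> DaySample:
    """Draw one uniformly random eligible day per patient.

    Patients whose eligibility window is empty are omitted and recorded
    in ``omitted``. A patient with a single eligible day always receives
    that day, independent of the generator state.
    """
    if windows is None:
        windows = eligible_windows(cohort)
    pids = sorted(windows)
    if not pids:
        raise ValueError("every patient has an empty eligibility window")
    u = rng.random(len(pids))
    assignments = {
        pid: windows[pid].days[int(u[i] * len(windows[pid].days))]
        for i, pid in enumerate(pids)
    }
    all_ids = set(cohort.patient_ids())
    omitted = tuple(sorted(all_ids - set(pids)))
    return DaySample(assignments=assignments, iteration=iteration, omitted=omitted)


@dataclass
class CutoffSelectionResults:
    """Outcome of the resampling cutoff selection for one symptom."""

    symptom: str
    chosen_cutoff: int
    win_counts: dict[int, int]
    auc_distribution: np.ndarray
    yi_distribution: np.ndarray
    n_iterations: int
    omitted_patients: tuple[str, ...] = ()

    def distribution_summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, arr in (("auc", self.auc_distribution), ("youden", self.yi_distribution)):
            out[name] = {
                "mean": float(np.mean(arr)),
                "median": float(np.median(arr)),
                "p2.5": float(np.percentile(arr, 2.5)),
                "p97.5": float(np.percentile(arr, 97.5)),
            }
        return out

    def summary(self) -> str:
        lines = [
            f"Cutoff selection: {self.symptom}",
            f"  iterations        {self.n_iterations}",
            f"  chosen cutoff     >= {self.chosen_cutoff}",
            "  win counts        "
            + ", ".join(f">={c}: {self.win_counts.get(c, 0)}" for c in CUTOFF_GRID),
        ]
        d = self.distribution_summary()
        for name in ("youden", "auc"):
            s = d[name]
            lines.append(
                f"  {name:<7} mean {s['mean']:.3f}  median {s['median']:.3f}  "
                f"95% band [{s['p2.5']:.3f}, {s['p97.5']:.3f}]"
            )
        if self.omitted_patients:
            lines.append(f"  omitted patients  {', '.join(self.omitted_patients)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "symptom": self.symptom,
            "chosen_cutoff": int(self.chosen_cutoff),
            "win_counts": {str(c): int(self.win_counts.get(c, 0)) for c in CUTOFF_GRID},
            "n_iterations": int(self.n_iterations),
            "distributions": self.distribution_summary(),
            "omitted_patients": list(self.omitted_patients),
        }


class SymptomCutoffModel:
    """Resampling model selecting one symptom's severity cutoff.

    Parameters
    ----------
    cohort
        Validated cohort with both hospitalized and non-hospitalized
        patients (after removal of patients with empty windows).
    symptom
        One of ``dyspnea, orthopnea, bendopnea, pnd``.
    cutoff_grid
        Candidate cutoffs; ``score >= 1`` is vacuous and excluded by
        default.
    """

    def __init__(
        self,
        cohort: Cohort,
        symptom: str,
        cutoff_grid: Sequence[int] = CUTOFF_GRID,
    ) -> None:
        self.cohort = cohort
        self.symptom = resolve_symptom(symptom)
        self.cutoff_grid = tuple(cutoff_grid)
        self.windows = eligible_windows(cohort)

        labels = cohort.labels()
        included = sorted(self.windows)
        self._labels = np.array([labels[p] for p in included], dtype=int)
        if self._labels.sum() == 0 or self._labels.sum() == len(included):
            missing_group = "hospitalized" if self._labels.sum() == 0 else "non-hospitalized"
            dropped = sorted(set(cohort.patient_ids()) - set(included))
            raise ValueError(
                f"no {missing_group} patient has a non-empty eligibility window"
                + (f" (dropped: {', '.join(dropped)})" if dropped else "")
            )
        self._included = included
        # per-patient lookup: visit day -> symptom score
        self._score_by_day = {
            pid: dict(
                zip(
                    cohort.patient_visits(pid)["day"].astype(int),
                    cohort.patient_visits(pid)[self.symptom].astype(int),
                )
            )
            for pid in included
        }

    def _iteration(self, rng: np.random.Generator, iteration: int):
        sample = sample_random_days(self.cohort, rng, windows=self.windows, iteration=iteration)
        scores = np.array(
            [self._score_by_day[pid][sample.assignments[pid]] for pid in self._included]
        )
        yis = [confusion_at_cutoff(scores, self._labels, c).youden for c in self.cutoff_grid]
        best = int(np.argmax(yis))  # np.argmax takes the first (lowest) maximum
        return self.cutoff_grid[best], float(yis[best]), roc_auc(scores, self._labels)

    def fit(self, n_iterations: int = 1000, seed: int | None = None) -> CutoffSelectionResults:
        """Run the resampling selection; reproducible from ``seed``.

        A root seed spawns one substream per iteration, so results do not
        depend on execution order.
        """
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        children = np.random.SeedSequence(seed).spawn(n_iterations)
        win_counts = {c: 0 for c in self.cutoff_grid}
        aucs = np.empty(n_iterations)
        yis = np.empty(n_iterations)
        for i, child in enumerate(children):
            winner, best_yi, auc = self._iteration(np.random.default_rng(child), i)
            win_counts[winner] += 1
            yis[i] = best_yi
            aucs[i] = auc
        top = max(win_counts.values())
        chosen = min(c for c, n in win_counts.items() if n == top)
        omitted = tuple(sorted(set(self.cohort.patient_ids()) - set(self._included)))
        return CutoffSelectionResults(
            symptom=self.symptom,
            chosen_cutoff=chosen,
            win_counts=win_counts,
            auc_distribution=aucs,
            yi_distribution=yis,
            n_iterations=n_iterations,
            omitted_patients=omitted,
        )


def select_cutoff(
    cohort: Cohort,
    symptom: str,
    n_iterations: int = 1000,
    seed: int | None = None,
) -> CutoffSelectionResults:
    """Convenience wrapper: build the model and fit it."""
    return SymptomCutoffModel(cohort, symptom).fit(n_iterations=n_iterations, seed=seed)
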