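"""End-to-end seeded pipeline: cohort -> windows -> cutoffs -> rules.

One root seed drives everything: a seed sequence is split into a cohort
stream (when simulating), one stream per symptom for cutoff selection and
one stream per rule-mode evaluation, so reports are byte-identical across
runs with the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SYMPTOMS, Cohort, read_cohort, write_cohort
from .cutoffs import CutoffSelectionResults, SymptomCutoffModel
from .rules import (
    TEMPORAL_MODES,
    RuleEvaluationResults,
    SymptomRuleModel,
    enumerate_rules,
    rank_rules,
)
from .simulate import SimConfig, generate_cohort
from .windows import group_contrast_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``sim`` (simulate a cohort) or ``visits_path`` +
    ``patients_path`` (load one) must be given. ``seed`` is mandatory:
    the pipeline refuses to run with silent nondeterminism.
    """

    seed: int
    sim: SimConfig | None = None
    visits_path: str | None = None
    patients_path: str | None = None
    iterations: int = 1000
    cutoff_overrides: dict[str, int] | None = None
    min_size: int = 2
    max_size: int = 3
    modes: tuple[str, ...] = TEMPORAL_MODES
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is required and must be an integer")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        has_paths = self.visits_path is not None and self.patients_path is not None
        if (self.sim is None) == (not has_paths):
            raise ValueError("give exactly one of a SimConfig or cohort CSV paths")
        for mode in self.modes:
            if mode not in TEMPORAL_MODES:
                raise ValueError(f"unknown temporal mode {mode!r}")

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "sim": self.sim.to_dict() if self.sim else None,
            "visits_path": self.visits_path,
            "patients_path": self.patients_path,
            "iterations": self.iterations,
            "cutoff_overrides": self.cutoff_overrides,
            "min_size": self.min_size,
            "max_size": self.max_size,
            "modes": list(self.modes),
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """All pipeline outputs plus a provenance block."""

    config: RunConfig
    cohort: Cohort
    table3: pd.DataFrame
    cutoff_selections: dict[str, CutoffSelectionResults]
    rule_evaluations: list[RuleEvaluationResults]

    @property
    def selected_cutoffs(self) -> dict[str, int]:
        cut = {s: r.chosen_cutoff for s, r in self.cutoff_selections.items()}
        if self.config.cutoff_overrides:
            cut.update(self.config.cutoff_overrides)
        return cut

    def to_dict(self) -> dict:
        visit_counts = self.cohort.visits.groupby("patient_id").size()
        return {
            "provenance": {
                "software": "hfsymptoms",
                "version": __version__,
                "seed": int(self.config.seed),
                "config_hash": self.config.digest(),
            },
            "cohort": {
                "n_patients": self.cohort.n_patients,
                "n_events": self.cohort.n_events,
                "n_visits": int(len(self.cohort.visits)),
                "visits_per_patient": {
                    "min": int(visit_counts.min()),
                    "max": int(visit_counts.max()),
                },
            },
            "table3": self.table3.to_dict(orient="records"),
            "cutoffs": {s: r.to_dict() for s, r in self.cutoff_selections.items()},
            "selected_cutoffs": self.selected_cutoffs,
            "rules": [e.to_dict() for e in rank_rules(self.rule_evaluations)],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _derive_seed(seedseq_child: np.random.SeedSequence) -> int:
    return int(seedseq_child.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; identical config+seed -> identical report."""
    root = np.random.SeedSequence(config.seed)
    cohort_ss, cutoff_ss, rule_ss = root.spawn(3)

    if config.sim is not None:
        sim = config.sim.with_seed(_derive_seed(cohort_ss))
        logger.info("simulating cohort (n=%d, seed=%d)", sim.n_patients, sim.seed)
        cohort = generate_cohort(sim)
    else:
        logger.info("reading cohort from %s / %s", config.visits_path, config.patients_path)
        cohort = read_cohort(config.visits_path, config.patients_path)

    table3 = group_contrast_table(cohort)

    cutoff_children = cutoff_ss.spawn(len(SYMPTOMS))
    selections: dict[str, CutoffSelectionResults] = {}
    if cohort.n_events and cohort.n_events < cohort.n_patients:
        for sym, child in zip(SYMPTOMS, cutoff_children):
            model = SymptomCutoffModel(cohort, sym)
            selections[sym] = model.fit(
                n_iterations=config.iterations, seed=_derive_seed(child)
            )
            logger.info("cutoff %s -> >=%d", sym, selections[sym].chosen_cutoff)
    else:
        logger.warning("single-group cohort: skipping cutoff selection and rules")

    evaluations: list[RuleEvaluationResults] = []
    if selections:
        cutoffs = {s: r.chosen_cutoff for s, r in selections.items()}
        if config.cutoff_overrides:
            cutoffs.update(config.cutoff_overrides)
        specs = [
            spec
            for mode in config.modes
            for spec in enumerate_rules(
                SYMPTOMS,
                min_size=config.min_size,
                max_size=config.max_size,
                cutoffs=cutoffs,
                temporal_mode=mode,
            )
        ]
        rule_children = rule_ss.spawn(len(specs))
        for spec, child in zip(specs, rule_children):
            model = SymptomRuleModel(cohort, spec)
            evaluations.append(
                model.fit(n_iterations=config.iterations, seed=_derive_seed(child))
            )

    return RunReport(
        config=config,
        cohort=cohort,
        table3=table3,
        cutoff_selections=selections,
        rule_evaluations=evaluations,
    )


def render_table3(report: RunReport) -> str:
    """Group-contrast table as CSV text (1-decimal summaries, 3-decimal p).

    Columns: ``group, measure, statistic, median, q1, q3, p_value``.
    Rendering only formats numbers already computed by the windows stage.
    """
    df = report.table3.copy()
    for col in ("median", "q1", "q3"):
        df[col] = df[col].map(lambda v: f"{v:.1f}")
    df["p_value"] = df["p_value"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    return df.to_csv(index=False)


def render_rules_csv(report: RunReport) -> str:
    """Ranked rule metrics as CSV text (metrics to 2 decimals)."""
    rows = []
    for ev in rank_rules(report.rule_evaluations):
        m = ev.metric_summary()
        row = {
            "rule": ev.rule.name,
            "temporal_mode": ev.rule.temporal_mode,
            "cutoffs": ";".join(f"{s}>={c}" for s, c in ev.rule.cutoffs),
        }
        for name in ("sensitivity", "specificity", "youden", "auc"):
            row[f"{name}_mean"] = f"{m[name]['mean']:.2f}"
            row[f"{name}_p2.5"] = f"{m[name]['p2.5']:.2f}"
            row[f"{name}_p97.5"] = f"{m[name]['p97.5']:.2f}"
        rows.append(row)
    return pd.DataFrame(rows).to_csv(index=False)


def write_report(report: RunReport, out_dir) -> dict[str, Path]:
    """Write cohort CSVs, table3.csv, cutoffs.json, rules.csv, report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": out / "visits.csv",
        "patients": out / "patients.csv",
        "table3": out / "table3.csv",
        "cutoffs": out / "cutoffs.json",
        "rules": out / "rules.csv",
        "report": out / "report.json",
    }
    write_cohort(report.cohort, paths["visits"], paths["patients"])
    paths["table3"].write_text(render_table3(report))
    paths["cutoffs"].write_text(
        json.dumps(
            {s: r.to_dict() for s, r in report.cutoff_selections.items()},
            indent=2,
            sort_keys=True,
        )
    )
    paths["rules"].write_text(render_rules_csv(report))
    paths["report"].write_text(report.to_json())
    return paths
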