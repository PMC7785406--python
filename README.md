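# hfsymptoms

Tools for asking a practical question in heart-failure (HF) telemonitoring:
when patients at high risk of decompensation are visited twice weekly for a
month — vitals measured, four respiratory symptoms (dyspnea, orthopnea,
bendopnea, paroxysmal nocturnal dyspnea) self-scored on a 5-point Likert
scale — can the symptom scores flag an imminent HF hospitalization, and at
what severity threshold?

The package is aimed at biostatisticians and clinical-research engineers
prototyping symptom-based early-warning rules on small longitudinal
cohorts. It provides:

- a **synthetic cohort generator** (`SimConfig`, `generate_cohort`) that
  emulates a ~29-patient, 30-day, twice-weekly pilot with a ~34% event
  rate: an invertible latent-Gaussian ordinal symptom model plus calibrated
  vitals (heart rate ≈80 vs ≈67 bpm between groups, BNP ≈1113 vs ≈546
  pg/mL with a ≈20 pg/mL/day pre-admission rise);
- **eligibility windows and windowed features**: the 7 days before
  admission for hospitalized patients, the whole period with ≥7-day
  clearance around any non-target admission otherwise; mean/SD/OLS-slope
  for vitals, median/range for symptoms, rank-sum and Fisher exact group
  contrasts;
- **cutoff selection by random-day resampling** (`SymptomCutoffModel`):
  draw one eligible day per patient, compute the Youden index
  J = sensitivity + specificity − 1 of each cutoff `score ≥ c`,
  c ∈ {2,…,5}, repeat 1000 times and take the modal winner (ties break
  low). For a binary cutoff rule AUC = (J + 1)/2, so J- and AUC-ranking
  coincide;
- a **rule engine** (`SymptomRuleModel`) evaluating every symptom
  combination (pairs and triples by default — 10 rules) under four
  temporal modes: severe on a single day, on either / both of two
  consecutive visits, or strictly increasing across them; metrics are
  averaged over 1000 seeded resampling iterations with percentile bands;
- a **CLI** (`hfsymptoms simulate | summarize | select-cutoffs |
  evaluate-rules | run-all`) writing cohort CSVs, a group-contrast table,
  `cutoffs.json`, `rules.csv` and a provenance-stamped `report.json` that
  is byte-identical across runs with the same seed.

## Worked example

```python
from hfsymptoms import (SimConfig, generate_cohort, select_cutoff,
                        RuleSpec, evaluate_rule)

cohort = generate_cohort(SimConfig(seed=42))
print(f"{cohort.n_patients} patients, {cohort.n_events} hospitalized")

sel = select_cutoff(cohort, "dyspnea", n_iterations=1000, seed=7)
print(sel.summary())

rule = RuleSpec.make(("dyspnea", "orthopnea", "bendopnea"),
                     {"dyspnea": 3, "orthopnea": 2, "bendopnea": 4})
print(evaluate_rule(rule, cohort, n_iterations=1000, seed=7).summary())
```

prints

```
29 patients, 10 hospitalized
Cutoff selection: dyspnea
  iterations        1000
  chosen cutoff     >= 4
  win counts        >=2: 0, >=3: 85, >=4: 915, >=5: 0
  youden  mean 0.903  median 0.900  95% band [0.788, 1.000]
  auc     mean 0.986  median 0.987  95% band [0.958, 1.000]
Rule dyspnea+orthopnea+bendopnea [single_day]
  cutoffs           dyspnea>=3, orthopnea>=2, bendopnea>=4
  iterations        1000 (0 skipped)
  sensitivity  mean 0.802  95% band [0.700, 0.900]
  specificity  mean 1.000  95% band [1.000, 1.000]
  youden       mean 0.801  95% band [0.700, 0.900]
  auc          mean 0.901  95% band [0.850, 0.950]
```

Reading this: across 1000 random-day draws on this synthetic cohort the
dyspnea cutoff most often maximizing the Youden index is "score ≥ 4"
(915 wins), one level above the generative optimum of 3 — with scores this
discrete the winner fluctuates between 3 and 4 across cohorts, which is
why recovery is assessed within ±1 level. The three-symptom conjunction
("dyspnea ≥ 3 AND orthopnea ≥ 2 AND bendopnea ≥ 4 on the sampled day")
catches on average 80% of the patients who go on to be hospitalized while
never firing for those who do not, giving a mean Youden index of 0.80 and
a binary-rule AUC of 0.90. The synthetic cohort is cleaner than real
telemonitoring data, so these operating characteristics are upper bounds
on what the same procedure yields in practice.

The same analysis end to end, from the shell:

```sh
hfsymptoms run-all --seed 42 --iterations 1000 --out results/
```

## Layout

| Module | Contents |
| --- | --- |
| `hfsymptoms.cohort` | `Cohort` container, CSV schema, validation, I/O |
| `hfsymptoms.simulate` | `SimConfig`, `generate_cohort` |
| `hfsymptoms.windows` | eligibility windows, windowed summaries, group tests |
| `hfsymptoms.metrics` | rank AUC, cutoff confusion, Youden/binary-AUC identities |
| `hfsymptoms.cutoffs` | `SymptomCutoffModel` → `CutoffSelectionResults` |
| `hfsymptoms.rules` | `RuleSpec`, `SymptomRuleModel` → `RuleEvaluationResults`, ranking |
| `hfsymptoms.pipeline` | `RunConfig`, `run_pipeline`, report rendering |
| `hfsymptoms.cli` | the `hfsymptoms` command |

See `docs/methods.md` for the statistical model, its assumptions, and what
the synthetic cohorts do and do not emulate.
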