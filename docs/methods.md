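# Methods

## Problem and setting

`hfsymptoms` implements an analysis pipeline for small heart-failure (HF)
telemonitoring cohorts: patients at high risk of decompensation are visited
twice weekly for about a month, and at each visit objective vitals (blood
pressure, heart rate, weight, point-of-care B-type natriuretic peptide) and
four self-reported respiratory symptoms — dyspnea, orthopnea, bendopnea and
paroxysmal nocturnal dyspnea (PND) — are recorded on a 5-point Likert scale
(1 = no symptoms, 5 = severe). The analytic question is whether, and at what
severity threshold, these ordinal symptom reports predict imminent HF
hospitalization, and which *combinations* of symptoms make the best
screening rule.

Because each patient contributes a short time series but a single outcome
label, the pipeline reduces the longitudinal data to patient-level
cross-sections by randomized day sampling rather than by fitting a
longitudinal model. All randomness is driven by explicit seeds.

## Eligibility windows

For a hospitalized patient only the visits in the week before admission are
informative about imminent decompensation: the window keeps visit days `d`
with `admission_day − d ∈ (0, 7]` — a full week, inclusive of the visit
exactly 7 days prior, exclusive of the admission day itself. Non-hospitalized
patients contribute their whole observation period, except that any
non-target admission (e.g. an infection without congestion) is skirted by at
least 7 whole days on each side. A hospitalized patient with no visit inside
the pre-admission week is flagged, logged and skipped — never silently
imputed.

## Windowed features

Objective vitals are summarized per patient by the arithmetic mean, the
sample standard deviation (n−1 denominator; 0 for a single visit) and the
ordinary-least-squares slope against study day (units/day; undefined, not
zero, with fewer than two visits). Whether the slope should be OLS or a
first-minus-last difference is genuinely open in this design; OLS was chosen
as the convention and is stated here as such. Symptoms are summarized by the
sample median (mean of the middle two for even n) and the range (max −
min). Group contrasts of these per-patient summaries use the two-sided
Wilcoxon rank-sum test — exact enumeration when both groups have n ≤ 10 and
no ties, otherwise the midrank normal approximation with tie and continuity
corrections (the continuity correction keeps the approximation within ~0.01
of the exact p at these sample sizes) — and the two-sided Fisher exact test
for 2×2 counts. Ordinal scores guarantee ties, so the midrank path is the
common case. No multiplicity adjustment is applied: the table is
descriptive, with one test per row.

## Cutoff selection by random-day resampling

For each symptom, one visit day per patient is drawn uniformly at random
from that patient's eligibility window, giving a cross-section of one score
and one label per patient. On it the Youden index J = sensitivity +
specificity − 1 of each candidate cutoff in {2, 3, 4, 5} is computed
(`score ≥ cutoff` predicts hospitalization; cutoff 1 is vacuous and
excluded). This is repeated 1000 times with fresh days; each iteration
credits one win to its best cutoff and the modal winner is chosen. Ties —
within an iteration and between modal counts — break toward the lower
cutoff, which favors sensitivity in a screening application.

The per-iteration criterion is the Youden index. For a single binary cutoff
rule the ROC has two segments and AUC = (J + 1)/2, a strictly increasing
transform of J, so an AUC-based argmax could never disagree with the
J-based one; no disagreement log is therefore carried. The ordinal
(multi-threshold) rank AUC of the raw scores is recorded per iteration as a
descriptive companion distribution.

Reproducibility: a root seed is expanded into one `SeedSequence` substream
per iteration, so per-iteration results are independent of execution order,
and the whole selection is invariant to the ordering of patients in the
input tables (patients are processed in sorted-id order).

## Decision rules over symptom combinations

A rule is a subset of the four symptoms (sizes 2–3 by default, giving the
10 combinations of pairs and triples; sizes 1 and 4 are available through
flags) with one cutoff per symptom and a temporal mode:

- `single_day` — on the sampled day, every symptom in the subset is at or
  above its cutoff;
- `either_of_two` / `both_of_two` — over a uniformly sampled pair of
  *consecutive* visits (adjacent in the patient's schedule, both inside the
  eligibility window), each symptom meets its cutoff on at least one / on
  both days;
- `increase` — each symptom's score is strictly greater on the later day;
  no cutoff is involved in this mode.

For multi-symptom rules the temporal predicate is evaluated per symptom and
the results conjoined; the composition order (predicate-then-conjunction) is
a design choice, as is the strict inequality for `increase`. Patients
without an eligible consecutive pair are omitted from two-day iterations and
logged; iterations in which the omissions empty either outcome group are
skipped and counted, and more than 50% skipped aborts the evaluation.

Each rule is evaluated over 1000 seeded iterations; sensitivity and
specificity are computed against the true hospitalization labels per
iteration and averaged, with 2.5/97.5 percentile bands. The Youden index and
AUC are derived per iteration through the binary-rule identities
J = sens + spec − 1 and AUC = (sens + spec)/2, so the invariants
`youden_mean = sensitivity_mean + specificity_mean − 1` and
`auc_mean = (sensitivity_mean + specificity_mean)/2` hold exactly. Rules are
ranked by mean Youden index, ties by mean AUC, then by name.

## Synthetic cohort generator

No raw patient-level data accompany this design, so the generator is a
first-class, tested component that emulates the study conditions: 29
patients, event fraction 10/29 (≈34%), visits on days
{0, 3, 7, 10, 14, 17, 21, 24, 28} of a 30-day window (twice-weekly cadence;
the exact days are a convention, not a recorded fact). Hospitalized patients
receive an admission day drawn uniformly from days 14–28 subject to having
at least two visits in the preceding week, so both single-day and
consecutive-pair rules are exercised; their visits stop at admission. One
non-hospitalized patient carries a fixed non-target admission interval
(days 12–13) to exercise the clearance logic.

Symptoms arise from a latent severity Gaussian per visit and symptom, cut
at fixed thresholds (1.5, 2.5, 3.5, 4.5) so that a latent value of k maps
to score round(k): the score is 1 plus the number of thresholds below the
latent draw. The latent mean is 2.0 (sd 0.7) outside the pre-admission
week and 3.9 inside it, reproducing the observed group medians of ≈2 vs ≈4.
The model is deliberately invertible: the Youden-optimal generative score
cutoff is 3 (the latent boundary 2.5 is nearest the equal-density point
2.95; at an event mean of exactly 4.0, cutoffs 3 and 4 would tie), so
cutoff-recovery tests have a known truth. With this overlap the finite-
sample winner still fluctuates between 3 and 4 across seeds — that is the
intended operating regime, and recovery is scored within ±1 level.

Vitals combine a per-patient Gaussian baseline offset (between-patient
spread, e.g. 6 bpm for heart rate, 12 kg for weight) with per-visit noise
(within-patient variability, e.g. 7.5 bpm, 1 kg), reproducing both the
spread of patient averages and the within-patient SDs of the target
contrasts (heart rate 80.4 vs 67.4 bpm). BNP is log-normal (multiplicative
patient offset sd 0.6 log-units, visit noise 0.2) with median 545.6 pg/mL
outside the event regime; inside the pre-admission week its median follows
a linear rise of 19.65 pg/mL/day centered so the window average is
1112.5 pg/mL. Gaussian vitals are truncated at zero (a floor never reached
at realistic parameters). Diastolic pressure (mean 72 mmHg) is carried to
complete the blood-pressure record; it has no group contrast.

What the generator does **not** emulate: missing or irregular visits,
measurement drift, within-patient symptom autocorrelation beyond the
regime switch, demographic or treatment effects, competing admissions
beyond the single non-target interval, and any dependence between symptoms
and vitals beyond their shared regime. Passing tests therefore demonstrate
that the *procedure* is correct and well calibrated under these idealized
conditions, not that the printed operating characteristics of any real
cohort are recoverable.

## Numerical and degenerate-input choices

- AUC uses the midrank formula, identical to all-pairs enumeration to
  machine precision (property-tested to n = 30).
- A single eligible day or pair is assigned deterministically, independent
  of the random stream.
- Empty windows, single-class label vectors, zero Fisher margins and
  configs without seeds raise named errors early rather than propagating
  NaNs.
- Reports round medians/IQRs to 1 decimal and rule metrics to 2 decimals
  for display; JSON artifacts keep full precision. Rendering performs no
  arithmetic beyond formatting.

## Problem sizes in the shipped checks

The test suite exercises the resampling machinery at reduced but
representative sizes — 200 generator seeds for calibration, 100 seeds ×
200 iterations for cutoff recovery, 10,000 iterations against an exact
enumeration oracle on a 6-patient cohort, 150-iteration end-to-end
determinism — sizes at which Monte-Carlo error is small relative to every
asserted tolerance. The acceptance script runs the full pipeline at the
default 1000 iterations.

## Known limitations

The evaluation is in-sample in the same sense as the study design it
implements: cutoffs are selected and rules evaluated on the same cohort,
with no cross-validation or patient-level bootstrap confidence intervals,
and the percentile bands describe day-resampling variability only, not
sampling variability of the cohort. Mean aggregation across iterations is
a convention; the underlying per-iteration distributions are retained on
the results objects for any other summary.
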