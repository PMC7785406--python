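"""Independent brute-force oracles used only by the test suite."""

from itertools import combinations

import numpy as np

from hfsymptoms.rules import consecutive_pairs
from hfsymptoms.windows import eligible_windows


def brute_force_auc(scores, labels):
    """AUC as the all-pairs win/tie probability, enumerated directly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def exact_ranksum_p(a, b):
    """Two-sided exact rank-sum p by enumerating all label assignments."""
    a = list(a)
    b = list(b)
    pooled = np.asarray(a + b, dtype=float)
    n1 = len(a)
    idx = range(len(pooled))
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # no ties assumed
    observed = ranks[:n1].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(idx, n1)]
    sums = np.asarray(sums)
    mean = sums.mean()
    p = np.mean(np.abs(sums - mean) >= abs(observed - mean) - 1e-12)
    return float(p)


def _predicate_single(scores_by_day, day, rule):
    cut = rule.cutoff_map
    return all(scores_by_day[day][s] >= cut[s] for s in rule.symptoms)


def _predicate_pair(scores_by_day, pair, rule):
    cut = rule.cutoff_map
    d1, d2 = pair
    for s in rule.symptoms:
        s1, s2 = scores_by_day[d1][s], scores_by_day[d2][s]
        if rule.temporal_mode == "either_of_two":
            ok = s1 >= cut[s] or s2 >= cut[s]
        elif rule.temporal_mode == "both_of_two":
            ok = s1 >= cut[s] and s2 >= cut[s]
        else:
            ok = s2 > s1
        if not ok:
            return False
    return True


def exact_rule_means(cohort, rule):
    """Exact expected sensitivity/specificity under uniform random-day
    (or random-pair) assignment.

    Because sensitivity is the average of per-patient indicators and each
    patient's day is drawn independently, the expectation over the full
    product space of assignments equals the average, over patients in the
    group, of the per-patient probability that the rule fires — enumerated
    here day by day. Valid when no iteration can empty a group (every
    patient must have at least one eligible day/pair).
    """
    from hfsymptoms.cohort import SYMPTOMS

    windows = eligible_windows(cohort)
    labels = cohort.labels()
    probs = {}
    for pid, win in windows.items():
        visits = cohort.patient_visits(pid)
        by_day = {
            int(r["day"]): {s: int(r[s]) for s in SYMPTOMS} for _, r in visits.iterrows()
        }
        if rule.temporal_mode == "single_day":
            choices = list(win.days)
            hits = [_predicate_single(by_day, d, rule) for d in choices]
        else:
            choices = consecutive_pairs(win, visits["day"])
            if not choices:
                continue
            hits = [_predicate_pair(by_day, p, rule) for p in choices]
        probs[pid] = float(np.mean(hits))
    pos = [probs[p] for p in probs if labels[p] == 1]
    neg = [probs[p] for p in probs if labels[p] == 0]
    sens = float(np.mean(pos))
    spec = float(1.0 - np.mean(neg))
    return sens, spec
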