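"""Discrimination metrics for ordinal scores and binary decision rules."""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
from scipy.stats import rankdata


def _check_binary(labels: np.ndarray) -> None:
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores: Iterable[float], labels: Iterable[int]) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 * P(tie).

    Computed with the midrank (Mann-Whitney) formula; higher scores must
    indicate the positive (hospitalized) class.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    _check_binary(y)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class Confusion(NamedTuple):
    sensitivity: float
    specificity: float
    youden: float


def confusion_at_cutoff(
    scores: Iterable[float], labels: Iterable[int], cutoff: int
) -> Confusion:
    """Sensitivity/specificity/Youden of the rule ``score >= cutoff``."""
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    _check_binary(y)
    if cutoff not in (2, 3, 4, 5):
        raise ValueError("cutoff must be an integer in {2, 3, 4, 5}")
    pred = s >= cutoff
    sens = float(pred[y == 1].mean())
    spec = float((~pred[y == 0]).mean())
    return Confusion(sens, spec, sens + spec - 1.0)


def youden(sensitivity: float, specificity: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def binary_rule_auc(sensitivity: float, specificity: float) -> float:
    """AUC of a single binary rule: the two-segment ROC gives
    (sensitivity + specificity) / 2."""
    return (sensitivity + specificity) / 2.0
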