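"""Performance and fairness scoring for humans, models and collaborations.

Performance: AUROC and AUPRC computed from a risk ordering (probabilities
for models, 6 - ESI for triage assessments, admit=1 for dispositions) plus
F1 on the binarized call.  Fairness: the absolute averaged odds difference

    AAOD = 1/2 |TPR_maj - TPR_min| + 1/2 |FPR_maj - FPR_min|

evaluated for three fixed demographic partitions — race (white / not
white), age (<50 / >=50) and gender (male / not male), majority side named
first — and summed across them.  AAOD = 0 means equalized odds holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

__all__ = [
    "MetricsReport",
    "roc_auc",
    "pr_auc",
    "f1",
    "aaod",
    "evaluate",
    "METRIC_NAMES",
]

METRIC_NAMES = ("auroc", "auprc", "f1", "aaod_race", "aaod_age", "aaod_gender", "aaod_sum")


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    f1: float
    aaod_by_attribute: dict[str, float]
    aaod_sum: float

    def to_dict(self) -> dict[str, float]:
        out = {"auroc": self.auroc, "auprc": self.auprc, "f1": self.f1}
        for attr, value in self.aaod_by_attribute.items():
            out[f"aaod_{attr}"] = value
        out["aaod_sum"] = self.aaod_sum
        return out


def _check_two_classes(outcomes: np.ndarray, what: str) -> None:
    if len(np.unique(outcomes)) < 2:
        raise ValueError(f"{what} undefined: outcomes contain a single class")


def roc_auc(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """AUROC over all distinct score thresholds; ties count as 1/2."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_two_classes(outcomes, "AUROC")
    return float(roc_auc_score(outcomes, scores))


def pr_auc(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Average-precision AUPRC (interpolation-free step summation)."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_two_classes(outcomes, "AUPRC")
    return float(average_precision_score(outcomes, scores))


def f1(binary_preds: np.ndarray, outcomes: np.ndarray) -> float:
    """F1 = 2TP / (2TP + FP + FN); defined as 0 when the denominator is 0."""
    return float(f1_score(np.asarray(outcomes, int), np.asarray(binary_preds, int), zero_division=0))


def _rates(preds: np.ndarray, outcomes: np.ndarray, side: str) -> tuple[float, float]:
    pos = outcomes == 1
    neg = ~pos
    if not pos.any():
        raise ValueError(f"AAOD undefined: group side '{side}' has no positive outcomes")
    if not neg.any():
        raise ValueError(f"AAOD undefined: group side '{side}' has no negative outcomes")
    tpr = float(preds[pos].mean())
    fpr = float(preds[neg].mean())
    return tpr, fpr


def aaod(binary_preds: np.ndarray, outcomes: np.ndarray, group_majority: np.ndarray) -> float:
    """Absolute averaged odds difference for one binary partition.

    ``group_majority`` is True on the majority side.  Errors (rather than
    silently reporting 0) when either side lacks a positive or negative
    outcome, since TPR/FPR would be undefined.
    """
    preds = np.asarray(binary_preds, dtype=int)
    outcomes = np.asarray(outcomes, dtype=int)
    maj = np.asarray(group_majority, dtype=bool)
    if not maj.any() or maj.all():
        raise ValueError("AAOD undefined: one side of the partition is empty")
    tpr_maj, fpr_maj = _rates(preds[maj], outcomes[maj], "majority")
    tpr_min, fpr_min = _rates(preds[~maj], outcomes[~maj], "minority")
    return 0.5 * abs(tpr_maj - tpr_min) + 0.5 * abs(fpr_maj - fpr_min)


def evaluate(
    scores: np.ndarray,
    binary_preds: np.ndarray,
    outcomes: np.ndarray,
    groups: dict[str, np.ndarray],
) -> MetricsReport:
    """Score one predictor: ranking metrics, F1, and AAOD per partition."""
    by_attr = {
        name: aaod(binary_preds, outcomes, majority) for name, majority in groups.items()
    }
    return MetricsReport(
        auroc=roc_auc(scores, outcomes),
        auprc=pr_auc(scores, outcomes),
        f1=f1(binary_preds, outcomes),
        aaod_by_attribute=by_attr,
        aaod_sum=float(sum(by_attr.values())),
    )
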