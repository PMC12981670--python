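"""Auditor models driving prediction suppression.

An auditor is a secondary classifier that decides, per patient, whether the
primary risk model's prediction should be concealed from the clinician.  It
is trained on the risk model's *training-set* outputs — never on held-out
outcomes — with one of two label constructions:

* ``predict_error``: 1 iff the model's thresholded label disagreed with the
  true outcome;
* ``predict_uncertainty``: 1 iff the virtual-ensemble uncertainty fell in
  the "high" half of a median split.

The three canonical suppression scenarios pair these strategies with an
L2-regularized logistic regression or a cost-complexity-pruned decision
tree (the pruning level picked by cross-validation):

==============  ===================  =============
scenario        suppression signal   auditor model
==============  ===================  =============
Collaboration1  predicted error      logistic
Collaboration2  predicted error      pruned tree
Collaboration3  predicted high
                uncertainty          pruned tree
==============  ===================  =============

Every auditor consumes the same three features: the model's predicted
probability of the positive class, the binarized human assessment, and the
model's uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import NotFittedError
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .predictors import RiskOutput

__all__ = [
    "AuditorSpec",
    "SuppressionVerdict",
    "ConstantAuditor",
    "CANONICAL_SCENARIOS",
    "auditor_features",
    "build_auditor_training_set",
    "discretize_uncertainty",
    "train_auditor",
    "audit",
]

#: Scenario name -> (suppression strategy, auditor family).
CANONICAL_SCENARIOS = {
    "Collaboration1": ("predict_error", "logistic"),
    "Collaboration2": ("predict_error", "pruned_tree"),
    "Collaboration3": ("predict_uncertainty", "pruned_tree"),
}

_STRATEGIES = ("predict_error", "predict_uncertainty")
_FAMILIES = ("logistic", "pruned_tree")


@dataclass(frozen=True)
class AuditorSpec:
    strategy: str = "predict_error"
    family: str = "logistic"
    l2_alpha: float = 1.0
    cv_folds: int = 3
    max_pruning_candidates: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown auditor family {self.family!r}")
        if self.l2_alpha <= 0:
            raise ValueError("l2_alpha must be positive")

    @property
    def is_canonical(self) -> bool:
        return (self.strategy, self.family) in CANONICAL_SCENARIOS.values()


@dataclass
class SuppressionVerdict:
    """Per-patient mask; 1 = hide the ML prediction from the clinician."""

    suppress: np.ndarray

    def __post_init__(self) -> None:
        self.suppress = np.asarray(self.suppress, dtype=int)
        if not np.isin(self.suppress, [0, 1]).all():
            raise ValueError("suppress mask must be binary")

    def __len__(self) -> int:
        return len(self.suppress)


class ConstantAuditor:
    """Degenerate auditor emitted when training labels are single-class."""

    def __init__(self, value: int):
        self.value = int(value)

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.value, dtype=int)


def discretize_uncertainty(u: np.ndarray) -> np.ndarray:
    """Median split into low (0) / high (1) bins.

    Values strictly above the median are "high"; ties with the median go to
    "low", so a constant vector is all-low.  With distinct values the two
    bins differ in size by at most one.
    """
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("cannot discretize an empty uncertainty vector")
    return (u > np.median(u)).astype(int)


def auditor_features(risk: RiskOutput, human_binary: np.ndarray) -> np.ndarray:
    """(prob, human prediction, uncertainty) matrix, one row per patient."""
    human_binary = np.asarray(human_binary, dtype=float)
    if len(human_binary) != len(risk):
        raise ValueError(
            f"length mismatch: {len(risk)} risk outputs vs {len(human_binary)} human predictions"
        )
    return np.column_stack([risk.prob, human_binary, risk.uncertainty])


def build_auditor_training_set(
    train_risk: RiskOutput,
    human_binary: np.ndarray,
    outcomes: np.ndarray,
    strategy: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the auditor's (features, labels) from training-set outputs."""
    outcomes = np.asarray(outcomes, dtype=int)
    if len(outcomes) != len(train_risk):
        raise ValueError(
            f"length mismatch: {len(train_risk)} risk outputs vs {len(outcomes)} outcomes"
        )
    X = auditor_features(train_risk, human_binary)
    if strategy == "predict_error":
        labels = (train_risk.label != outcomes).astype(int)
    elif strategy == "predict_uncertainty":
        labels = discretize_uncertainty(train_risk.uncertainty)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return X, labels


def _fit_pruned_tree(X, y, spec: AuditorSpec) -> DecisionTreeClassifier:
    base = DecisionTreeClassifier(random_state=spec.seed)
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if len(alphas) > spec.max_pruning_candidates:
        idx = np.linspace(0, len(alphas) - 1, spec.max_pruning_candidates).round().astype(int)
        alphas = alphas[np.unique(idx)]
    best_alpha, best_score = 0.0, -np.inf
    n_min = int(np.bincount(y, minlength=2).min())
    folds = max(2, min(spec.cv_folds, n_min))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    for alpha in alphas:
        tree = DecisionTreeClassifier(random_state=spec.seed, ccp_alpha=alpha)
        score = cross_val_score(tree, X, y, cv=cv, scoring="accuracy").mean()
        if score > best_score:
            best_alpha, best_score = float(alpha), float(score)
    final = DecisionTreeClassifier(random_state=spec.seed, ccp_alpha=best_alpha)
    final.fit(X, y)
    return final


def train_auditor(X: np.ndarray, labels: np.ndarray, spec: AuditorSpec | None = None):
    """Fit the requested auditor; single-class labels yield a constant auditor."""
    spec = spec or AuditorSpec()
    spec.validate()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(X) != len(labels):
        raise ValueError(f"length mismatch: {len(X)} feature rows vs {len(labels)} labels")

    classes = np.unique(labels)
    if len(classes) == 1:
        return ConstantAuditor(int(classes[0]))

    if spec.family == "logistic":
        # default penalty is L2; C is the inverse regularization strength
        clf = LogisticRegression(C=1.0 / spec.l2_alpha, max_iter=2000, random_state=spec.seed)
        clf.fit(X, labels)
        return clf
    return _fit_pruned_tree(X, labels, spec)


def audit(auditor, features: np.ndarray) -> SuppressionVerdict:
    """Apply a fitted auditor; a positive call means suppress."""
    try:
        preds = auditor.predict(np.asarray(features, dtype=float))
    except NotFittedError as exc:
        raise ValueError("auditor is not fitted") from exc
    return SuppressionVerdict(suppress=np.asarray(preds, dtype=int))
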