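"""Risk predictors: a boosted-tree model with virtual-ensemble uncertainty,
and an artificially accurate oracle.

The realistic predictor is a gradient-boosted tree ensemble trained with
early stopping on binary log loss (15% of the training data held out as a
validation slice, up to 1000 trees) and optional hyperparameter grid search
with 3-fold cross-validation.  Per-instance epistemic-style uncertainty
comes from a *virtual ensemble*: the fitted booster is truncated to K
equally spaced boosting prefixes and the variance of their probability
predictions is reported, avoiding any retraining.

The oracle predictor looks up the true outcome and reports it with a fixed
correctness probability (default 95%), providing a near-best-case AI against
which collaboration scenarios can be benchmarked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import Cohort

__all__ = [
    "ModelConfig",
    "RiskOutput",
    "RiskModel",
    "train_risk_model",
    "predict_with_uncertainty",
    "oracle_predict",
    "FEATURE_COLUMNS",
]

#: Model inputs: demographics, vitals, complaint and utilization counts.
#: The human assessment (ESI / disposition) and the outcome are excluded.
FEATURE_COLUMNS = (
    "age",
    "sex",
    "race",
    "heart_rate",
    "resp_rate",
    "sbp",
    "dbp",
    "spo2",
    "temperature",
    "chief_complaint",
    "n_prior_ed_visits",
    "n_chronic_conditions",
    "n_medications",
)

_CATEGORICAL = ("sex", "race", "chief_complaint")


@dataclass(frozen=True)
class ModelConfig:
    max_trees: int = 1000
    validation_fraction: float = 0.15
    depth_grid: tuple[int, ...] = (3,)
    l2_grid: tuple[float, ...] = (1.0,)
    cv_folds: int = 3
    n_virtual_subensembles: int = 10
    learning_rate: float = 0.1
    early_stopping_rounds: int = 30
    decision_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError(
                f"validation_fraction must be in (0, 1), got {self.validation_fraction}"
            )
        if not self.depth_grid or not self.l2_grid:
            raise ValueError("depth_grid and l2_grid must be nonempty")
        if self.max_trees < 1 or self.n_virtual_subensembles < 1:
            raise ValueError("max_trees and n_virtual_subensembles must be >= 1")


@dataclass
class RiskOutput:
    """Per-patient probability, thresholded label, and scalar uncertainty."""

    prob: np.ndarray
    label: np.ndarray
    uncertainty: np.ndarray

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if not (len(self.prob) == len(self.label) == len(self.uncertainty)):
            raise ValueError("prob, label, uncertainty must have equal length")
        if ((self.prob < 0) | (self.prob > 1)).any():
            raise ValueError("prob must lie in [0, 1]")
        if (self.uncertainty < 0).any():
            raise ValueError("uncertainty must be nonnegative")

    def __len__(self) -> int:
        return len(self.prob)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": np.arange(len(self.prob)),
                "prob": self.prob,
                "label": self.label,
                "uncertainty": self.uncertainty,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RiskOutput":
        df = pd.read_csv(path)
        return cls(df["prob"].to_numpy(), df["label"].to_numpy(), df["uncertainty"].to_numpy())


def feature_frame(cohort: Cohort) -> pd.DataFrame:
    """Extract the model's input matrix from a cohort."""
    missing = [c for c in FEATURE_COLUMNS if c not in cohort.df.columns]
    if missing:
        raise ValueError(f"cohort is missing model feature columns: {missing}")
    X = cohort.df[list(FEATURE_COLUMNS)].copy()
    for col in _CATEGORICAL:
        X[col] = pd.Categorical(
            X[col], categories=sorted(pd.unique(X[col].astype(str)))
        )
    return X


@dataclass
class RiskModel:
    """A fitted boosted-tree risk model with prefix-truncatable predictions."""

    booster: lgb.Booster
    config: ModelConfig
    best_iteration: int
    categories: dict[str, list[str]]
    best_params: dict = field(default_factory=dict)

    def _matrix(self, cohort: Cohort) -> pd.DataFrame:
        X = feature_frame(cohort)
        # categories must match training so codes line up
        for col, cats in self.categories.items():
            X[col] = pd.Categorical(X[col].astype(str), categories=cats)
        return X

    def predict_prefix(self, cohort: Cohort, n_trees: int | None = None) -> np.ndarray:
        """Probability from the first ``n_trees`` boosting iterations."""
        X = self._matrix(cohort)
        n = self.best_iteration if n_trees is None else n_trees
        return np.asarray(self.booster.predict(X, num_iteration=n))

    def save(self, path) -> None:
        payload = {
            "model": self.booster.model_to_string(),
            "config": asdict(self.config),
            "best_iteration": self.best_iteration,
            "categories": self.categories,
            "best_params": self.best_params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "RiskModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        for key in ("depth_grid", "l2_grid"):
            cfg[key] = tuple(cfg[key])
        return cls(
            booster=lgb.Booster(model_str=payload["model"]),
            config=ModelConfig(**cfg),
            best_iteration=payload["best_iteration"],
            categories=payload["categories"],
            best_params=payload["best_params"],
        )


def _lgb_params(depth: int, l2: float, config: ModelConfig) -> dict:
    return {
        "objective": "binary",
        "metric": "binary_logloss",
        "max_depth": depth,
        "num_leaves": min(2**depth, 64) if depth > 0 else 31,
        "lambda_l2": l2,
        "learning_rate": config.learning_rate,
        "seed": config.seed,
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
        "verbosity": -1,
    }


def _fit_one(X_tr, y_tr, X_va, y_va, depth: float, l2: float, config: ModelConfig):
    train_set = lgb.Dataset(X_tr, label=y_tr)
    valid_set = lgb.Dataset(X_va, label=y_va, reference=train_set)
    booster = lgb.train(
        _lgb_params(depth, l2, config),
        train_set,
        num_boost_round=config.max_trees,
        valid_sets=[valid_set],
        callbacks=[lgb.early_stopping(config.early_stopping_rounds, verbose=False)],
    )
    return booster


def train_risk_model(train_cohort: Cohort, config: ModelConfig | None = None) -> RiskModel:
    """Fit the boosted ensemble; tree count by early stopping on log loss."""
    config = config or ModelConfig()
    config.validate()
    y = train_cohort.outcomes
    if len(np.unique(y)) < 2:
        raise ValueError("training outcomes contain a single class; cannot fit")

    X = feature_frame(train_cohort)
    categories = {c: list(X[c].cat.categories) for c in _CATEGORICAL}

    combos = [(d, l2) for d in config.depth_grid for l2 in config.l2_grid]
    best = combos[0]
    if len(combos) > 1:
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        losses = {}
        for depth, l2 in combos:
            fold_losses = []
            for tr_idx, va_idx in skf.split(X, y):
                booster = _fit_one(
                    X.iloc[tr_idx], y[tr_idx], X.iloc[va_idx], y[va_idx], depth, l2, config
                )
                fold_losses.append(booster.best_score["valid_0"]["binary_logloss"])
            losses[(depth, l2)] = float(np.mean(fold_losses))
        best = min(combos, key=lambda c: losses[c])

    X_tr, X_va, y_tr, y_va = train_test_split(
        X,
        y,
        test_size=config.validation_fraction,
        random_state=config.seed,
        stratify=y,
    )
    booster = _fit_one(X_tr, y_tr, X_va, y_va, best[0], best[1], config)
    return RiskModel(
        booster=booster,
        config=config,
        best_iteration=booster.best_iteration or config.max_trees,
        categories=categories,
        best_params={"max_depth": best[0], "lambda_l2": best[1]},
    )


def subensemble_variance(prefix_probs: np.ndarray) -> np.ndarray:
    """Population variance across sub-ensemble probability predictions.

    ``prefix_probs`` is (K, n): one row per boosting prefix.
    """
    prefix_probs = np.asarray(prefix_probs, dtype=float)
    return prefix_probs.var(axis=0, ddof=0)


def predict_with_uncertainty(model: RiskModel, cohort: Cohort) -> RiskOutput:
    """Full-ensemble probability plus virtual-ensemble variance.

    Sub-ensemble k (k = 1..K) is the boosting prefix of the first
    ceil(k*T/K) trees, where T is the early-stopped tree count; the
    uncertainty is the variance of the K prefix probabilities.
    """
    T = model.best_iteration
    K = model.config.n_virtual_subensembles
    prefix_lengths = sorted({-(-k * T) // K for k in range(1, K + 1)})
    prefixes = np.stack(
        [model.predict_prefix(cohort, n_trees=n) for n in prefix_lengths]
    )
    # repeat duplicated prefix lengths (tiny T) so K rows always contribute
    if len(prefix_lengths) < K:
        full = [-(-k * T) // K for k in range(1, K + 1)]
        idx = [prefix_lengths.index(n) for n in full]
        prefixes = prefixes[idx]
    prob = model.predict_prefix(cohort)
    label = (prob >= model.config.decision_threshold).astype(int)
    return RiskOutput(prob=prob, label=label, uncertainty=subensemble_variance(prefixes))


def oracle_predict(
    outcomes: np.ndarray, p_correct: float = 0.95, seed: int = 0
) -> RiskOutput:
    """Look up the true outcome and report it with probability ``p_correct``.

    Each label independently equals the true outcome with probability
    ``p_correct`` and its complement otherwise.  The reported probability is
    ``p_correct`` when the label is positive and ``1 - p_correct`` when
    negative, so ranking metrics see a two-level score; uncertainty is 0.
    """
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError(f"p_correct must be in [0, 1], got {p_correct}")
    outcomes = np.asarray(outcomes, dtype=int)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(outcomes)) < p_correct
    label = np.where(keep, outcomes, 1 - outcomes)
    prob = np.where(label == 1, p_correct, 1.0 - p_correct)
    return RiskOutput(prob=prob, label=label, uncertainty=np.zeros(len(outcomes)))
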