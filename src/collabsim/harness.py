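"""Replicated experiment orchestration.

One replicate = one 75%/25% train/test partition: the risk model (boosted
ensemble or oracle) and all three auditors are fit on the training portion
only, and six scenarios are scored on the test portion:

* ``AI`` — the model alone;
* ``Human`` — the clinician's unaided assessment;
* ``CollaborationAll`` — simulated clinician shown every prediction;
* ``Collaboration1/2/3`` — simulated clinician with auditor-driven
  suppression (error/logistic, error/pruned-tree, uncertainty/pruned-tree).

The full experiment repeats this (including data generation or
re-partitioning, and model training) ``n_replicates`` times (default 30),
reports per-scenario means with 95% confidence intervals, and fills
pairwise one-sided Mann-Whitney p-value matrices — performance tested as
"row's median AUROC exceeds column's", fairness as "row's median summed
AAOD is below column's".
"""

from __future__ import annotations

import itertools
import json
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .auditors import (
    CANONICAL_SCENARIOS,
    AuditorSpec,
    audit,
    auditor_features,
    build_auditor_training_set,
    train_auditor,
)
from .cohort import Cohort, CohortSpec, generate_cohort, read_cohort
from .collaboration import BehaviorConfig, simulate_collaboration
from .metrics import METRIC_NAMES, MetricsReport, evaluate
from .predictors import ModelConfig, RiskOutput, oracle_predict, predict_with_uncertainty, train_risk_model

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "SCENARIOS",
    "run_replicate",
    "run_experiment",
    "sensitivity_analysis",
    "mann_whitney_one_sided",
]

SCENARIOS = ("AI", "Human", "CollaborationAll", "Collaboration1", "Collaboration2", "Collaboration3")

SUPPRESSION_SCENARIOS = tuple(CANONICAL_SCENARIOS)


def _derive_seed(*parts) -> int:
    """Deterministic child seed below 2**31 from heterogeneous parts."""
    ints = [
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) % (2**31) for p in parts
    ]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    task: str = "triage"
    cohort_spec: CohortSpec | None = None
    cohort_path: str | None = None
    model_config: ModelConfig = field(default_factory=ModelConfig)
    behavior_config: BehaviorConfig = field(default_factory=BehaviorConfig)
    auditor_specs: dict = field(
        default_factory=lambda: {
            name: AuditorSpec(strategy=strategy, family=family)
            for name, (strategy, family) in CANONICAL_SCENARIOS.items()
        }
    )
    ai_kind: str = "gbt"  # or "oracle"
    oracle_p_correct: float = 0.95
    train_fraction: float = 0.75
    n_replicates: int = 30
    ci_level: float = 0.95
    ci_method: str = "percentile"  # or "t"
    seed: int = 0
    sensitivity_rates: tuple[float, ...] = (0.0, 0.1, 0.2, 0.4, 0.8)

    def validate(self) -> None:
        if self.task not in ("triage", "discharge"):
            raise ValueError(f"unknown task {self.task!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.n_replicates < 2:
            raise ValueError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if self.ai_kind not in ("gbt", "oracle"):
            raise ValueError(f"ai_kind must be 'gbt' or 'oracle', got {self.ai_kind!r}")
        if self.cohort_spec is None and self.cohort_path is None:
            raise ValueError("one of cohort_spec or cohort_path is required")
        if self.cohort_spec is not None and self.cohort_spec.task != self.task:
            raise ValueError(
                f"cohort_spec.task {self.cohort_spec.task!r} does not match task {self.task!r}"
            )
        if self.ci_method not in ("percentile", "t"):
            raise ValueError(f"ci_method must be 'percentile' or 't', got {self.ci_method!r}")


@dataclass
class ExperimentReport:
    per_replicate: pd.DataFrame  # columns: replicate, scenario, metric, value
    aggregate: pd.DataFrame  # columns: scenario, metric, mean, ci_lo, ci_hi
    pvalues: dict[str, pd.DataFrame]  # metric -> 6x6 one-sided p matrix

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_replicate.to_csv(out / "per_replicate.csv", index=False)
        agg = {
            scenario: {
                row["metric"]: {"mean": row["mean"], "ci_lo": row["ci_lo"], "ci_hi": row["ci_hi"]}
                for _, row in group.iterrows()
            }
            for scenario, group in self.aggregate.groupby("scenario")
        }
        with open(out / "aggregate.json", "w") as fh:
            json.dump(agg, fh, indent=2)
        for metric, matrix in self.pvalues.items():
            matrix.to_csv(out / f"pvalues_{metric}.csv")

    def scenario_values(self, scenario: str, metric: str) -> np.ndarray:
        df = self.per_replicate
        mask = (df["scenario"] == scenario) & (df["metric"] == metric)
        return df.loc[mask].sort_values("replicate")["value"].to_numpy()


def mann_whitney_one_sided(a, b, alternative: str = "greater") -> float:
    """One-sided Mann-Whitney U p-value.

    Exact by permutation enumeration (midrank-tie-aware) when both samples
    have at most 8 observations; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    if alternative == "less":
        return mann_whitney_one_sided(b, a, "greater")

    def u_stat(x: np.ndarray, y: np.ndarray) -> float:
        diff = x[:, None] - y[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    if len(a) <= 8 and len(b) <= 8:
        pooled = np.concatenate([a, b])
        n, m = len(a), len(b)
        u_obs = u_stat(a, b)
        count = total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = u_stat(pooled[mask], pooled[~mask])
            count += u >= u_obs - 1e-12
            total += 1
        return count / total

    res = scipy.stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def _split_indices(n: int, train_fraction: float, outcomes: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(train_fraction * n))
    for attempt in range(10):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if len(np.unique(outcomes[tr])) == 2 and len(np.unique(outcomes[te])) == 2:
            if attempt > 0:
                warnings.warn(f"resampled split {attempt} time(s) to get both classes")
            return tr, te
    raise ValueError("could not find a split with both outcome classes in train and test")


def _ai_outputs(train: Cohort, test: Cohort, config: ExperimentConfig, seed: int):
    if config.ai_kind == "oracle":
        train_out = oracle_predict(train.outcomes, config.oracle_p_correct, seed=_derive_seed(seed, "oracle-train"))
        test_out = oracle_predict(test.outcomes, config.oracle_p_correct, seed=_derive_seed(seed, "oracle-test"))
        return train_out, test_out
    model = train_risk_model(train, replace(config.model_config, seed=_derive_seed(seed, "model")))
    return predict_with_uncertainty(model, train), predict_with_uncertainty(model, test)


def fit_auditors(
    train_out: RiskOutput,
    train_human_binary: np.ndarray,
    train_outcomes: np.ndarray,
    specs: dict,
    seed: int,
) -> dict:
    """Fit one auditor per suppression scenario on training-set outputs only."""
    fitted = {}
    for name, spec in specs.items():
        if hasattr(spec, "predict"):  # pre-fitted auditor injected (e.g. constant)
            fitted[name] = spec
            continue
        spec = replace(spec, seed=_derive_seed(seed, name))
        X, labels = build_auditor_training_set(
            train_out, train_human_binary, train_outcomes, spec.strategy
        )
        fitted[name] = train_auditor(X, labels, spec)
    return fitted


def run_replicate(
    cohort: Cohort, config: ExperimentConfig, replicate_seed: int
) -> dict[str, MetricsReport]:
    """Run one split: fit on train, evaluate the six scenarios on test."""
    config.validate()
    rng = np.random.default_rng(replicate_seed)
    outcomes = cohort.outcomes
    tr_idx, te_idx = _split_indices(len(cohort), config.train_fraction, outcomes, rng)
    train, test = cohort.subset(tr_idx), cohort.subset(te_idx)

    train_out, test_out = _ai_outputs(train, test, config, replicate_seed)
    auditors = fit_auditors(
        train_out, train.human_binary(), train.outcomes, config.auditor_specs, replicate_seed
    )
    test_features = auditor_features(test_out, test.human_binary())
    # one behavior seed per replicate: acceptance coins are shared across
    # scenarios, so suppression is the only thing that differs between them
    behavior = replace(config.behavior_config, seed=_derive_seed(replicate_seed, "behavior"))

    groups = test.group_attributes()
    y = test.outcomes
    results: dict[str, MetricsReport] = {}
    results["AI"] = evaluate(test_out.prob, test_out.label, y, groups)
    results["Human"] = evaluate(test.human_score(), test.human_binary(), y, groups)

    collab_all = simulate_collaboration(test, test_out, None, behavior)
    results["CollaborationAll"] = evaluate(collab_all.final_score(), collab_all.final_binary(), y, groups)
    for name in config.auditor_specs:
        verdict = audit(auditors[name], test_features)
        collab = simulate_collaboration(test, test_out, verdict, behavior)
        results[name] = evaluate(collab.final_score(), collab.final_binary(), y, groups)
    return results


def _aggregate(per_replicate: pd.DataFrame, ci_level: float, method: str) -> pd.DataFrame:
    rows = []
    alpha = 1.0 - ci_level
    for (scenario, metric), grp in per_replicate.groupby(["scenario", "metric"], sort=False):
        v = grp["value"].to_numpy()
        mean = float(v.mean())
        if method == "percentile":
            lo, hi = np.quantile(v, [alpha / 2, 1 - alpha / 2])
        else:
            sem = v.std(ddof=1) / np.sqrt(len(v))
            t = scipy.stats.t.ppf(1 - alpha / 2, df=len(v) - 1)
            lo, hi = mean - t * sem, mean + t * sem
        rows.append(
            {"scenario": scenario, "metric": metric, "mean": mean, "ci_lo": float(lo), "ci_hi": float(hi)}
        )
    return pd.DataFrame(rows)


def _pvalue_matrices(per_replicate: pd.DataFrame) -> dict[str, pd.DataFrame]:
    tests = {"auroc": "greater", "aaod_sum": "less"}
    out = {}
    for metric, alternative in tests.items():
        of_metric = per_replicate[per_replicate["metric"] == metric]
        samples = {
            s: of_metric.loc[of_metric["scenario"] == s, "value"].to_numpy()
            for s in SCENARIOS
        }
        matrix = pd.DataFrame(np.ones((len(SCENARIOS), len(SCENARIOS))), index=SCENARIOS, columns=SCENARIOS)
        for r in SCENARIOS:
            for c in SCENARIOS:
                if r != c:
                    matrix.loc[r, c] = mann_whitney_one_sided(samples[r], samples[c], alternative)
        out[metric] = matrix
    return out


def _replicate_cohort(config: ExperimentConfig, replicate: int, base: Cohort | None) -> Cohort:
    if base is not None:
        return base
    spec = replace(config.cohort_spec, seed=_derive_seed(config.seed, "cohort", replicate))
    return generate_cohort(spec)


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentReport:
    """Run the replicated study; a fresh synthetic cohort per replicate when
    a spec is given, re-partitioning a fixed cohort when a file is given."""
    config.validate()
    base = read_cohort(config.cohort_path) if config.cohort_path else None
    rows = []
    try:
        for rep in range(config.n_replicates):
            cohort = _replicate_cohort(config, rep, base)
            results = run_replicate(cohort, config, _derive_seed(config.seed, "replicate", rep))
            for scenario, report in results.items():
                for metric, value in report.to_dict().items():
                    rows.append(
                        {"replicate": rep, "scenario": scenario, "metric": metric, "value": value}
                    )
    except Exception:
        if out_dir is not None and rows:  # persist whatever finished
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            pd.DataFrame(rows).to_csv(Path(out_dir) / "per_replicate_partial.csv", index=False)
        raise
    per_replicate = pd.DataFrame(rows)
    report = ExperimentReport(
        per_replicate=per_replicate,
        aggregate=_aggregate(per_replicate, config.ci_level, config.ci_method),
        pvalues=_pvalue_matrices(per_replicate),
    )
    if out_dir is not None:
        report.save(out_dir)
    return report


def sensitivity_analysis(config: ExperimentConfig, out_dir=None) -> dict[float, ExperimentReport]:
    """Re-run the experiment across base acceptance rates with shared
    replicate seeds, for paired comparisons."""
    config.validate()
    if not config.sensitivity_rates:
        raise ValueError("sensitivity_rates must be nonempty")
    reports = {}
    for rate in config.sensitivity_rates:
        rate_config = replace(
            config, behavior_config=replace(config.behavior_config, base_accept_rate=rate)
        )
        sub_dir = None if out_dir is None else Path(out_dir) / f"rate_{rate:g}"
        reports[rate] = run_experiment(rate_config, out_dir=sub_dir)
    return reports
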