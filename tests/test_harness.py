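"""Experiment orchestration: replicates, aggregation, hypothesis tests."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from collabsim import (
    ConstantAuditor,
    ExperimentConfig,
    mann_whitney_one_sided,
    run_experiment,
    run_replicate,
    sensitivity_analysis,
)
from collabsim.cohort import CohortSpec, discharge_spec
from collabsim.harness import SCENARIOS, fit_auditors, _derive_seed
from collabsim.auditors import audit, auditor_features
from collabsim.predictors import oracle_predict
from collabsim.collaboration import BehaviorConfig
from dataclasses import replace


def small_config(task="triage", **overrides):
    from collabsim.predictors import ModelConfig

    spec = CohortSpec(n_patients=3000) if task == "triage" else discharge_spec(n_patients=3000)
    base = dict(
        task=task,
        cohort_spec=spec,
        model_config=ModelConfig(max_trees=120, early_stopping_rounds=12, seed=0),
        n_replicates=3,
        seed=17,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


class TestMannWhitney:
    def test_exact_small_sample_enumeration(self):
        assert mann_whitney_one_sided([10, 11, 12], [1, 2, 3], "greater") == pytest.approx(0.05)

    def test_identical_samples_give_no_evidence(self):
        p = mann_whitney_one_sided([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], "greater")
        assert p > 0.4

    def test_swap_and_flip_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(6), rng.random(5)
        assert mann_whitney_one_sided(a, b, "greater") == pytest.approx(
            mann_whitney_one_sided(b, a, "less")
        )

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(30) + 0.1, rng.random(25)
        expected = mannwhitneyu(a, b, alternative="greater", method="asymptotic").pvalue
        assert mann_whitney_one_sided(a, b, "greater") == pytest.approx(float(expected))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_one_sided([], [1.0], "greater")


class TestRunReplicate:
    def test_constant_auditors_hit_the_two_limits(self, triage_cohort, fast_model_config):
        config = small_config(
            model_config=fast_model_config,
            auditor_specs={
                "Collaboration1": ConstantAuditor(1),
                "Collaboration2": ConstantAuditor(0),
                "Collaboration3": ConstantAuditor(1),
            },
        )
        results = run_replicate(triage_cohort, config, replicate_seed=23)
        human = results["Human"].to_dict()
        all_shown = results["CollaborationAll"].to_dict()
        assert results["Collaboration1"].to_dict() == human  # full suppression
        assert results["Collaboration3"].to_dict() == human
        assert results["Collaboration2"].to_dict() == all_shown  # no suppression

    def test_oracle_collaboration_beats_human_on_discharge(self):
        cohort_spec = discharge_spec(n_patients=2000, fraction_meeting_acceptance_criteria=1.0, seed=2)
        from collabsim.cohort import generate_cohort

        cohort = generate_cohort(cohort_spec)
        config = small_config(
            task="discharge",
            cohort_spec=cohort_spec,
            ai_kind="oracle",
            oracle_p_correct=1.0,
            behavior_config=BehaviorConfig(base_accept_rate=1.0),
        )
        results = run_replicate(cohort, config, replicate_seed=3)
        # universal acceptance of a perfect AI only converts missed admissions
        assert results["CollaborationAll"].auroc >= results["Human"].auroc

    def test_auditors_never_see_test_outcomes(self, discharge_cohort, fast_model_config):
        """Verdicts on the test set depend on test features only."""
        from collabsim.predictors import predict_with_uncertainty, train_risk_model

        rng = np.random.default_rng(4)
        idx = rng.permutation(len(discharge_cohort))
        train = discharge_cohort.subset(idx[:4500])
        test = discharge_cohort.subset(idx[4500:])
        model = train_risk_model(train, fast_model_config)
        train_out = predict_with_uncertainty(model, train)
        config = small_config(task="discharge")
        auditors = fit_auditors(
            train_out, train.human_binary(), train.outcomes, config.auditor_specs, seed=9
        )
        test_out = predict_with_uncertainty(model, test)
        features = auditor_features(test_out, test.human_binary())
        before = {k: audit(a, features).suppress.copy() for k, a in auditors.items()}
        test.df["outcome"] = 1 - test.df["outcome"]  # flip every test outcome
        features_after = auditor_features(test_out, test.human_binary())
        for k, a in auditors.items():
            np.testing.assert_array_equal(before[k], audit(a, features_after).suppress)


class TestRunExperiment:
    def test_report_shape_and_determinism(self, tmp_path):
        config = small_config(n_replicates=2)
        r1 = run_experiment(config, out_dir=tmp_path / "report")
        r2 = run_experiment(config)
        assert r1.per_replicate.equals(r2.per_replicate)
        assert (tmp_path / "report" / "per_replicate.csv").exists()
        assert (tmp_path / "report" / "aggregate.json").exists()
        assert (tmp_path / "report" / "pvalues_auroc.csv").exists()
        counts = r1.per_replicate.groupby("scenario")["replicate"].nunique()
        assert set(counts.index) == set(SCENARIOS)
        assert (counts == 2).all()

    def test_ci_contains_mean(self):
        report = run_experiment(small_config(n_replicates=3))
        agg = report.aggregate
        assert ((agg["ci_lo"] <= agg["mean"] + 1e-12) & (agg["mean"] <= agg["ci_hi"] + 1e-12)).all()

    def test_pvalue_matrices_are_probabilities(self):
        report = run_experiment(small_config(n_replicates=3))
        for matrix in report.pvalues.values():
            assert ((matrix.values >= 0) & (matrix.values <= 1)).all()
            assert list(matrix.index) == list(SCENARIOS)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_replicates"):
            small_config(n_replicates=1).validate()
        with pytest.raises(ValueError, match="cohort_spec.task"):
            small_config(task="discharge", cohort_spec=CohortSpec()).validate()


class TestSensitivity:
    def test_singleton_rate_reproduces_main_experiment(self):
        config = small_config(n_replicates=2, sensitivity_rates=(0.2,))
        main = run_experiment(config)
        sweep = sensitivity_analysis(config)
        assert sweep[0.2].per_replicate.equals(main.per_replicate)

    def test_zero_rate_without_criteria_collapses_to_human(self):
        spec = CohortSpec(n_patients=3000, fraction_meeting_acceptance_criteria=0.0, seed=6)
        config = small_config(cohort_spec=spec, n_replicates=2, sensitivity_rates=(0.0,))
        report = sensitivity_analysis(config)[0.0]
        human = report.per_replicate[report.per_replicate.scenario == "Human"]
        for scenario in ("CollaborationAll", "Collaboration1", "Collaboration2", "Collaboration3"):
            other = report.per_replicate[report.per_replicate.scenario == scenario]
            np.testing.assert_allclose(other["value"].to_numpy(), human["value"].to_numpy())

    def test_oracle_collaboration_auroc_monotone_in_rate(self):
        config = small_config(
            task="discharge",
            cohort_spec=discharge_spec(n_patients=2000),
            ai_kind="oracle",
            oracle_p_correct=1.0,
            n_replicates=2,
            sensitivity_rates=(0.0, 0.5, 1.0),
        )
        sweep = sensitivity_analysis(config)
        aurocs = [
            sweep[r].scenario_values("CollaborationAll", "auroc").mean() for r in (0.0, 0.5, 1.0)
        ]
        assert aurocs[0] <= aurocs[1] + 1e-12 <= aurocs[2] + 2e-12


def test_derived_seeds_are_stable_and_bounded():
    s1 = _derive_seed(7, "replicate", 3)
    s2 = _derive_seed(7, "replicate", 3)
    assert s1 == s2 and 0 <= s1 < 2**31
    assert _derive_seed(7, "replicate", 4) != s1
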