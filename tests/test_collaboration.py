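"""Behavioral rules 1 and 2 and the collaboration simulator."""

import numpy as np
import pytest

from collabsim import (
    BehaviorConfig,
    RiskOutput,
    SuppressionVerdict,
    acceptance_draws,
    meets_acceptance_criteria,
    oracle_predict,
    rule1_accepts,
    rule2_override,
    simulate_collaboration,
)

from conftest import make_cohort


def _ai(labels):
    labels = np.asarray(labels, int)
    prob = np.where(labels == 1, 0.9, 0.1)
    return RiskOutput(prob=prob, label=labels, uncertainty=np.zeros(len(labels)))


def _record(**overrides):
    base = {"age": 40, "n_medications": 1, "n_chronic_conditions": 1, "chief_complaint": "headache"}
    base.update(overrides)
    return base


class TestRule1:
    def test_each_criterion_forces_acceptance(self):
        config = BehaviorConfig(base_accept_rate=0.0)
        rng = np.random.default_rng(0)
        assert rule1_accepts(_record(age=70), config, rng)
        assert rule1_accepts(_record(n_medications=5), config, rng)
        assert rule1_accepts(_record(n_chronic_conditions=5), config, rng)
        assert rule1_accepts(_record(chief_complaint="chest pain"), config, rng)

    def test_age_threshold_is_exclusive(self):
        config = BehaviorConfig(base_accept_rate=0.0)
        rng = np.random.default_rng(0)
        assert not rule1_accepts(_record(age=65), config, rng)
        assert rule1_accepts(_record(age=66), config, rng)

    def test_zero_rate_non_criteria_never_accepts(self):
        config = BehaviorConfig(base_accept_rate=0.0)
        rng = np.random.default_rng(0)
        assert not any(rule1_accepts(_record(), config, rng) for _ in range(200))

    def test_base_rate_recovered_on_non_criteria_patients(self):
        config = BehaviorConfig(base_accept_rate=0.2, seed=5)
        draws = acceptance_draws(config.seed, 10_000)
        accepted = [rule1_accepts(_record(), config, float(u)) for u in draws]
        se = np.sqrt(0.2 * 0.8 / 10_000)
        assert abs(np.mean(accepted) - 0.2) < 3 * se


class TestRule2:
    @pytest.mark.parametrize(
        "esi,expected", [(1, 1), (2, 1), (3, 2), (4, 2), (5, 2)]
    )
    def test_accepted_positive_upgrades_esi(self, esi, expected):
        assert rule2_override("triage", esi, ai_label=1, accepted=True) == expected

    @pytest.mark.parametrize("esi", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("ai_label,accepted", [(0, True), (0, False), (1, False)])
    def test_all_other_cells_leave_esi_unchanged(self, esi, ai_label, accepted):
        assert rule2_override("triage", esi, ai_label, accepted) == esi

    @pytest.mark.parametrize(
        "dispo,ai,accepted,expected",
        [
            ("discharge", 1, True, "admit"),
            ("admit", 1, True, "admit"),
            ("discharge", 0, True, "discharge"),
            ("discharge", 1, False, "discharge"),
            ("admit", 0, True, "admit"),
        ],
    )
    def test_discharge_cells(self, dispo, ai, accepted, expected):
        assert rule2_override("discharge", dispo, ai, accepted) == expected

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="task"):
            rule2_override("icu", 3, 1, True)


class TestSimulateCollaboration:
    def test_full_suppression_reduces_to_human(self, triage_cohort):
        ai = _ai(np.ones(len(triage_cohort), int))
        verdict = SuppressionVerdict(np.ones(len(triage_cohort), int))
        res = simulate_collaboration(triage_cohort, ai, verdict, BehaviorConfig(seed=1))
        np.testing.assert_array_equal(res.final_assessment, triage_cohort.human_assessment())
        assert not res.shown.any() and not res.accepted.any()

    def test_all_negative_ai_is_a_no_op(self, triage_cohort):
        ai = _ai(np.zeros(len(triage_cohort), int))
        res = simulate_collaboration(triage_cohort, ai, None, BehaviorConfig(seed=1))
        np.testing.assert_array_equal(res.final_assessment, triage_cohort.human_assessment())

    def test_selection_law_across_verdicts(self, triage_cohort):
        """Suppressed rows match the all-suppressed run, shown rows the
        unsuppressed run, under shared acceptance draws."""
        n = len(triage_cohort)
        ai = _ai(np.random.default_rng(3).integers(0, 2, n))
        config = BehaviorConfig(seed=7)
        verdict = SuppressionVerdict(np.random.default_rng(4).integers(0, 2, n))
        mixed = simulate_collaboration(triage_cohort, ai, verdict, config)
        none = simulate_collaboration(triage_cohort, ai, None, config)
        full = simulate_collaboration(
            triage_cohort, ai, SuppressionVerdict(np.ones(n, int)), config
        )
        s = verdict.suppress == 1
        np.testing.assert_array_equal(mixed.final_assessment[s], full.final_assessment[s])
        np.testing.assert_array_equal(mixed.final_assessment[~s], none.final_assessment[~s])

    def test_severity_never_relaxed(self, triage_cohort, discharge_cohort):
        for cohort in (triage_cohort, discharge_cohort):
            ai = _ai(np.random.default_rng(5).integers(0, 2, len(cohort)))
            res = simulate_collaboration(cohort, ai, None, BehaviorConfig(seed=2))
            human = cohort.human_score()
            assert (res.final_score() >= human).all()
            if cohort.task == "triage":
                assert (res.final_assessment <= cohort.human_assessment()).all()

    def test_zero_rate_without_criteria_equals_human(self):
        cohort = make_cohort(n=300, outcome=np.random.default_rng(6).integers(0, 2, 300))
        ai = _ai(np.ones(300, int))
        config = BehaviorConfig(base_accept_rate=0.0, seed=3)
        assert not meets_acceptance_criteria(cohort.df, config).any()
        res = simulate_collaboration(cohort, ai, None, config)
        np.testing.assert_array_equal(res.final_assessment, cohort.human_assessment())

    def test_oracle_acceptance_admits_true_positive_discharges(self):
        # 40 patients spanning the (disposition x outcome) cells
        y = np.array([0, 1] * 20)
        dispo = np.array(["discharge", "admit"] * 10 + ["admit", "discharge"] * 10)
        cohort = make_cohort(n=40, task="discharge", age=70, disposition=dispo, outcome=y)
        ai = oracle_predict(y, p_correct=1.0, seed=0)
        res = simulate_collaboration(cohort, ai, None, BehaviorConfig(base_accept_rate=1.0, seed=4))
        # every patient with a positive outcome ends up admitted
        assert (res.final_assessment[y == 1] == "admit").all()
        # true negatives keep the human call
        np.testing.assert_array_equal(res.final_assessment[y == 0], dispo[y == 0])

    def test_misaligned_inputs_rejected(self, triage_cohort):
        ai = _ai(np.ones(10, int))
        with pytest.raises(ValueError, match="mismatch"):
            simulate_collaboration(triage_cohort, ai, None, BehaviorConfig())
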