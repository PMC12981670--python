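"""Evidence-informed simulation of the clinician's response to ML alerts.

Two behavioral rules, drawn from the clinical-decision-support literature,
govern the simulated clinician:

Rule 1 (who accepts): patients who are elderly (age strictly over 65), on
at least 5 medications, carrying 5 or more chronic conditions, or presenting
with a severe chief complaint have their alert accepted 100% of the time;
for everyone else the alert is accepted with a fixed base rate (default
20%).

Rule 2 (what acceptance changes): the clinician only ever moves toward
greater severity.  An accepted positive prediction upgrades a triage ESI of
2 to 1 and an ESI of 3, 4 or 5 to 2 (ESI 1 is already maximal), and flips a
discharge disposition to admit.  A negative prediction never relaxes the
clinician's assessment.

Acceptance randomness is a counter-based stream keyed by (seed, patient
index), so the same patient draws the same coin regardless of which
predictions are suppressed — suppression limits are then exact identities,
not merely distributional ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .auditors import SuppressionVerdict
from .cohort import Cohort, SEVERE_COMPLAINTS
from .predictors import RiskOutput

__all__ = [
    "BehaviorConfig",
    "CollaborationResult",
    "acceptance_draws",
    "meets_acceptance_criteria",
    "rule1_accepts",
    "rule2_override",
    "simulate_collaboration",
]


@dataclass(frozen=True)
class BehaviorConfig:
    base_accept_rate: float = 0.20
    elderly_age_threshold: int = 65  # exclusive: "over 65"
    polypharmacy_threshold: int = 5  # inclusive: "at least 5"
    chronic_condition_threshold: int = 5  # inclusive: "5 or more"
    severe_complaint_set: frozenset = field(default_factory=lambda: SEVERE_COMPLAINTS)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.base_accept_rate <= 1.0:
            raise ValueError(f"base_accept_rate must be in [0, 1], got {self.base_accept_rate}")


@dataclass
class CollaborationResult:
    """Final assessments after the simulated human response."""

    task: str
    final_assessment: np.ndarray  # ESI ints (triage) or 'admit'/'discharge'
    accepted: np.ndarray
    shown: np.ndarray

    def final_score(self) -> np.ndarray:
        """Risk ordering of the final assessment (higher = riskier)."""
        if self.task == "triage":
            return 6.0 - self.final_assessment.astype(float)
        return (self.final_assessment == "admit").astype(float)

    def final_binary(self) -> np.ndarray:
        if self.task == "triage":
            return (self.final_assessment.astype(int) <= 2).astype(int)
        return (self.final_assessment == "admit").astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": np.arange(len(self.final_assessment)),
                "shown": self.shown.astype(int),
                "accepted": self.accepted.astype(int),
                "final_assessment": self.final_assessment,
            }
        )


def acceptance_draws(seed: int, n: int) -> np.ndarray:
    """Uniform(0,1) draw for each patient index, counter-based in (seed, i)."""
    return np.random.Generator(np.random.Philox(key=seed)).random(n)


def meets_acceptance_criteria(df: pd.DataFrame, config: BehaviorConfig) -> np.ndarray:
    """Rule 1's automatic-acceptance mask (elderly / polypharmacy / chronic /
    severe complaint)."""
    return (
        (df["age"].to_numpy() > config.elderly_age_threshold)
        | (df["n_medications"].to_numpy() >= config.polypharmacy_threshold)
        | (df["n_chronic_conditions"].to_numpy() >= config.chronic_condition_threshold)
        | np.isin(df["chief_complaint"].to_numpy(), list(config.severe_complaint_set))
    )


def rule1_accepts(record, config: BehaviorConfig, rng) -> bool:
    """Whether one clinician-patient encounter accepts a shown AI prediction.

    ``record`` is a mapping/Series with age, n_medications,
    n_chronic_conditions and chief_complaint; ``rng`` supplies the uniform
    draw for non-criteria patients (a numpy Generator or a float in [0,1)).
    """
    criteria = (
        record["age"] > config.elderly_age_threshold
        or record["n_medications"] >= config.polypharmacy_threshold
        or record["n_chronic_conditions"] >= config.chronic_condition_threshold
        or record["chief_complaint"] in config.severe_complaint_set
    )
    if criteria:
        return True
    u = rng if isinstance(rng, float) else float(rng.random())
    return u < config.base_accept_rate


def rule2_override(task: str, human_assessment, ai_label: int, accepted: bool):
    """Apply the worse-off-only override to a single assessment."""
    if task == "triage":
        esi = int(human_assessment)
        if not accepted or ai_label != 1:
            return esi
        if esi == 1:
            return 1  # already maximal severity
        return 1 if esi == 2 else 2
    if task == "discharge":
        if not accepted or ai_label != 1:
            return human_assessment
        return "admit"
    raise ValueError(f"unknown task {task!r}")


def _override_vector(task: str, human, ai_label, accepted) -> np.ndarray:
    act = accepted & (ai_label == 1)
    if task == "triage":
        esi = human.astype(int)
        out = esi.copy()
        out[act & (esi == 2)] = 1
        out[act & (esi >= 3)] = 2
        return out
    out = human.astype(object).copy()
    out[act] = "admit"
    return out


def simulate_collaboration(
    cohort: Cohort,
    ai: RiskOutput,
    verdict: SuppressionVerdict | None,
    config: BehaviorConfig | None = None,
) -> CollaborationResult:
    """Produce final assessments under a (possibly suppressed) AI.

    ``verdict=None`` means no suppression: every prediction is shown.
    """
    config = config or BehaviorConfig()
    config.validate()
    n = len(cohort)
    if len(ai) != n:
        raise ValueError(f"length mismatch: cohort has {n} records, AI output {len(ai)}")
    if verdict is not None and len(verdict) != n:
        raise ValueError(
            f"length mismatch: cohort has {n} records, verdict {len(verdict)}"
        )

    shown = np.ones(n, dtype=bool) if verdict is None else verdict.suppress == 0
    criteria = meets_acceptance_criteria(cohort.df, config)
    draws = acceptance_draws(config.seed, n)
    would_accept = criteria | (draws < config.base_accept_rate)
    accepted = shown & would_accept

    human = cohort.human_assessment()
    final = _override_vector(cohort.task, human, ai.label, accepted)
    return CollaborationResult(
        task=cohort.task, final_assessment=final, accepted=accepted, shown=shown
    )
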