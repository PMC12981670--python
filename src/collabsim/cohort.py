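"""Seeded synthetic emergency-department cohorts.

Real studies of human-AI triage collaboration run on restricted-access EHR
extracts.  This module generates tabular cohorts with the same statistical
skeleton — triage vitals, ESI acuity, disposition, utilization counts,
demographics with configurable subgroup disparities, and a binary adverse
outcome — so that every downstream stage (risk model, auditors, behavioral
simulation, fairness metrics) is testable without any data access.

Generation is built around a single latent severity score per patient:

* the outcome is a deterministic threshold of the latent (the threshold is
  solved so the marginal positive rate matches the requested prevalence);
* triage vitals are noisy linear channels of the latent, so a learned model
  can recover it imperfectly;
* the simulated clinician scores the same latent plus Gaussian noise whose
  scale is solved numerically so the clinician's continuous AUROC hits
  ``human_auroc_target``; the ESI (triage) or disposition (discharge) is a
  monotone discretization of that noisy score.

A signed ``subgroup_effect`` shifts the latent of the non-white subgroup and
biases the clinician's perception of it, making equalized-odds fairness
metrics nondegenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "COMPLAINT_CATEGORIES",
    "SEVERE_COMPLAINTS",
    "COHORT_COLUMNS",
]

COMPLAINT_CATEGORIES = (
    "chest pain",
    "shortness of breath",
    "altered mental status",
    "abdominal pain",
    "headache",
    "fever",
    "injury",
    "back pain",
    "nausea",
    "dizziness",
)

#: Complaint categories treated as automatically severe for alert acceptance.
SEVERE_COMPLAINTS = frozenset(
    {"chest pain", "shortness of breath", "altered mental status"}
)

VITAL_COLUMNS = ("heart_rate", "resp_rate", "sbp", "dbp", "spo2", "temperature")

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "race",
    *VITAL_COLUMNS,
    "esi",
    "disposition",
    "chief_complaint",
    "n_prior_ed_visits",
    "n_chronic_conditions",
    "n_medications",
    "outcome",
)

# Fraction of patients assigned each ESI level, from 1 (most urgent) to 5.
DEFAULT_ESI_FRACTIONS = (0.03, 0.12, 0.45, 0.30, 0.10)

Task = Literal["triage", "discharge"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters controlling one synthetic cohort.

    Parameters
    ----------
    task:
        ``"triage"`` (outcome: ICU transfer or death; human assessment: ESI)
        or ``"discharge"`` (outcome: 30-day ED readmission; human
        assessment: disposition).
    n_patients:
        Cohort size.
    prevalence:
        Marginal positive-outcome probability.  Defaults mirror the two
        tasks: ~6.5% adverse outcomes at triage, ~50% readmission.
    human_auroc_target:
        AUROC of the clinician's *continuous* latent assessment against the
        outcome, in (0.5, 1].  Discretization to ESI/disposition can only
        lower the observed AUROC.
    subgroup_effect:
        Signed disparity dial: shifts the non-white subgroup's outcome
        log-risk (latent shift) and biases the clinician's perceived risk
        for that subgroup in the opposite direction.  0 disables both.
    missingness_rate:
        Per-field probability that a vital is recorded as -1 and that a
        demographic field is "other/unknown".
    fraction_meeting_acceptance_criteria:
        Expected fraction of patients meeting at least one automatic
        alert-acceptance criterion (elderly, polypharmacy, >=5 chronic
        conditions, severe chief complaint).
    feature_noise:
        Gaussian noise scale on each vital channel relative to the latent
        signal; larger values make the learned model weaker.
    """

    task: Task = "triage"
    n_patients: int = 20_000
    prevalence: float = 0.065
    human_auroc_target: float = 0.78
    subgroup_effect: float = 0.6
    missingness_rate: float = 0.03
    fraction_meeting_acceptance_criteria: float = 0.35
    feature_noise: float = 3.5
    esi_fractions: tuple[float, ...] = DEFAULT_ESI_FRACTIONS
    seed: int = 0

    def validate(self) -> None:
        if self.task not in ("triage", "discharge"):
            raise ValueError(f"task must be 'triage' or 'discharge', got {self.task!r}")
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not 0.5 < self.human_auroc_target <= 1.0:
            raise ValueError(
                f"human_auroc_target must be in (0.5, 1], got {self.human_auroc_target}"
            )
        for name in ("missingness_rate", "fraction_meeting_acceptance_criteria"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.feature_noise < 0:
            raise ValueError(f"feature_noise must be >= 0, got {self.feature_noise}")
        if len(self.esi_fractions) != 5 or abs(sum(self.esi_fractions) - 1.0) > 1e-9:
            raise ValueError("esi_fractions must be 5 nonnegative values summing to 1")


def discharge_spec(**overrides) -> CohortSpec:
    """Default spec for the discharge/readmission task.

    The human-superior regime: a well-informed clinician (continuous AUROC
    target 0.95) against a model trained on noisy vitals.
    """
    base = dict(
        task="discharge",
        prevalence=0.50,
        human_auroc_target=0.95,
        feature_noise=7.0,
    )
    base.update(overrides)
    return CohortSpec(**base)


def triage_spec(**overrides) -> CohortSpec:
    """Default spec for the triage task (AI-superior regime)."""
    return CohortSpec(**overrides) if overrides else CohortSpec()


@dataclass
class Cohort:
    """A patient table plus its task and demographic partitions."""

    task: Task
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.task == other.task and self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True)
        )

    @property
    def outcomes(self) -> np.ndarray:
        return self.df["outcome"].to_numpy(dtype=int)

    def human_assessment(self) -> np.ndarray:
        """ESI (triage) or disposition string (discharge)."""
        if self.task == "triage":
            return self.df["esi"].to_numpy(dtype=int)
        return self.df["disposition"].to_numpy(dtype=object)

    def human_binary(self) -> np.ndarray:
        """Binarized human call: ESI <= 2 (triage) / admit (discharge)."""
        if self.task == "triage":
            return (self.df["esi"].to_numpy(dtype=int) <= 2).astype(int)
        return (self.df["disposition"].to_numpy() == "admit").astype(int)

    def human_score(self) -> np.ndarray:
        """Risk ordering implied by the human assessment (higher = riskier)."""
        if self.task == "triage":
            return 6.0 - self.df["esi"].to_numpy(dtype=float)
        return (self.df["disposition"].to_numpy() == "admit").astype(float)

    def group_attributes(self) -> dict[str, np.ndarray]:
        """Binary partitions; True marks the *majority* side of each.

        race: white / not white; age: <50 / >=50; gender: male / not male.
        Unknown demographics fall on the minority ("not X") side, so the two
        sides of each partition cover every record exactly once.
        """
        df = self.df
        return {
            "race": (df["race"].to_numpy() == "white"),
            "age": (df["age"].to_numpy() < 50),
            "gender": (df["sex"].to_numpy() == "male"),
        }

    def subset(self, index: np.ndarray) -> "Cohort":
        return Cohort(self.task, self.df.iloc[index].reset_index(drop=True))


def _solve_outcome_threshold(prevalence: float, shift: float, p_min: float) -> float:
    """Threshold t with P(latent > t) = prevalence under the group mixture.

    latent ~ (1 - p_min) N(0,1) + p_min N(shift, 1).
    """

    def excess(t: float) -> float:
        sf = (1 - p_min) * norm.sf(t) + p_min * norm.sf(t - shift)
        return sf - prevalence

    lo, hi = -12.0 - abs(shift), 12.0 + abs(shift)
    return brentq(excess, lo, hi)


def _pairwise_auroc(scores: np.ndarray, y: np.ndarray) -> float:
    # rank-based AUROC (ties count 1/2); equivalent to the trapezoidal sweep
    from scipy.stats import rankdata

    r = rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return (r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _solve_human_noise(
    latent: np.ndarray,
    bias: np.ndarray,
    noise: np.ndarray,
    y: np.ndarray,
    target: float,
) -> float:
    """Noise scale sigma such that AUROC(latent + bias + sigma*noise, y) = target."""
    if target >= 1.0:
        return 0.0

    def gap(sigma: float) -> float:
        return _pairwise_auroc(latent + bias + sigma * noise, y) - target

    lo, hi = 0.0, 1.0
    if gap(lo) <= 0.0:
        # bias alone already puts the clinician below target; best effort
        return 0.0
    while gap(hi) > 0.0:
        hi *= 2.0
        if hi > 1e3:
            return hi
    return brentq(gap, lo, hi, xtol=1e-4)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one synthetic cohort; bit-reproducible for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    # --- demographics -----------------------------------------------------
    sex = rng.choice(["male", "female"], size=n, p=[0.49, 0.51]).astype(object)
    race = rng.choice(["white", "non-white"], size=n, p=[0.65, 0.35]).astype(object)
    sex[rng.random(n) < spec.missingness_rate] = "other/unknown"
    race[rng.random(n) < spec.missingness_rate] = "other/unknown"
    minority = (race != "white").astype(float)

    # --- alert-acceptance criteria skeleton -------------------------------
    # Patients flagged for criteria get exactly one forced criterion; everyone
    # else is drawn from ranges that satisfy none, so the criteria fraction is
    # a Bernoulli draw around the configured value.
    meets = rng.random(n) < spec.fraction_meeting_acceptance_criteria
    which = rng.integers(0, 4, size=n)  # elderly / meds / chronic / complaint

    age = 18 + np.floor(48 * rng.beta(1.8, 2.0, size=n)).astype(int)  # 18..65
    age_mult = (age - 18) / 60.0  # utilization rises with age

    def zip_counts(base: float, cap: int) -> np.ndarray:
        lam = base * (0.5 + 1.5 * age_mult)
        c = rng.poisson(lam)
        c[rng.random(n) < 0.30] = 0
        return np.minimum(c, cap)

    n_meds = zip_counts(2.0, cap=4)
    n_chronic = zip_counts(1.6, cap=4)
    nonsevere = [c for c in COMPLAINT_CATEGORIES if c not in SEVERE_COMPLAINTS]
    complaint = rng.choice(nonsevere, size=n).astype(object)

    elderly = meets & (which == 0)
    age[elderly] = 66 + rng.integers(0, 30, size=int(elderly.sum()))
    poly = meets & (which == 1)
    n_meds[poly] = 5 + rng.poisson(2.5, size=int(poly.sum()))
    chron = meets & (which == 2)
    n_chronic[chron] = 5 + rng.poisson(2.0, size=int(chron.sum()))
    sev = meets & (which == 3)
    complaint[sev] = rng.choice(sorted(SEVERE_COMPLAINTS), size=int(sev.sum()))

    # --- latent severity, outcome -----------------------------------------
    latent = rng.standard_normal(n) + spec.subgroup_effect * minority
    threshold = _solve_outcome_threshold(
        spec.prevalence, spec.subgroup_effect, float(minority.mean())
    )
    outcome = (latent > threshold).astype(int)

    # --- vitals: noisy channels of the latent ------------------------------
    s = spec.feature_noise
    z = lambda: rng.standard_normal(n)  # noqa: E731
    heart_rate = np.round(82 + 16 * latent + 10 * s * z(), 0)
    resp_rate = np.round(16 + 3.5 * latent + 2.5 * s * z(), 0)
    sbp = np.round(126 - 11 * latent + 9 * s * z(), 0)
    dbp = np.round(76 - 7 * latent + 6 * s * z(), 0)
    spo2 = np.minimum(np.round(97.5 - 2.0 * latent + 1.4 * s * z(), 0), 100.0)
    temperature = np.round(36.9 + 0.35 * latent + 0.3 * s * z(), 1)
    n_prior = np.minimum(rng.poisson(np.exp(0.25 * latent) * 0.8), 20)

    vitals = {
        "heart_rate": heart_rate,
        "resp_rate": resp_rate,
        "sbp": sbp,
        "dbp": dbp,
        "spo2": spo2,
        "temperature": temperature,
    }
    for name, values in vitals.items():
        values[rng.random(n) < spec.missingness_rate] = -1.0

    # --- clinician assessment ----------------------------------------------
    perception_bias = -0.5 * spec.subgroup_effect * minority
    noise = rng.standard_normal(n)
    sigma = _solve_human_noise(
        latent, perception_bias, noise, outcome, spec.human_auroc_target
    )
    human = latent + perception_bias + sigma * noise

    # ESI: right-skewed quantile bins of perceived risk, 1 = most urgent.
    cuts = np.quantile(human, np.cumsum(spec.esi_fractions[::-1])[:-1])
    esi = 5 - np.searchsorted(cuts, human, side="right")
    # Disposition: admit iff perceived risk clears the *outcome* threshold,
    # i.e. the clinician admits patients they believe will hit the outcome.
    disposition = np.where(human > threshold, "admit", "discharge").astype(object)

    df = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": age,
            "sex": sex,
            "race": race,
            **vitals,
            "esi": esi.astype(int),
            "disposition": disposition,
            "chief_complaint": complaint,
            "n_prior_ed_visits": n_prior.astype(int),
            "n_chronic_conditions": n_chronic.astype(int),
            "n_medications": n_meds.astype(int),
            "outcome": outcome,
        },
        columns=list(COHORT_COLUMNS),
    )
    return Cohort(spec.task, df)


# --------------------------------------------------------------------------
# serialization

_INT_COLUMNS = (
    "patient_id",
    "age",
    "esi",
    "n_prior_ed_visits",
    "n_chronic_conditions",
    "n_medications",
    "outcome",
)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (missing vitals stay literally ``-1``)."""
    out = cohort.df.copy()
    out.insert(0, "task", cohort.task)
    out.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV, validating the schema and per-row invariants."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError("no records: cohort file is empty") from None
    if len(df) == 0:
        raise ValueError("no records: cohort file has a header but no rows")
    if "task" not in df.columns:
        raise ValueError("malformed cohort file: missing 'task' column")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed cohort file: missing columns {missing}")

    tasks = df["task"].unique()
    if len(tasks) != 1 or tasks[0] not in ("triage", "discharge"):
        raise ValueError(f"malformed cohort file: bad task column values {tasks!r}")

    bad_esi = ~df["esi"].isin([1, 2, 3, 4, 5])
    if bad_esi.any():
        row = int(np.flatnonzero(bad_esi.to_numpy())[0])
        raise ValueError(f"parse error at row {row}: esi={df['esi'].iloc[row]} not in 1..5")
    bad_outcome = ~df["outcome"].isin([0, 1])
    if bad_outcome.any():
        row = int(np.flatnonzero(bad_outcome.to_numpy())[0])
        raise ValueError(f"parse error at row {row}: outcome not in {{0,1}}")

    body = df[list(COHORT_COLUMNS)].copy()
    for col in _INT_COLUMNS:
        body[col] = body[col].astype(int)
    for col in VITAL_COLUMNS:
        body[col] = body[col].astype(float)
    return Cohort(str(tasks[0]), body.reset_index(drop=True))
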