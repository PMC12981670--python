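# Methods

## The model of collaboration

A decision episode has three actors: a clinician who has already committed
an assessment (an ESI acuity score at triage, an admit/discharge call at
discharge), a risk model that emits a probability of the adverse outcome,
and an optional auditor that decides whether the model's prediction is
shown at all. The final assessment is the clinician's, possibly upgraded
in severity by an accepted alert. Collaboration quality is then scored
exactly like any other predictor: the final assessments are converted to a
risk ordering (6 − ESI for triage, admit = 1 for discharge) and compared
to the true outcome.

Two behavioral rules define the clinician's response. Rule 1 models *who*
accepts an alert: acceptance is certain for patients over 65 years old
(strictly greater, following the wording of the underlying alert-fatigue
evidence), patients on at least 5 medications, patients with 5 or more
chronic conditions, and patients with a severe chief complaint; for all
other patients acceptance is Bernoulli with a base rate of 0.20. Rule 2
models *what* acceptance changes: only predictions of a *worse* outcome
are ever acted on. An accepted positive prediction maps ESI 2 → 1 and
ESI 3, 4, 5 → 2; ESI 1 has no more severe value and stays at 1 (the
mapping leaves this cell implicit; we pin it to the identity). At
discharge an accepted positive flips discharge → admit. A shown negative
prediction is a no-op: "accepting" it is observationally identical to
ignoring it, so the two readings are not distinguished.

Acceptance coins are drawn from a counter-based Philox stream keyed by
(seed, patient index). The draw for patient *i* therefore does not depend
on which other predictions were suppressed, which turns the two
suppression limits into exact identities rather than distributional ones:
suppressing everything reproduces the Human scenario metric-for-metric,
and suppressing nothing reproduces CollaborationAll. The same property
means all six scenarios within a replicate share one acceptance stream —
a deliberate choice (the alternative, independent coins per scenario,
would only add variance without changing any expectation).

## Predictors

The realistic model is a LightGBM gradient-boosted tree ensemble:
binary log-loss objective, up to 1000 trees, learning rate 0.1, with 15%
of the training split held out to pick the tree count by early stopping
(patience 30 rounds). Hyperparameters (`max_depth`, L2 leaf
regularization) can be grid-searched with stratified 3-fold CV; the
default grids are singletons (depth 3, λ₂ = 1.0) because the synthetic
cohorts are low-dimensional and the search adds cost without changing any
qualitative result. Training is single-threaded and deterministic for a
fixed seed. Model inputs are demographics, vitals, chief complaint and
utilization counts — never the human assessment or the outcome.

Uncertainty is epistemic-style, from a *virtual ensemble*: with T fitted
trees and K = 10 sub-ensembles, sub-ensemble k is the boosting prefix of
the first ⌈kT/K⌉ trees, and the reported uncertainty is the population
variance of the K prefix probabilities. Prefixes are overlapping
truncations of one model, so no retraining is involved. When T < K some
prefixes coincide; they are still counted K times so the estimator's
definition does not change with T. The variance of p equals the variance
of 1 − p, so the measure is invariant to relabeling the positive class.

The oracle predictor returns the true label with probability 0.95
(independently per patient), reports probability 0.95 for positive calls
and 0.05 for negative calls so ranking metrics see a two-level score, and
has uncertainty identically 0 — under the median-split discretization
below, an all-zero uncertainty vector yields no "high" bin, so
uncertainty-driven suppression correctly degenerates to no suppression
for the oracle.

## Auditors

An auditor is trained on the risk model's *training-set* outputs — the
predicted probability, the binarized human assessment (ESI ≤ 2 at triage,
admit at discharge), and the uncertainty — and never sees held-out
outcomes; at test time it consumes the same three features only. Labels
are either model error (thresholded label ≠ outcome) or high uncertainty.
"High" is a median split: values strictly above the median are high, ties
go to low, so with distinct values the bins differ in size by at most one
and a constant vector is all-low.

The two families are an L2-penalized logistic regression with
regularization coefficient α = 1 (i.e. sklearn C = 1/α) and a decision
tree pruned by cost-complexity, with the pruning strength chosen by
stratified cross-validated accuracy over the tree's own pruning path
(subsampled to at most 20 candidate alphas). The pruned tree plays the
role of a tree-based uncertainty auditing framework; its subgroup-typing
machinery is out of scope here, where only its function — a pruned tree
predicting error or high uncertainty — matters. Whether that framework's
original implementation consumed raw patient features rather than the
three-feature summary is not documented; we use the same three features
for both families so the comparison isolates the model class. If the
auditor's training labels are single-class (e.g. a perfect model has no
errors), a constant auditor predicting that class is returned, which
downstream reduces collaboration to the correct limit scenario.

## Synthetic cohorts

Each patient carries a scalar latent severity u ~ N(0, 1), shifted by
`subgroup_effect` for non-white patients. The outcome is the
deterministic indicator u > t, with t solved (Brent's method on the
two-component normal-mixture survival function) so the marginal positive
rate equals the requested prevalence; the observed positive count is then
binomial around it. Vitals are affine channels of u with Gaussian noise
scaled by `feature_noise`; counts of prior visits rise with u; chronic
conditions and medications follow zero-inflated, age-increasing Poisson
draws. Missing vitals are encoded −1 and unknown demographics
"other/unknown", at rate `missingness_rate`.

The clinician's perceived risk is h = u − 0.5·`subgroup_effect`·𝟙[minority]
+ σε, with σ solved by root-finding so the empirical AUROC of h against
the outcome equals `human_auroc_target` (σ = 0 at target 1.0, where h
orders outcomes perfectly). ESI is a quantile discretization of h with a
right-skewed default marginal (3/12/45/30/10% for ESI 1…5; no published
marginal exists for the real cohorts, so these are plausible placeholders
and live in config). The disposition is admit iff h exceeds the *outcome*
threshold t — the clinician admits exactly the patients they believe will
hit the outcome — which makes the noiseless clinician's disposition
coincide with the outcome. Under ESI the 5-level discretization caps the
observable AUROC below 1 whenever a bin straddles the outcome quantile;
this is a property of ESI itself, not a defect of the dial.

Alert-acceptance criteria are generated structurally: a Bernoulli flag
with the configured criteria fraction picks the patients who meet at
least one criterion; each of those is forced into exactly one uniformly
chosen criterion (elderly / ≥5 medications / ≥5 chronic conditions /
severe complaint), and everyone else is drawn from ranges satisfying
none. The observed criteria fraction is therefore binomial around the
configured value by construction.

### Default study conditions

Defaults are fixed per task, chosen once to realize the two regimes the
study design contrasts:

| parameter | triage | discharge |
|---|---|---|
| prevalence | 0.065 | 0.50 |
| human_auroc_target (continuous) | 0.78 | 0.95 |
| feature_noise | 3.5 | 7.0 |
| subgroup_effect | 0.6 | 0.6 |
| criteria fraction | 0.35 | 0.35 |

At triage these yield a learned-model test AUROC near 0.89 against an
ESI-based clinician near 0.74 (the AI-superior regime); at discharge a
model near 0.74 against a disposition-based clinician near 0.87 (the
human-superior regime). The generator emulates the *statistical
structure* the analysis needs — prevalence, tunable human skill,
learnable features, subgroup disparities, criteria mix — not any real
hospital's marginals, feature correlations, temporal structure or coding
practices; passing tests show the pipeline behaves correctly under these
conditions, not that real-data effect sizes would match.

## Metrics

AUROC is the full threshold sweep with ties counted ½ (equivalently,
pairwise concordance; the test suite checks this equivalence by brute
force). AUPRC is interpolation-free average precision. F1 uses the
binarizations above, with 0/0 defined as 0. AAOD is computed per
partition — race white/not-white, age <50/≥50, gender male/not-male, the
first-named side as majority, unknowns on the minority side so the
partition covers every record — and summed over the three partitions for
the headline fairness value. A partition side with no positives (or no
negatives) makes TPR (FPR) undefined; this raises an error naming the
side and class rather than silently reporting 0.

## Experiment and statistics

One replicate: a uniformly random 75/25 split (resampled up to 10 times,
with a warning, if a side lacks an outcome class), model and all three
auditors fit on the training side, six scenarios scored on the test side.
The full experiment runs 30 replicates; when a cohort spec is given, each
replicate also draws a fresh cohort (mirroring a study design that
re-partitions real data — both resampling modes are supported, and
re-splitting is the default when a cohort file is supplied). Aggregates
are means with 95% percentile confidence intervals over replicates
(t-based intervals are available via `ci_method="t"`; the interval method
is otherwise an open choice). Pairwise comparisons use one-sided
Mann-Whitney U tests — AUROC tested as "row's median exceeds column's",
summed AAOD as "row's median is below" — exact by enumeration of all
C(n+m, n) assignments (midrank U, tie-aware) when both samples have ≤ 8
observations, and the tie-corrected normal approximation otherwise. Raw
p-values are reported without multiple-testing correction, matching the
presentation style of pairwise matrices; a Holm correction can be applied
downstream from the per-replicate table if desired.

All randomness flows from one master seed through CRC-32-keyed
`SeedSequence` derivations (per replicate, per component), so a config
plus seed fixes every number in the report, and child seeds stay below
2³¹.

## Problem sizes and numerical choices

The acceptance checks run the directional-regime experiments at 30
replicates of 20,000-patient cohorts per task — large enough that the
Mann-Whitney tests at the 0.05 level resolve the regime orderings, small
enough to iterate on a laptop. Unit tests use 2,000–6,000-patient
cohorts and a 120–150-tree model configuration. Degenerate inputs are
handled explicitly: single-class training outcomes, empty uncertainty
vectors, unfitted auditors, misaligned lengths, and out-of-range ESI
values in cohort files all raise errors naming the offending field or
row.

## Known limitations

* The behavioral model is static: no trust dynamics, no learning from
  repeated exposure, no interpretation of an alert's *absence*.
* Suppression has no budget or per-subgroup rate constraint.
* The latent-severity construction gives every feature a monotone
  relationship to risk; real EHR features are messier, so auditor
  difficulty here is optimistic.
* Oracle uncertainty is identically zero, so the uncertainty-auditor
  scenario is only informative for the learned model.
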