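# Methods

This note documents the models, defaults and numerical choices behind
`severitree`: what the synthetic-cohort generator emulates, how the CART
engine and the rule-mining ensemble are defined, how rules are scored, and
where the design was genuinely open.

## Severity stratification

Both instruments score each item 0–3; totals span 0–21 (GAD-7) and 0–27
(PHQ-9).  The tripartite outcome is a deterministic function of the total:
minimal/mild below 10, moderate in [10, 15) for GAD-7 and [10, 20) for
PHQ-9 (displayed as "moderate or moderately severe"), severe at or above
15 / 20.  Cutoffs live in `ScaleSpec`, so alternative stratifications (for
instance the common single clinical cutoff of 10) are configuration, not
code.  Tables are validated row-wise: any missing, non-integer or
out-of-range item response drops the row (incomplete records are excluded),
and the count of dropped rows is reported.  Validation is idempotent.

## Synthetic cohorts

No respondent-level dataset ships with the package; the generator emulates
the statistical structure the analysis assumes.

**Item model.**  A latent severity trait θ ~ N(0, 1) drives every item
through a graded (cumulative-logit) response model,
P(X_ij ≥ k | θ_i) = logistic(a_j (θ_i − b_jk)), k = 1..3, the simplest
ordinal model with per-item discrimination.  Sampling uses a single uniform
draw per (respondent, item) compared against the three cumulative
probabilities, so the cumulative-probability monotonicity is structural.

**Hub items.**  Items GAD 2/4 and PHQ 2/4/8 default to discrimination
a = 2.0; all other items to a = 0.8.  The hubs are the intended ground
truth for rule-recovery experiments: mined top rules should be built from
them.

**Default thresholds.**  One triple for hub items and one for the others,
frozen after a coarse development grid search:

| scale | hub b | non-hub b |
|---|---|---|
| GAD-7 | (−1.6, −0.4, 0.6) | (−2.6, −0.4, 1.8) |
| PHQ-9 | (−0.9, 0.0, 0.8) | (−1.8, −0.4, 1.0) |

Two goals shaped the search.  First, class prevalences roughly matching the
reference survey's prototypical-tree class shares (≈ 0.28/0.36/0.36 for
GAD-7; ≈ 0.27/0.48/0.25 for PHQ-9); the calibrated defaults achieve
≈ 0.28/0.44/0.29 and ≈ 0.21/0.55/0.24 — the PHQ-9 severe class cannot be
pushed further past its 20-of-27 cutoff without collapsing the minimal
class, a structural limit of the model.  Exact prevalences are not a
contract.  Second, genuine hub dominance: because the outcome is defined
from the item total, *noise* variance in a non-hub item is itself
predictive (the item is part of the sum).  With one shared threshold triple
the non-hub category noise is large enough that non-hub items intrude into
mined rules in roughly a third of small-cohort runs, defeating the point of
the hub design.  The wide non-hub spread concentrates those items'
conditional distributions (low category noise) while the narrow hub spread
lets the hubs track the trait finely, raising the hub-versus-non-hub Gini
gain margin at the first two tree levels from ≈ 1.2× to ≈ 1.65× (GAD-7,
measured on n = 120,000 cohorts).

**Demographics.**  Sex, skin colour, education and age group are drawn from
marginals fixed at the reference survey's exact category counts over
20,585 respondents (e.g. female 18,844/20,585 ≈ 91.5%).  Age is drawn
within the sampled band from a truncated normal; band locations are
anchored at band midpoints (62.5 for the right-skewed open ">60" band,
truncated at 80) plus a single global shift, with one shared within-band
SD.  The shift and SD are moment-matched at config time (exact truncated
moments via `scipy.stats.truncnorm`, Brent root-finding for the mean,
bounded scalar minimisation for the SD) to the survey's printed overall
moments, mean 41.1 and SD 12.9; the achieved mixture reproduces both to
well under 0.1.  Demographics are independent of the trait by default.
`demographic_effect` adds that many SDs of trait to one designated category
(default variable `sex`, category `female`, effect 0) and is the positive
control: with a shift applied to a near-balanced category (education
"graduate", 49%), the demographic genuinely competes its way into mined
rules.  A shift on the 92%/8% sex split cannot — the minority child of any
sex split falls below every scaled `minbucket`, and conditional on the
items a demographic carries no further information, because the outcome is
a function of the items.

**What the generator does not emulate.**  Real item responses correlate
beyond a single latent factor (method effects, item wording); demographics
in real data are not independent of severity; real cohorts contain
missingness and careless responding.  Passing tests therefore demonstrate
that the *pipeline* behaves as designed under a known data-generating
process, not that the mined rules transfer to any particular population.

## CART engine

`CartClassifier` is a from-scratch implementation of classic recursive
partitioning (the scikit-learn tree is used only as an independent test
oracle):

* **Splits** minimise weighted Gini impurity.  Ordinal predictors use
  thresholds midway between consecutive observed values (`value <
  threshold` goes left — a row sitting on value k goes left of k + 0.5);
  nominal predictors (≤ 8 levels) enumerate all 2^(L−1) − 1 binary category
  partitions.  A split must leave ≥ `minbucket` rows on each side; a node
  must hold ≥ `minsplit` rows to be split at all (the two constraints are
  checked independently, mirroring recursive-partitioning convention).
  Splits with zero gain are refused (tolerance 1e-12).
* **Tie-breaking** is fully deterministic: largest gain, then lowest
  predictor index (column order), then lowest threshold / first category
  subset in enumeration order.  Deterministic trees are a requirement for
  rule counting.
* **Depth** is the only pruning parameter.  When unset it is selected over
  a grid (default 1..8 — mined rules have few conditions, so 8 is a
  generous ceiling) by stratified K-fold cross-validation (default 10),
  maximising *pooled* held-out accuracy (total correct over all folds; well
  defined even when a small fold misses a class), ties broken toward the
  shallowest depth.  Because growth at a node never depends on the depth
  cap, the CV fits one deepest tree per fold and evaluates it truncated at
  every candidate depth.
* **Prediction** routes rows to a leaf; the label is the leaf majority with
  ties resolved toward the most severe class (screening-conservative);
  probabilities are leaf class counts normalised.  Missing predictor values
  are rejected — there are no surrogate splits, and no cost-complexity
  pruning or priors.
* **Variable importance** is the raw sum of n·gain over the internal nodes
  splitting on each predictor.
* `scale_to_n`: `minsplit`/`minbucket` values quoted for the reference
  training size of 14,410 rows (70% of 20,585) are rescaled proportionally
  to the actual training size, preserving the constraint geometry of the
  full-scale design at desk scale (500 → 97 at a training size of 2,800).

## Rule mining

Each repetition draws a without-replacement 70/30 partition — the printed
reference sizes 14,410/6,175 are exactly 70%/30% of 20,585, which a
with-replacement bootstrap would not produce, so Monte-Carlo
cross-validation is the implemented reading.  Training size is
round-half-up(n × fraction), computed with exact rational arithmetic
(binary floats would give 14,409).  The full design crosses feature sets
(items only, plus one demographic at a time: sex, skin colour, education,
age group — the composition of demographic models was open, one-at-a-time
chosen) with the 3 × 3 hyperparameter grid, 1,000 repetitions per cell:
5 × 9 × 1,000 = 45,000 trees per scale.  Every repetition's seed derives
deterministically from (base seed, feature-set index, configuration index,
repetition index).  Configurations whose effective `minsplit` exceeds the
training size are skipped with a warning.

Every leaf contributes one rule: the root-to-leaf conjunction, canonicalised
by intersecting per-item intervals, dropping full-range conditions, and
sorting conditions (items in scale order, then demographics), so logically
identical paths are string-identical ("GAD2<2", "GAD4≥2", "GAD4=3",
interior intervals as "1≤GAD4<3").  The catalog counts one repetition per
leaf per tree, pooled across feature sets and configurations.  Top rules
per class are ordered by repetition count, ties preferring fewer conditions
then lexicographic text; defaults keep one rule per extreme class and two
for the middle class.

## Evaluation

Rules are one-vs-rest screeners.  Point metrics come from the confusion
counts; undefined precision (no predicted positives) is reported as 0 with
an explicit flag so means stay computable.  AUC is the trapezoidal area
under the ROC, computed in count space with a single final division so it
equals the Mann–Whitney concordance probability (ties counted ½) to the
last bit; for a 0/1 score it reduces exactly to
(sensitivity + specificity)/2.  Two scoring modes exist because a binary
indicator cannot produce per-rule AUCs above that closed form, while
published per-rule AUCs typically are — and a shared AUC for both
middle-class rules indicates a class-level curve.  The default mode
therefore scores each repetition's test rows by the repetition tree's
predicted probability of the rule's class (both moderate rules of a tree
then share one AUC); the rule-indicator mode is available where no tree
accompanies the rules (external validation).  Selected rules are evaluated
on *every* repetition's test partition whether or not that repetition's
tree contained the rule; repetitions whose test partition lacks the target
class are skipped and counted.  Summary SDs are population SDs (a single
repetition reports SD 0).  External validation applies a frozen rule set
unchanged, once, to a full new table, with the middle class screened by the
union (OR) of its two rules.

## Profiles and problem sizes

The `replication` profile encodes the full-scale design (n = 20,585,
5 feature sets, 9 configurations, 1,000 repetitions).  The `demo` profile —
used throughout the test suite — runs n = 4,000, items only, one
configuration, 50 repetitions, and completes in a few seconds on one CPU.
Its configuration is the most constrained grid cell, (2000, 2000) scaled:
its effective `minbucket` (≈ 14% of the training rows) is what keeps trees
at the two-to-three-level depth whose leaf paths are the short rules the
full-scale design reports; under the permissive (500, 500) cell,
cross-validation legitimately prefers deep trees (every item carries real
signal about its own sum) and the mined rules grow to four or five
conditions.

## Known limitations

* The generator's single-factor structure understates real item
  covariance; calibration targets are marginal, not joint.
* PHQ-9 class shares undershoot the severe target (see above).
* Rules are mined and scored on cohorts whose outcome is exactly the scale
  total — there is no measurement error in the outcome, so absolute metric
  levels run higher than field data would give.
* No surrogate splits: rows with missing items must be dropped before
  prediction, as in the validation step.
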