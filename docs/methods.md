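# Methods

## The virtual-twins procedure

The package estimates heterogeneous effects of a dichotomous "subgroup"
variable T (e.g. *attended ≥ 1 self-help group*) on a binary success
outcome y, without randomization: it is a descriptive, model-based
procedure, not a causal estimator. Stage 1 fits P(y = 1 | X) on all
predictors; stage 2 predicts each subject twice — once as observed, once
with T flipped — and orients the pair by the observed arm so that

    z_i = P(y=1 | x_i, T active) − P(y=1 | x_i, T inactive)

for every subject regardless of arm. A regression tree over the remaining
covariates then partitions the cohort by predicted effect. The key
assumptions are (a) the stage-1 model extrapolates credibly to the flipped
arm — which requires overlap, i.e. both arms observed across the covariate
space — and (b) z heterogeneity is axis-aligned enough for a binary tree
to express. Subgroups are *model-estimated*; no confidence intervals or
honest-inference corrections are attempted.

## Stage 1: evaluation protocol and model families

The split scheme is a stratified 70/30 holdout; 10-fold stratified CV runs
inside the 70 % (fold metrics are reported, and any list-valued
hyperparameter is chosen there by mean CV AUC), the model is refitted on
the full training split, and reported accuracy (0.5 threshold) and AUC come
from the untouched 30 %. This is the only arrangement in which a 70/30
split and tenfold CV coexist without leakage; both CV-mean and holdout
metrics appear in the evaluation report, labelled. AUC is computed in the
Mann–Whitney rank form (ties count half), so it is invariant under
monotone score transforms and exactly equals positive/negative pair
counting.

Families and defaults:

- **logistic_regression** — standardized features, L2 (C = 1), lbfgs.
- **gradient_boosting** — 100 trees, depth 3.
- **random_forest** — 500 trees, `min_samples_leaf` = 3 % of n. The leaf
  floor is deliberately high for a forest: stage 2 differences two
  predictions per subject, so any noise the forest memorises appears
  directly in z, and a smoother forest trades a little AUC for markedly
  less counterfactual noise (on outcome-independent data the maximum
  spurious subgroup effect stays under 5 percentage points at the default
  tree parameters).
- **feedforward_net** — one hidden layer of width max(8, #features),
  early stopping; the smallest "deep" architecture sensible for cohorts of
  a few hundred rows.

Ties in model selection go to the declared family order (logistic first),
with a logged warning.

Feature importance is permutation importance on held-out data: the raw
(schema-level) column is permuted, the table re-encoded — so all one-hot
columns of a categorical variable move together — and the mean AUC drop
over `n_repeats` (default 5) shuffles is the raw score. Scores are clipped
at zero and divided by the maximum, so the top variable scores exactly 1.
Permutation, not impurity, importance: it is defined identically for all
four families.

## Encoding and missing data

Categoricals are one-hot encoded in sorted level order recorded at fit
time, so counterfactual rows encode deterministically. Missing categorical
values become an explicit `Unknown` level at load time; missing numeric
predictors are imputed with the training-split median (fitted on the
training rows only and stored with the encoder). Targets may never be
missing. Counts are validated as non-negative integers, binaries as {0,1}.

## Stage 2: flip and tree

Subgroup variables must be dichotomous before flipping; counts are
dichotomized at their declared threshold (1 iff value > threshold, default
0, matching "none vs any" subgrouping). The flip regenerates all derived
encoded columns rather than editing them in place. By default the stage-2
prediction model is the selected family refitted on the full cohort
(`refit_on_full_data: false` reuses a training-split fit instead); the
full-data refit is the more stable choice for a descriptive second stage
and is the documented default.

The tree is a variance-reduction (CART-style) regression tree on the
continuous z — "classification tree" outputs in this literature are
probability-difference percentages, so regression on z is the faithful
reading. Numeric splits use midpoints between adjacent observed values
(hence fractional thresholds such as 2.5 goals on integer counts);
categorical variables with ≤ 8 levels are split by exhaustive level-subset
search, beyond that one-vs-rest. Left branches always mean the condition
is satisfied. Determinism: among equal-gain splits the earliest variable
in schema order wins, then the lowest threshold / lexicographically
earliest subset (gain comparisons use a 1e-12 tolerance). Defaults:
`max_depth = 5`, `min_leaf_fraction = 0.05` (every reported subgroup
covers ≥ 5 % of the cohort), `complexity_penalty = 0` (minimum split gain
as a fraction of root variance). Deep trees find narrow, possibly
non-generalizable subgroups; the depth cap and leaf floor are the
guardrails, and internal nodes can be extracted as coarser subgroups.
"Top split variables" are ranked by split gain (sum-of-squares reduction),
not tree level, so the strongest moderators are named even when one sits
below the root. Per-node bookkeeping guarantees the conservation laws
(children's coverages sum to the parent's; the parent mean effect is the
coverage-weighted child mean) by construction; tests assert them to 1e-10.

## Synthetic cohort generator

The generator emulates the *marginal* structure of the motivating cohort:
40 mixed-type predictors (10 categorical, 25 binary, 5 counts) whose
default marginals encode the reported frequencies (87.9 % Black, 70.7 %
aged 41–60, 85.2 % single, 74.7 % ≥ grade 12, 37.9 % alcohol / 43.4 %
cocaine, 80.5 % court-ordered, 52.3 % criminal-system involvement, 22.7 %
SNAP at intake, 78.1 % PCP at intake, 68.4 % PCP-linked, 28.1 % dual
diagnosis); unreported marginals are plausible fillers and the variable
names beyond those quoted in published results are reconstructed, not
verbatim. Counts (self-help sessions, goals) are zero-inflated Poisson —
a hard never-engaged class plus a right tail — so subgrouping at 0 vs > 0
and at fractional thresholds is meaningful.

Outcomes are Bernoulli draws from a logistic model: intercept + indicator
main effects + planted effects (a log-odds shift active when the affected
variable is active AND a conjunction of covariate literals holds). The
default links engagement counts and PCP/SNAP linkage to both outcomes,
with PCP- and SNAP-conditioned planted interactions echoing the kind of
subgroup structure the method is meant to find. Intercepts are calibrated
to the reported prevalences (57.8 % / 44.9 %) by Brent root-finding on the
mean logistic probability over a fixed internal covariate sample
(seed 987654321, n = 100,000), independent of the user-facing seed.
Closed-form per-row true effects (`true_effects`) force the affected
variable's active state to 1 and 0 analytically; a model may therefore
depend on a subgroup variable only through its active indicator.

Predictors are independent by default; an optional Gaussian-copula layer
induces pairwise association (each marginal is sampled by inverse CDF from
a latent normal, so declared correlations act monotonically). What the
generator does **not** emulate: the real cohort's joint distribution,
non-logistic outcome mechanisms, informative missingness, or measurement
error — so passing recovery tests demonstrates that the pipeline finds
structure it is pointed at, not that the published clinical findings
replicate.

Reproducibility is byte-exact for a fixed (config, seed): one latent
matrix for all predictors in schema order, then one uniform vector per
outcome in declared order.

## Benchmark experiments and problem sizes

`vtwins.experiments` fixes three small designs used by the test suite and
`scripts/acceptance.py`:

- **planted_interaction_config** — T, moderators A/B, 10 nulls; shift
  0.85 gives true z ≈ 0.20 inside A=1 ∧ B=0 and 0 outside (mean ≈ 0.05).
  At n = 5,000 the random-forest pipeline recovers {A, B} as the two
  strongest splits in ≥ 18/20 seeded runs and tracks the mean true effect
  within 0.05.
- **two_signal_config** — two signal predictors among 20 nulls
  (n = 2,000); both occupy the top-2 scaled importances, leader exactly 1,
  in ≥ 18/20 runs.
- **null_config** — intercept-only outcome (n = 2,000); holdout AUC stays
  in [0.4, 0.6] for all families and no tree leaf reaches |effect| 0.05.

These sizes (2,000–10,000 rows, 10–20 seeds) were chosen as the smallest
at which the binomial noise floor is well below the quantities being
scored; the acceptance script uses the same designs at 5–10 seeds.

## Known limitations

- Stage-1 extrapolation to the flipped arm is untestable on real data
  without overlap diagnostics (none are built in).
- Permutation importance under correlated predictors spreads credit; the
  default generator is independent, real cohorts are not.
- The tree reports no uncertainty; subgroup effects are point estimates
  from a single fit.
- The pipeline's determinism contract covers a fixed software environment;
  changing library versions may change fitted models.
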