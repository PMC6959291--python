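# Methods

This note documents the statistical procedures implemented in `methleuk`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Nearest shrunken centroids

`nsc` implements the standard NSC formulation on beta values. For CpG *i*,
class *k* with n_k of n samples:

- class centroid x̄_ik, grand centroid x̄_i;
- pooled within-class SD s_i with denominator n − K;
- fudge constant s0 = median_i s_i, guarding CpGs with near-zero variance
  (if the median is 0 but some s_i > 0, the smallest positive s_i is used;
  if the matrix is constant, s0 = 1);
- m_k = √(1/n_k + 1/n); d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s0)).

The alternative normalizer √(1/n_k − 1/n) appears in parts of the NSC
literature; it only rescales the Δ axis and does not change which CpGs
survive at the cross-validated threshold. Class-proportion priors are the
default (`priors="uniform"` is available): with strongly unbalanced
cohorts the prior term −2 log π_k decides fully shrunken models, which is
the behaviour the majority-class baseline expects.

**Threshold selection.** Δ is tuned on a grid of 30 equally spaced values
from 0 to max|d_ik| by stratified k-fold CV (k = 10, reduced with a
warning when a class is smaller). The grid value with the fewest CV
misclassifications is chosen; *error ties are broken by the highest
held-out log posterior of the true class, then by the largest Δ*. The
likelihood tie-break is load-bearing: on strongly separated cohorts the
CV error is exactly zero over almost the entire grid, and a pure
sparsest-at-minimum rule degenerates to a single-CpG classifier, whereas
the held-out likelihood peaks where all informative CpGs are retained and
the noise CpGs are shrunk away. Prediction ties go to the
lexicographically first class label; folds come from a seeded shuffle, so
CV is reproducible.

## Consensus diagnosis

Repeated 70/30 splits are stratified by class (floor(0.7·n_class) to
training, remainder to validation) — plain random splitting can produce
class-empty training sets at small n. Each repeat draws its own child
seed, so fold assignments and splits resample independently per repeat.
The consensus panel is the exact intersection of the per-repeat selected
sets; an empty intersection is reported with a warning, not an error.

Panel evaluation refits the NSC at Δ = 0 on the panel CpGs only (the
panel is already a selected set; further shrinkage would re-tune it) and
scores samples by the case-class posterior. A logistic-regression score
over the panel betas is available (`score="logistic"`) as a
model-independent alternative. ROC curves group tied scores into a single
threshold step, making the trapezoid AUC equal to the Mann–Whitney
fraction with ties counted one half.

Confusion tables are reported with predicted classes as rows and true
classes as columns, per-class one-vs-rest sensitivity (correct_k/total_k)
and specificity (TN_k/(TN_k+FP_k)), and percentages rounded half-up to one
decimal — full precision is kept on the objects. The three clinically
distinct error types (disease missed, healthy called disease, wrong
leukemia type) are tallied by `error_taxonomy`.

## Semisupervised survival classification

The *Cox score* of a CpG is the absolute Wald z (|β̂|·√I(β̂)) of a
univariate Cox proportional-hazards fit of survival on its beta values,
with Breslow tie handling — the simplest convention, adequate for
continuous covariates. Fits use a safeguarded Newton iteration vectorized
across CpGs (steps clipped to ±2, |β| capped at 30; non-convergent fits
score 0 with a warning; a constant covariate scores 0). The
partial-likelihood score statistic U(0)/√I(0) is available via
`statistic="score"`; on a binary covariate it reproduces the log-rank
statistic, which the test suite exploits as a cross-check. The test suite
also verifies both statistics against `lifelines`.

The cutoff grid spans 100 equally spaced values from the 90th percentile
of the scores (linear interpolation between order statistics — percentile
conventions differ, so this is pinned) to their maximum. Cutoffs selecting
identical CpG sets are evaluated once; a cutoff selecting no CpGs, or
whose 2-means clusters leave fewer than two patients on a side, is
infeasible and skipped.

For each feasible cutoff: patients (observations) are clustered by
2-means on the selected CpGs' raw beta values (no feature scaling — betas
already share the [0,1] scale), using Lloyd's algorithm with 20 seeded
restarts keeping the best within-cluster sum of squares; the clusters are
compared by a two-group log-rank test; and an NSC classifier is
cross-validated on the cluster labels. "Most significant survival
difference with the smallest CV error" is operationalized as the minimum
rank-sum of the log-rank p (ascending) and the CV error (ascending) —
rank-sum is scale-free across the two criteria — with ties preferring
fewer CpGs, then a larger cutoff. Clusters are named good/bad survival by
Kaplan–Meier median survival (by KM survival at the last common event
time when both medians are unreached), so the naming is invariant to
cluster-id relabeling. The log-rank decision uses training data only;
validation cohorts are untouched until risk-group prediction.

The model's `selected_cpgs` are exactly the CpGs above the chosen cutoff;
`signature_cpgs` are the subset with a nonzero shrunken difference in the
embedded NSC model — the working interpretation of how a cutoff-selected
list condenses into a final reported signature.

The log-rank test and the Kaplan–Meier product-limit estimator are
implemented directly (they sit inside the 100-cutoff sweep); both are
verified against `lifelines` and hand-worked small examples in the tests.

## Padlock count processing

Raw records are (cpg_id, sample_id, umi, methylated). Reads sharing a UMI
within one CpG/sample collapse to a single molecule; the surviving
methylation call is the first record after a stable sort by (cpg_id,
sample_id, umi). The underlying chemistry does not dictate how a
methylated/unmethylated UMI collision resolves — first-seen-after-sort is
a convention chosen for determinism and idempotence. Methylation frequency
is meth/total molecules, with zero-coverage cells missing (NaN), never 0.
The coverage filter drops a CpG when *any* sample has fewer than
`min_reads` (default 20) molecules; a (CpG, sample) pair absent from the
table counts as zero coverage, consistent with the any-sample reading.
Conversion efficiency is the percentage of non-CpG (CH) cytosines read as
converted, reported per library.

## Synthetic cohorts

Beta values are drawn from Beta(mean·c, (1−mean)·c) — the
(mean, concentration) parameterization makes an effect size a shift of
the mean at fixed dispersion. Background CpGs get a per-CpG baseline mean
drawn once from U(0.1, 0.9), identical across classes, at concentration
30 (SD ≈ 0.05–0.09, typical of technically stable array probes).

*Diagnostic markers* shift the mean in the target class only; the default
recovery cohort plants 5 AML markers at 0.85 vs 0.10 (concentration 50)
in a 729-CpG panel with 100 samples per class — a strong, cleanly
separated effect, as reported differential panels tend to be.

*Prognostic markers* are driven by a latent binary risk group
(50/50 by default). Half the markers are hypermethylated in the high-risk
group, half hypomethylated (real signatures contain both, and mixed signs
keep the cohort's linear predictor centred). Each marker is strongly
bimodal (concentration 0.5: mass piled near 0 and 1, the shape array
betas actually take at variably methylated CpGs), with the risk group
shifting the probability of the methylated state from 0.35 to 0.65. A
single marker therefore stratifies patients poorly and only the joint
panel is reliable — the regime semisupervised survival selection exists
for. The group-level log hazard ratio (default 3) is split evenly over
the markers as per-CpG coefficients ±group_log_hr/(n_markers·Δmean),
recorded in `TruthPanel.effect_sizes`.

*Survival times* are exponential with hazard = baseline·exp(Σ coef·beta);
censoring is min(administrative horizon, U(0, 2·horizon)). Defaults
(baseline 0.06/month, horizon 60 months) put the cohort median near one
year with ~70% observed events — an aggressive-leukemia timescale.

*Read counts*: molecules per (CpG, sample) are Poisson(depth_mean), each
methylated with probability beta, UMIs drawn without replacement from the
4^6 6-mers; PCR duplicates (same UMI, same call) are injected at a
configurable rate.

One global seed expands into per-stage child seeds
(`numpy.random.SeedSequence`), so each stage is independently
reproducible.

**What the synthetic cohorts do not show.** They contain no batch or
cohort effects, no probe cross-reactivity, no cell-composition
confounding, no correlation structure among background CpGs, and no
missing values; planted effects are exchangeable across marker CpGs.
Passing the recovery suites demonstrates that the pipeline's selection
and calibration logic is correct under its own assumptions — not that a
panel recovered from real 450K/padlock data would have the same size,
identity or error rates.

## Problem sizes in the test and acceptance runs

The recovery suites run the full pipelines at the cohort sizes stated
above (diagnostic: 20 pipeline runs × 20 splits; prognostic: 10 signal
and 10 null runs; null calibrations at 500 replicates, n = 200); the
acceptance script uses 10 diagnostic and 5 + 5 prognostic runs. These
replicate counts keep a complete run in the minutes range while leaving
the binomial uncertainty of the reported rates small relative to the
90%-of-runs thresholds they are compared against.

## Known limitations

- The Cox fit is univariate only; no multivariate modelling, competing
  risks or time-dependent covariates.
- Wald z under near-separation (a covariate that almost perfectly orders
  survival) is unstable in any implementation; the score statistic is the
  robust alternative in that regime.
- The rank-sum cutoff selection inherits the optimism of maximizing a
  training-data statistic over 100 candidate cutoffs; training log-rank
  p-values are therefore anti-conservative and only the validation
  log-rank should be quoted.
- 2-means with 20 restarts is exact on the small instances the test suite
  enumerates, but global optimality is not guaranteed in general.
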