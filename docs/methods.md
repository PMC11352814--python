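# Methods

This note records the statistical model behind `protomort`, the defaults
and why they hold their values, the numerical choices that affect
results, and what the synthetic generator does and does not emulate.

## Screening model

Let X be the patients × proteins abundance matrix on the linear scale
with explicit missingness, and let the two outcome groups be survivors
(s) and non-survivors (d) at the end of a 1460-day follow-up. All
analysis happens on log2(X).

**Coverage routing.** A protein enters the quantitative branch iff its
observed fraction is ≥ 0.80 in *each* group (`coverage_threshold`,
configurable). Routing is a partition: quantitative, qualitative
candidate, or excluded (candidates that fail the presence/absence
pattern below). The 80 % bar is evaluated per group rather than overall
so that a protein cannot qualify by being fully observed in the larger
group alone.

**Imputation.** Missing cells of quantitative proteins are presumed to
sit below the detection limit and receive `imputation_factor` × (the
protein's minimum observed linear value), default 0.95, then log2. Two
properties are guaranteed and tested: observed cells are never altered,
and imputed values fall strictly below the protein's observed minimum.
The factor is per-protein and configurable because "95 % of the
minimum" admits other readings (global minimum, 5th percentile); the
chosen reading is the one consistent with a per-protein detection-limit
interpretation.

**Quantitative test.** Each group is gated through Shapiro–Wilk at
α = 0.05 (`alpha_normality`); an equal-variance two-sample *t*-test is
used when both groups look normal, a two-sided Mann–Whitney U otherwise.
Groups too small for Shapiro–Wilk (n < 3) or with zero range are treated
as non-normal. The effect is log2FC = mean_d − mean_s of log2 values;
%Δ = (2^log2FC − 1)·100 is emitted alongside and the bijection is
enforced to 1e-6 in tests.

**Qualitative (presence/absence) test.** A candidate is eligible when
detected in ≥ 80 % of one group and ≤ 20 % of the other
(`qual_present_min`, `qual_absent_max`; the 80/20 operationalization of
"present in almost all of one group, absent in the other" mirrors the
coverage constant). The test is Barnard's unconditional exact test on
the 2×2 detection table:

- ordering statistic: pooled Wald z; tables with pooled detection rate
  0 or 1 get statistic 0;
- two-sided tail: |z| ≥ |z_obs| − 1e-12. The epsilon keeps the exact
  mirror table (x1→n1−x1, x2→n2−x2), whose statistic equals −z_obs
  mathematically but not always in floating point, inside the tail;
- nuisance maximization: dense grid π ∈ {0.0005, 0.0015, …, 0.9995}
  (step 1e-3, boundaries excluded), fully vectorized over the table
  lattice;
- degenerate tables (no detections anywhere, or detections everywhere)
  return φ = 0, p = 1.

The effect is the φ / Matthews coefficient of the detection table,
signed so that positive means more present in non-survivors. Tests
compare the kernel against an exhaustive exact-rational oracle (tie
membership decided with `fractions.Fraction`, no floating point) and
against `scipy.stats.barnard_exact` as an independent implementation;
the scipy comparison is one-sided-tolerant because scipy's strict float
comparison can drop exactly-tied boundary tables.

**Significance.** The DAP set is the union of both branches at raw
two-sided p < 0.05. No multiplicity correction is applied to the
decision — the screening is a hypothesis-generating step on ~350
features at n = 34, and several meaningful effects sit just under 0.05 —
but a Benjamini–Hochberg q-value column is emitted for reference.

## Predictive model

Both targets (death at 4 years; days of survival) run through the same
pipeline: standard scaling → class rebalancing → univariate K-best
selection → aggregated conformal Random Forest. The full pipeline is
refit inside every training fold of the 5-fold internal validation;
nothing downstream of the fold split ever sees held-out rows (a planted
leak-detector feature verifies this in the tests).

**Rebalancing.** Instance Hardness Threshold for the categorical target:
per-sample hardness is 1 − cross-validated predicted probability of the
sample's own class (Random-Forest estimator), and the hardest
majority-class samples are dropped until the classes balance. All-KNN
for the continuous target (applied to the event labels, with the
surviving rows' day counts used for fitting): for k = 1, 2, 3 in turn,
majority-class samples whose k nearest neighbors majority-vote against
them are removed. In both methods the minority class never shrinks, and
classes with fewer than 2 members skip rebalancing with a warning. The
method-to-target assignment is deliberate and configurable
(`ModelConfig.rebalance`), even though the reverse pairing would be the
more conventional choice.

**Feature selection.** ANOVA-F (classification) or F-regression scores;
k = 10 by default ("auto" resolves to 10, matching the reported model
size). Constant features score zero and are never selected above varying
ones.

**Conformal engine.** Ten sub-models per predictor
(`n_acp_models = 10`). Each draws a bootstrap sample of the training
rows (proper training set) and calibrates on the out-of-bag rows,
redrawing (bounded retries) if either part misses a class. Forests use
200 trees, balanced class weights, min_samples_split = 2,
max_features = floor(√k), OOB scoring enabled, and deterministic
sub-seeds spawned from the master seed (46 by default).

- Classification nonconformity: 1 − p̂(class). A test point's p-value
  against calibration scores α₁…α_n is (#{αᵢ ≥ α_test} + 1)/(n + 1).
  Sub-model p-values are combined by the median; the prediction set at
  confidence 0.8 is {class : p > 0.2}, conclusive iff a singleton.
- Calibration pooling: *marginal* by default. Class-conditional
  (Mondrian) calibration is implemented (`ModelConfig(mondrian=True)`)
  and is the principled guard for per-class validity under the 23/11
  imbalance, but with bootstrap-OOB calibration at n = 34 each class
  retains only ~3–5 scores, so the smallest attainable p-value
  1/(n_cal + 1) exceeds 0.2 and *no* prediction can ever be conclusive —
  the model would report 0 % coverage no matter how good it is. Marginal
  calibration preserves marginal validity (verified empirically on ≥ 500
  exchangeable test points) and yields informative coverage at cohort
  scale.
- Regression nonconformity: |y − ŷ| / σ̂(x), where σ̂(x) is the mean
  absolute training residual among the 15 nearest training neighbors
  (`knn_norm_k`) in selected-feature space plus a floor
  β = 0.01·sd(y) (a tiny positive constant when y is constant). The
  per-model interval is ŷ ± q·σ̂(x) with q the ⌈0.8·(n_cal+1)⌉-th
  smallest calibration score (capped at the maximum when the rank
  overflows); intervals aggregate by the median of lower and upper
  bounds. Regression predictions are always conclusive.

Median aggregation of per-model conformal p-values is only
approximately valid in theory; the empirical prediction-set error is
checked against the 1 − confidence target within three binomial
standard errors in the acceptance tests.

**Permutation importance.** On each held-out fold, every selected
feature is permuted 20 times (`n_permutations`) and the mean degradation
of fold accuracy (classification) or fold R² (regression) is recorded;
features never selected score 0. Permutations are batched into a single
prediction call per (fold, feature) for speed.

## Evaluation

Sensitivity, specificity and MCC are computed over conclusive
predictions only; inconclusive sets count only against coverage. This is
the only reading under which a reported coverage below 1 can coexist
with perfect specificity on the same row. PPV/NPV/accuracy at an
arbitrary prevalence π follow the Bayes identities (README); evaluated
at the conclusive-set's own empirical prevalence they reproduce the raw
confusion-matrix values exactly (tested to 1e-12). Yearly cumulative
mortality is the fraction dead by 365·k days, rounded to integer
percent; patients with unknown survival are excluded with a count.

## Synthetic cohort generator

The generator defines the study conditions for every test. Defaults:
23 survivors / 11 non-survivors; 300 LC-MS + 63 multiplex proteins;
15 planted quantitative effects of +2 log2 units in non-survivors;
16 planted presence/absence effects with detection probability 0.9 in
the carrying group and 0.1 in the other (alternating direction);
baseline log2 means U(3, 10) with per-protein log2 SD 1.0;
left-censoring at each protein's null 10 % quantile plus 3 % random
dropout; follow-up 1460 days; seed 46.

Rationale for the missingness constants: with per-group coverage
thresholds of ⌈0.8·23⌉ = 19 and ⌈0.8·11⌉ = 9, an observation
probability of (1 − 0.10)(1 − 0.03) ≈ 0.873 puts the expected
quantitative-branch fraction near 60 % of proteins — the regime the
pipeline is meant to operate in, where a substantial minority of the
panel must be handled by the presence/absence branch. The censoring
threshold is the *null* distribution quantile, not the realized sample
quantile, so a planted group shift changes that group's detection rate
(the MNAR mechanism) without moving the detection limit itself.

Survival times for non-survivors are exponential waiting times truncated
to the follow-up window, with rate (1/1500 days) · exp(0.3 · risk),
where risk is the mean standardized log2 deviation of the planted
quantitative markers — the simplest generative form that links both the
categorical and the continuous target to the planted signal. The
frequent-exacerbator flag is drawn with death-dependent probability
(7/11 among non-survivors, 7/23 among survivors) so stratified mortality
is exercisable.

What the generator does **not** emulate: peptide-level structure and
rollup, platform batch effects and plate layout, heavy-tailed or
correlated protein co-expression (proteins are independent given group),
informative censoring of the survivors, and real biological annotation
(synthetic protein ids map to "orphan"). Passing tests therefore
demonstrate the pipeline's statistical behavior under a clean MNAR +
group-shift model, not performance on real plasma data.

## Problem sizes in tests

The conformal validity checks use 900 exchangeable patients (300
training, 600 test) over 30 proteins; screening calibration uses 100
replicate 23/11 cohorts of 80 proteins with ten planted 2-log2FC
effects; determinism and leakage checks run the full pipeline on reduced
cohorts (50 proteins) and ensembles. These sizes give the property under
test a comfortable signal-to-noise margin while keeping the whole suite
fast enough to run habitually.

## Known limitations

- Barnard p-values use a fixed 1e-3 nuisance grid; an adversarially
  narrow likelihood peak between grid points would be missed (bounded by
  the grid step; negligible at these margins).
- With fewer than ~8 calibration points per sub-model the conformal
  quantile saturates at the maximum calibration score, making intervals
  conservative rather than invalid.
- The IHT cross-validated hardness estimate is itself seeded; changing
  the seed can move one or two samples across the balance boundary at
  small n.
- Q² on 34 patients has high variance across seeds; single-cohort Q²
  values should be read as illustrative, not as stable estimates.
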