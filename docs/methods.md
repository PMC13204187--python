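# Methods

`pmfscreen` implements a screening analysis for a rare hematologic disease
(primary myelofibrosis, PMF) in longitudinal electronic health records, built
around positive-unlabeled (PU) learning. This note records the models, the
conventions frozen into the code, the synthetic cohort the tests run on, and
the design choices made where the design was genuinely open.

## The screening problem

A hospital database contains a handful of confirmed PMF cases (the labeled
positives, ~67 at study scale) and a vast pool of patients with no PMF
diagnosis (~110,000). The pool is *unlabeled*, not negative: PMF prevalence in
such a population is ≈ 0.061%, diagnoses are missed or miscoded, and EHR
systems rarely record ruled-out conditions. The task is to rank the pool by
PMF risk from routinely collected data — 22 complete-blood-count (CBC)
parameters measured over the two years before an anchor date, ICD-10 codes,
and demographics — so that a short, reviewable list of high-risk patients can
be referred for hematological evaluation.

## Cohort construction

* **Putative-case flagging** uses a word-boundary regex on the Polish stem for
  myelofibrosis plus five ICD-10 case codes (C94, C94.4, D47, D47.1, D47.4);
  a bare three-character root matches all of its subcodes.
* **Analysis windows** are half-open: `[anchor − 730 d, anchor)`. Events on
  the anchor (diagnosis) day are excluded so same-day diagnostic labs cannot
  leak into features. Control anchors are sampled uniformly no later than the
  last visit, so control windows may be shorter than two years — mirroring
  real record truncation.
* **Control matching** stratifies on age decade × gender with quotas
  proportional to the positive cohort's stratum shares, apportioned by
  largest remainder (per-stratum deviation < 1/n).
* **Leakage exclusion** removes every ICD-10 code whose root lies in D45,
  D46, D47, D70–D77 or C81–C96 (hematologic malignancy ranges) from the
  feature set; membership is decided by the three-character root, so subcodes
  inherit their root's fate.

## Feature engineering

Each CBC parameter contributes one binary *measured* indicator and eight
aggregates of its time-ordered values: 25th/50th/75th percentiles (linear
interpolation), min, max, sample variance (n−1 divisor; 0 for a single
value), |last − first|, and monotonicity (last > first; ties are False).
ICD-10 codes and PheWAS-style phenotype groups (exact code lookup with
three-character-root fallback) contribute binary indicators; age at anchor
and gender complete the schema. At the default synthetic schema this yields
22 + 176 + 7 + 5 + 2 = 212 columns.

Modeling uses **decile bins** in place of raw aggregates: interior edges at
the control group's percentiles 10…90, a value equal to an edge falling in
the lower interval, ties collapsing to fewer effective bins. Bins are always
fitted on the control (unlabeled) rows of the *training* data — inside CV
folds, never on validation rows. Optional parameters, codes and phenotypes
pass a joint prevalence filter: present in ≥ 5% (inclusive) of both classes,
re-applied inside each training fold. Missing values stay missing end to end
(NaN sentinel); there is no imputation — learners either handle missingness
natively (boosted trees) or encode it as a category (one-hot logistic,
Weight-of-Evidence). WoE uses a 0.5 pseudo-count so empty cells stay finite.

## Univariate statistics

Each feature is tested on its raw scale with a single-predictor logistic
regression under balanced class weights `w_class = n/(2 n_class)` and a Wald
p-value; for a binary predictor the weighted MLE slope equals the log
cross-product ratio, so class weighting does not move the OR (verified
against a brute-force likelihood maximizer in the tests).
Benjamini–Hochberg adjustment runs over the testable features only; features
with zero variance are flagged, not fitted, and do not enter m. Volcano rows
flag |log₂ OR| ≥ 0.585 (OR outside [0.67, 1.5]) at adjusted p < 0.05
(strict). Quasi-separated features get slope capped at ±50 to keep the OR a
finite, recognizably extreme number. The same machinery re-runs on arbitrary
binary partitions (e.g. consensus false positives vs true negatives).

## PU wrappers

**Elkan–Noto.** Under SCAR (labeled positives selected completely at random
from all positives), a classifier `g` trained on labeled-vs-unlabeled
satisfies `g(x) = c·p(y=1|x)` with `c` the label frequency. We hold out 10%
of labeled positives, fit the base learner on the rest vs the unlabeled pool,
estimate `ĉ` as the mean holdout score (clipped to (ε, 1]), and rescale
scores by `1/ĉ`, capped at 1. The first-stage fit is **unweighted**: the
identity above holds only for an uncorrected estimate of P(s=1|x); balancing
weights inflate positive-region scores and with them `ĉ` (we measured
`ĉ → 0.9` for a true `c = 0.5` on separable cohorts with balanced weights).
Calibration is a monotone transform, so rankings, AP and AUROC are unchanged;
only the probability scale — and hence a fixed decision threshold — moves.

**Spy.** 10% of labeled positives are planted among the unlabeled; a
first-stage model is fitted on the remaining positives vs (unlabeled +
spies); the threshold is the ⌈0.2·n_spies⌉-th smallest spy score (the 20%
noise tolerance: that fraction of spies may fall below it); reliable
negatives are the non-spy unlabeled scoring strictly below; the second stage
refits on *all* original positives (spies returned) vs reliable negatives
only. Remaining unlabeled samples are excluded from the second fit and only
scored at prediction. Zero reliable negatives is a loud error, never a
silent fallback.

Both wrappers are scikit-learn estimators (`fit(X, s)` on observed PU
labels, `predict_proba`, fitted attributes `c_hat_`, `threshold_t_`,
`reliable_negative_indices_`, …) and compose with any base adapter exposing
`fit(X, y, sample_weight)` / `predict_proba`. Shipped adapters: LightGBM and
XGBoost (native NaN handling, deliberately shallow and strongly regularized
for tiny positive cohorts), random forest behind WoE encoding, and a
dependency-light one-hot logistic on the binned features. The supervised
baseline and the spy stages use inverse-class-frequency sample weights.

## Evaluation

Repeated randomized stratified 10-fold CV (10 repetitions ⇒ 100 validation
runs at study scale; desk-scale tests use smaller k × reps, noted per
experiment). Within every training fold: prevalence filter, bin edges, WoE
tables and PU holdout/spy draws are re-fitted; validation folds are only
transformed and scored. Metrics per run: AP, AUROC, and threshold metrics at
0.5 (precision, recall, specificity, F1), with 0/0 ratios recorded as
missing and excluded from summaries. Summaries are medians with empirical
95% CIs (2.5/97.5 percentiles across runs). AP is computed without
interpolation — `Σ (Rₙ − Rₙ₋₁) Pₙ` over descending unique thresholds —
because trapezoidal PR areas interpolate across sparse regions and
overestimate performance under extreme imbalance. The recall-binned PR
profile pools every per-threshold (recall, precision) point of every run and
reports median + IQR per 10% recall bin (the last bin closed so recall = 1
is counted).

**Consensus misclassification:** a patient is assigned TP/FP/FN/TN when the
same predicted class occurs in strictly more than half of their validation
evaluations (exact ties are `unstable`), crossed with the observed label.
Venn region counts compare consensus sets across model variants.
**Screening arithmetic:** enrichment = precision % / prevalence %; review
workload = flagged × 15 min / 60.

## Synthetic cohorts

Real screening EHR data are private, so the generator emulates the
statistical structure the analysis assumes:

* **Class-conditional CBC marginals.** Per parameter, a log-normal with
  median equal to the published per-group median (e.g. platelets 233 G/l in
  controls vs 416 G/l in cases; hemoglobin 13.3 vs 10.2 g/dl) and a
  dispersion derived from the published (min, max) range, treating the
  control range as ≈ 8 log-sigma wide (n ≈ 110k sample). Percent-scale
  parameters are clipped at 100. Log-normal keeps positive support for
  concentration-type labs; only marginals are modeled — no multivariate lab
  correlation, no disease progression (an optional linear log-drift knob
  exists but defaults to 0).
* **Visits.** Homogeneous Poisson over the 730-day window at class-specific
  rates (defaults 1.5/yr controls, 2.5/yr cases, matching the reported ~3 vs
  ~5 visits per window), minimum one visit (the inclusion criterion of a
  usable record). The 8 optional parameters are dropped per visit at rate
  0.3.
* **Codes.** Bernoulli emission per window; case odds are the control odds
  times a multiplier. Defaults give D64.8 ("other anemias") and Z03
  (diagnostic observation) 8-fold odds in cases — the characteristic coding
  signature — plus five common comorbidity codes at neutral odds. Five codes
  map to phenotype groups; two stay unmapped.
* **PU structure.** Labeled positives are a SCAR draw; hidden positives use
  case distributions for labs and codes but carry `s_observed = 0`. At
  `hidden_positive_rate = 0` the cohort degrades to a classical binary
  problem (and ĉ → 1).
* **Desk scale.** Default config: 1,100 unlabeled + 50 labeled positives
  (the study's 110,000 ÷ 100, with 5 positives per each of 10 centers since
  0.67 per center is unusably sparse), hidden rate 0.05.

Because the generator matches class-conditional marginals but not the messy
correlation structure, non-stationarity, or coding idiosyncrasies of real
EHR data, passing tests demonstrate that the *pipeline machinery* is correct
and that the PU estimators recover known generating parameters — not that
the study-scale clinical performance numbers transfer.

## Recovery experiments and their problem sizes

* **Label-frequency recovery:** separable SCAR cohort of n = 2,000 (1,800
  unlabeled + 200 labeled positives, hidden rate chosen so the realized
  labeling frequency is 0.5), low-dispersion parameter specs, 20 seeds. The
  first-stage learner is the one-hot logistic at C = 0.1: at ~1,900 encoded
  columns on 2,000 rows the default regularization lets the learner
  partially separate labeled from latent positives on noise, which makes
  positive-region scores bimodal and the holdout mean needlessly noisy. With
  a holdout of ⌈0.1·200⌉ = 20 positives, SE(ĉ) ≈ 0.05 even for a perfectly
  calibrated model, so the ±0.1 recovery band is asserted on the seed
  ensemble (mean and median error) with ≥ 90% per-seed coverage.
* **Spy purity:** 1,000 unlabeled + 60 positives, 10% hidden, 20 seeds; the
  reliable-negative set must carry a strictly smaller latent-positive
  fraction than the pool it was mined from (it does, ~0.01–0.08 vs ~0.1).
* **Consensus-FP enrichment:** the end-to-end analogue of the study's
  hidden-positive finding. 500 unlabeled + 30 positives, 8% hidden, baseline
  variant, k = 5 × 2 repetitions, 20 seeds; the consensus false-positive set
  is compared to the unlabeled background by one-sided Wilcoxon on the
  paired latent-positive fractions. These reduced CV depths and cohort sizes
  are the package's desk-scale experiment sizes; the full 10 × 10 study
  configuration is available through `RunConfig` defaults.

## Numerical conventions and degenerate inputs

Linear-interpolation percentiles everywhere (aggregates, bin edges, CI
bounds); strict-below bin assignment; monotonicity ties → False; empty lab
series → all-missing aggregates (row retained); empty event list → flagging
false, windowing error; single-class or constant univariate inputs →
flagged-missing, not exceptions; all seeds fan out from one top-level seed
via `numpy` Generator streams, and identical config + seed reproduce
byte-identical artifacts.

## Known limitations

* The generator's marginal-only lab model cannot exercise failure modes that
  depend on correlated features or temporal trends.
* Study-scale headline metrics (AP ≈ 21%, sensitivity ≈ 46% at ~0.06%
  prevalence) are properties of the private multi-hospital data and are not
  reproduced at desk scale; the package reports its own cohort's metrics.
* Hyperparameter search is out of scope: adapters ship fixed, strongly
  regularized defaults.
* No free-text processing beyond the single case-flagging regex; no
  cross-center patient de-duplication.
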