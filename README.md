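# pmfscreen

Positive-unlabeled (PU) screening for rare disease in longitudinal electronic
health records, packaged as scikit-learn-style estimators.

Primary myelofibrosis (PMF) is a rare blood cancer (prevalence ≈ 0.061% in a
hospital population) whose early signs hide in routine complete-blood-count
(CBC) results. A screening model must learn from a handful of confirmed cases
against a huge pool of *unlabeled* patients — a pool that itself contains
undiagnosed cases, so treating it as negative biases everything. `pmfscreen`
implements the full analysis for this setting:

* a **synthetic cohort generator** producing PU-structured longitudinal EHR
  data (class-conditional CBC marginals calibrated to published per-group
  medians, Poisson visit processes, ICD-10 code emission with case-dependent
  odds, configurable hidden-positive rate) so every stage is testable without
  any private data;
* **cohort construction**: regex/ICD-10 case flagging, half-open two-year
  analysis windows, age/gender-stratified control matching, leakage-code
  exclusion (D45–D47, D70–D77, C81–C96);
* **feature engineering**: eight longitudinal aggregates per CBC parameter,
  control-anchored decile binning, presence indicators, a joint 5% prevalence
  filter, PheWAS-style phenotype mapping, Weight-of-Evidence encoding — all
  fold-safe, with missingness kept as missing;
* **univariate statistics**: balanced-class-weight logistic odds ratios, Wald
  p-values, Benjamini–Hochberg FDR, volcano tables;
* **PU wrappers** over pluggable base learners (LightGBM, XGBoost, WoE +
  random forest, one-hot logistic):

  * `ElkanNotoClassifier` — estimates the label frequency
    `c = P(labeled | positive)` as the mean score of a 10% positive holdout
    and rescales scores by `1/ĉ` (a monotone calibration);
  * `SpyClassifier` — plants 10% of positives as spies among the unlabeled,
    thresholds at the 20% noise-tolerance spy quantile, and refits on all
    positives vs the mined reliable negatives;

* **evaluation**: repeated randomized stratified k-fold CV, non-interpolated
  average precision (AP) as the priority metric, median + empirical 95% CI
  summaries, recall-binned precision–recall profiles, consensus
  misclassification with Venn overlaps, and the screening arithmetic
  (enrichment factor, review workload).

## Worked example

```python
import dataclasses, json
from pmfscreen.pipeline import RunConfig, run_pipeline
from pmfscreen.simulate import CohortConfig

cfg = RunConfig(
    seed=7, output_dir="out/demo",
    cohort=CohortConfig(n_unlabeled=600, n_labeled_positive=40,
                        hidden_positive_rate=0.05),
    k=5, reps=2, variant="elkan_noto", learner="lightgbm",
)
result = run_pipeline(cfg)
print(json.dumps({k: dataclasses.asdict(v)
                  for k, v in result.report.summary().items()}, indent=2))
print(result.report.consensus()["consensus_category"].value_counts().to_dict())
```

prints (abridged):

```
"ap":          {"median": 0.723, "ci_low": 0.466, "ci_high": 0.908}
"auroc":       {"median": 0.986, "ci_low": 0.960, "ci_high": 0.994}
"recall":      {"median": 0.750, ...}
"specificity": {"median": 0.975, ...}
{'TN': 581, 'TP': 27, 'FP': 15, 'unstable': 11, 'FN': 6}
```

Reading this: over 10 validation runs (5 folds × 2 repetitions) the
Elkan–Noto-calibrated LightGBM ranks held-out patients almost perfectly
(AUROC ≈ 0.99) and keeps a median AP of 0.72 on a 6%-positive cohort. The
consensus table classifies each patient by the outcome occurring in more
than half of their validation runs: the 15 consensus "false positives" are
unlabeled patients persistently flagged across runs — in a PU cohort these
are exactly where hidden (undiagnosed) positives concentrate, and on
synthetic cohorts their latent-positive fraction far exceeds the ~5%
background (the package's tests verify this). At study scale this is the
arithmetic that turns a modest precision into a usable screening tool:
20.81% precision over a 0.061% prevalence is a ~341-fold enrichment, and a
median of 15 flagged patients per hospital costs 15 min each ≈ 3.75 h of
physician review.

The same pipeline is scriptable from a shell:

```bash
screen simulate --config cfg.yaml --out out/cohort
screen run --config cfg.yaml --variant spy --adapter lightgbm
screen report --run-dir out
```

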