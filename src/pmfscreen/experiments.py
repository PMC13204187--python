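"""Synthetic-recovery experiments: the study-scale questions answered at desk
scale.

Each experiment generates a fresh cohort from a seed, runs the relevant slice
of the pipeline, and measures recovery of a quantity the generator knows
exactly (the latent labels or the true labeling frequency). The problem sizes
are the package's desk-scale defaults; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .cohort import windows_from_cohort
from .constants import DEFAULT_PHENOTYPE_MAPPING
from .evaluation import make_repeated_stratified_folds, run_cv
from .features import DecileBinner, build_feature_matrix, load_phewas_mapping
from .pipeline import RunConfig
from .pu import ElkanNotoClassifier, SpyClassifier, make_learner
from .simulate import (
    CohortConfig,
    generate_cohort,
    patients_frame,
    separable_parameter_specs,
    true_labeling_frequency,
)


def _binned_matrix(patients, prevalence_threshold=None):
    """Windows -> feature matrix -> globally decile-binned aggregates.

    Global binning is appropriate here because these experiments measure
    parameter recovery, not generalization error (no train/validation split).
    """
    windows = windows_from_cohort(patients)
    demo = patients_frame(patients)[["patient_id", "birth_year", "gender"]]
    matrix = build_feature_matrix(
        windows,
        demographics=demo,
        mapping=load_phewas_mapping(DEFAULT_PHENOTYPE_MAPPING),
        prevalence_threshold=prevalence_threshold,
    )
    agg = matrix.aggregate_columns
    binner = DecileBinner(columns=agg).fit(matrix.frame, matrix.labels.to_numpy())
    X = binner.transform(matrix.frame)
    return X, matrix.labels.to_numpy(), np.array([p.y_true for p in patients])


def _calibration_learner():
    """Strongly regularized one-hot logistic for the label-frequency
    experiment.

    Estimating c requires a *probability-calibrated* first-stage model: with
    ~1,900 one-hot columns on 2,000 rows the default regularization lets the
    learner partially separate labeled from latent positives on noise, making
    individual positive-region scores bimodal and the holdout mean noisy.
    C = 0.1 suppresses that separation; every positive then scores near c, as
    the SCAR identity requires.
    """
    from sklearn.impute import SimpleImputer
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import OneHotEncoder

    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="constant", fill_value=-1.0)),
            ("onehot", OneHotEncoder(handle_unknown="ignore")),
            ("clf", LogisticRegression(max_iter=2000, C=0.1)),
        ]
    )


def scar_cohort_config(
    n_unlabeled: int = 1800,
    n_labeled_positive: int = 200,
    labeling_frequency: float = 0.5,
    seed: int = 0,
) -> CohortConfig:
    """A separable SCAR cohort with a known true labeling frequency c.

    With P labeled positives, the hidden-positive rate is chosen so the
    expected latent-positive count among the unlabeled pool equals
    P (1 - c) / c, giving E[c_realized] = c.
    """
    hidden = n_labeled_positive * (1.0 - labeling_frequency) / labeling_frequency
    rate = hidden / n_unlabeled
    if not 0.0 <= rate < 1.0:
        raise ValueError("labeling frequency incompatible with cohort sizes")
    return CohortConfig(
        n_unlabeled=n_unlabeled,
        n_labeled_positive=n_labeled_positive,
        hidden_positive_rate=rate,
        parameter_specs=separable_parameter_specs(),
        seed=seed,
    )


@dataclass
class ChatRecovery:
    c_hat: float
    c_true: float
    n: int


def elkan_noto_chat_recovery(
    seed: int,
    n_unlabeled: int = 1800,
    n_labeled_positive: int = 200,
    labeling_frequency: float = 0.5,
) -> ChatRecovery:
    """Fit the Elkan-Noto wrapper on a separable SCAR cohort and compare its
    label-frequency estimate with the realized truth."""
    cfg = scar_cohort_config(n_unlabeled, n_labeled_positive, labeling_frequency, seed)
    patients = generate_cohort(cfg)
    X, s, _ = _binned_matrix(patients)
    model = ElkanNotoClassifier(
        estimator=_calibration_learner(), random_state=seed
    ).fit(X, s)
    return ChatRecovery(
        c_hat=model.c_hat_,
        c_true=true_labeling_frequency(patients),
        n=len(patients),
    )


@dataclass
class SpyPurity:
    rn_latent_fraction: float
    pool_latent_fraction: float
    n_reliable_negatives: int


def spy_reliable_negative_purity(
    seed: int,
    n_unlabeled: int = 1000,
    n_labeled_positive: int = 60,
    hidden_positive_rate: float = 0.1,
) -> SpyPurity:
    """Latent-positive contamination of the spy method's reliable negatives
    versus the unlabeled pool it mined them from."""
    cfg = CohortConfig(
        n_unlabeled=n_unlabeled,
        n_labeled_positive=n_labeled_positive,
        hidden_positive_rate=hidden_positive_rate,
        parameter_specs=separable_parameter_specs(),
        seed=seed,
    )
    patients = generate_cohort(cfg)
    X, s, y_true = _binned_matrix(patients)
    model = SpyClassifier(estimator=make_learner("logistic_bins"), random_state=seed).fit(X, s)
    unl = np.flatnonzero(s == 0)
    rn = model.reliable_negative_indices_
    return SpyPurity(
        rn_latent_fraction=float(y_true[rn].mean()),
        pool_latent_fraction=float(y_true[unl].mean()),
        n_reliable_negatives=int(rn.size),
    )


@dataclass
class FPEnrichment:
    fp_latent_fraction: float
    pool_latent_fraction: float
    n_consensus_fp: int


def consensus_fp_enrichment(
    seed: int,
    n_unlabeled: int = 500,
    n_labeled_positive: int = 30,
    hidden_positive_rate: float = 0.08,
    k: int = 5,
    reps: int = 2,
    variant: str = "baseline",
) -> FPEnrichment:
    """End-to-end desk-scale analogue of the hidden-positive finding: are the
    consensus false positives of a repeated-CV run enriched in latent
    positives relative to the unlabeled background?

    Patients with no consensus FP (empty set) yield fp_latent_fraction = NaN.
    """
    cfg = CohortConfig(
        n_unlabeled=n_unlabeled,
        n_labeled_positive=n_labeled_positive,
        hidden_positive_rate=hidden_positive_rate,
        seed=seed,
    )
    patients = generate_cohort(cfg)
    windows = windows_from_cohort(patients)
    demo = patients_frame(patients)[["patient_id", "birth_year", "gender"]]
    matrix = build_feature_matrix(
        windows,
        demographics=demo,
        mapping=load_phewas_mapping(DEFAULT_PHENOTYPE_MAPPING),
        prevalence_threshold=None,
    )
    s = matrix.labels.to_numpy()
    plan = make_repeated_stratified_folds(s, k=k, reps=reps, seed=seed)
    report = run_cv(
        matrix,
        plan,
        variant=variant,
        estimator=make_learner("logistic_bins"),
        seed=seed,
        refilter_per_fold=False,
    )
    consensus = report.consensus()
    latent = {p.patient_id: p.y_true for p in patients}
    fp_ids = consensus.loc[consensus["consensus_category"] == "FP", "patient_id"]
    unlabeled_ids = [p.patient_id for p in patients if p.s_observed == 0]
    fp_frac = (
        float(np.mean([latent[i] for i in fp_ids])) if len(fp_ids) else float("nan")
    )
    return FPEnrichment(
        fp_latent_fraction=fp_frac,
        pool_latent_fraction=float(np.mean([latent[i] for i in unlabeled_ids])),
        n_consensus_fp=int(len(fp_ids)),
    )
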