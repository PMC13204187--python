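"""Repeated stratified cross-validation and the screening metric suite.

Average precision is the priority metric and is computed without
interpolation: AP = sum_n (R_n - R_{n-1}) P_n over descending unique score
thresholds. Trapezoidal PR areas implicitly interpolate between sparse
points and overestimate performance on extremely imbalanced cohorts; the
recall-binned precision profile (median + IQR of pooled per-threshold PR
points within 10% recall bins) serves the same purpose for plots.

Threshold-dependent metrics are taken at a fixed operating point (default
0.5 on balanced/calibrated scores). Undefined ratios (0/0) are recorded as
missing and excluded from summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .constants import DEFAULT_DECISION_THRESHOLD, REVIEW_MINUTES_PER_PATIENT
from .features import DecileBinner, FeatureMatrix, prevalence_filter
from .pu import make_variant

METRIC_NAMES = ("ap", "auroc", "f1", "precision", "recall", "specificity")


# --- CV plan -----------------------------------------------------------------

@dataclass
class CVPlan:
    """Repeated stratified fold assignments: ``assignments[rep][i]`` is the
    validation fold of patient i in that repetition."""

    k: int
    reps: int
    assignments: list[np.ndarray]
    seed: int


def make_repeated_stratified_folds(
    labels: Sequence[int], k: int = 10, reps: int = 10, seed: int = 0
) -> CVPlan:
    """Randomized stratified k-fold plans for each repetition (k x reps
    validation runs in total). Per-fold labeled-positive counts differ by at
    most one within each repetition."""
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos < k:
        raise ValueError(f"{n_pos} labeled positives cannot stratify into {k} folds")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        fold_of = np.empty(labels.size, dtype=int)
        for j, (_, val_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
            fold_of[val_idx] = j
        assignments.append(fold_of)
    return CVPlan(k=k, reps=reps, assignments=assignments, seed=seed)


# --- metrics -----------------------------------------------------------------

def average_precision(truth: Sequence[int], scores: Sequence[float]) -> float:
    """Non-interpolated AP over descending unique score thresholds; NaN when
    the truth is single-class."""
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or n_pos == y.size:
        return float("nan")
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tp = np.cumsum(y_sorted == 1)
    n_pred = np.arange(1, y.size + 1)
    # evaluate only at the last occurrence of each unique score (the threshold
    # admits every tied observation at once)
    is_threshold = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    precision = tp[is_threshold] / n_pred[is_threshold]
    recall = tp[is_threshold] / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def pr_curve_points(
    truth: Sequence[int], scores: Sequence[float]
) -> list[tuple[float, float]]:
    """(recall, precision) at every descending unique score threshold."""
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        return []
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tp = np.cumsum(y_sorted == 1)
    n_pred = np.arange(1, y.size + 1)
    is_threshold = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    return [
        (float(tp[i] / n_pos), float(tp[i] / n_pred[i]))
        for i in np.flatnonzero(is_threshold)
    ]


def compute_metrics(
    truth: Sequence[int],
    scores: Sequence[float],
    threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> dict[str, float]:
    """The six-metric suite; undefined ratios (0/0) are NaN, never 0."""
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    nan = float("nan")
    out = {name: nan for name in METRIC_NAMES}
    if np.unique(y).size < 2:
        return out
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    out["ap"] = average_precision(y, s)
    out["auroc"] = float(roc_auc_score(y, s))
    out["precision"] = tp / (tp + fp) if (tp + fp) else nan
    out["recall"] = tp / (tp + fn) if (tp + fn) else nan
    out["specificity"] = tn / (tn + fp) if (tn + fp) else nan
    p, r = out["precision"], out["recall"]
    if not (math.isnan(p) or math.isnan(r)) and (p + r) > 0:
        out["f1"] = 2 * p * r / (p + r)
    return out


@dataclass
class MetricSummary:
    median: float
    ci_low: float
    ci_high: float


def summarize_metric(values: Sequence[float]) -> MetricSummary:
    """Median and empirical 95% CI (2.5th/97.5th percentiles, linear
    interpolation) over the defined values; missing entries are excluded."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no defined values to summarize")
    lo, med, hi = np.percentile(arr, [2.5, 50, 97.5])
    return MetricSummary(float(med), float(lo), float(hi))


# --- recall-binned PR profile ------------------------------------------------

def binned_pr_profile(
    points: Sequence[tuple[float, float]], bin_width: float = 0.1
) -> pd.DataFrame:
    """Median and IQR of precision within recall bins, over the pooled
    per-threshold PR points of all runs. The last bin is closed so recall = 1
    is counted. Empty bins appear with n_points = 0."""
    n_bins = int(round(1.0 / bin_width))
    rows = []
    arr = np.asarray(points, dtype=float).reshape(-1, 2)
    for i in range(n_bins):
        lo, hi = i * bin_width, (i + 1) * bin_width
        if i == n_bins - 1:
            mask = (arr[:, 0] >= lo) & (arr[:, 0] <= hi) if arr.size else np.array([], bool)
        else:
            mask = (arr[:, 0] >= lo) & (arr[:, 0] < hi) if arr.size else np.array([], bool)
        prec = arr[mask, 1] if arr.size else np.array([])
        if prec.size:
            q25, med, q75 = np.percentile(prec, [25, 50, 75])
        else:
            q25 = med = q75 = float("nan")
        rows.append(
            {
                "recall_bin_low": lo,
                "recall_bin_high": hi,
                "median_precision": med,
                "q25": q25,
                "q75": q75,
                "n_points": int(prec.size),
            }
        )
    return pd.DataFrame(rows)


# --- consensus misclassification --------------------------------------------

def consensus_classify(
    predictions: pd.DataFrame, truth: Mapping[str, int]
) -> pd.DataFrame:
    """Per-patient consensus category across validation runs.

    ``predictions`` needs columns patient_id and predicted (0/1); a patient is
    assigned the outcome that occurs in strictly more than half of their
    evaluations, crossed with their truth label into TP/FP/FN/TN. Exact ties
    are ``unstable``.
    """
    grouped = predictions.groupby("patient_id")["predicted"]
    n_eval = grouped.count()
    n_pos = grouped.sum()
    rows = []
    for pid in n_eval.index:
        n, npos = int(n_eval[pid]), int(n_pos[pid])
        if 2 * npos > n:
            majority = 1
        elif 2 * (n - npos) > n:
            majority = 0
        else:
            majority = None
        t = int(truth[pid])
        if majority is None:
            category = "unstable"
        elif t == 1:
            category = "TP" if majority == 1 else "FN"
        else:
            category = "FP" if majority == 1 else "TN"
        rows.append(
            {
                "patient_id": pid,
                "n_evaluations": n,
                "n_predicted_positive": npos,
                "consensus_category": category,
            }
        )
    return pd.DataFrame(rows)


def venn_counts(category_sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every intersection region across model variants for one
    consensus category. Keys are the sorted tuple of variants a patient
    belongs to; regions partition the union of all sets."""
    names = sorted(category_sets)
    union = set().union(*category_sets.values()) if category_sets else set()
    regions: dict[tuple[str, ...], int] = {}
    for member in union:
        key = tuple(n for n in names if member in category_sets[n])
        regions[key] = regions.get(key, 0) + 1
    return regions


def consensus_venn(
    consensus_by_variant: Mapping[str, pd.DataFrame], category: str
) -> dict[tuple[str, ...], int]:
    """Venn regions for one category (TP/FP/FN/TN) across model variants;
    all variants must cover the same patient universe."""
    universes = {
        name: set(df["patient_id"]) for name, df in consensus_by_variant.items()
    }
    first = next(iter(universes.values()))
    for name, uni in universes.items():
        if uni != first:
            raise ValueError(f"variant {name!r} covers a different patient universe")
    sets = {
        name: set(df.loc[df["consensus_category"] == category, "patient_id"])
        for name, df in consensus_by_variant.items()
    }
    return venn_counts(sets)


# --- screening arithmetic ----------------------------------------------------

def enrichment_factor(precision_pct: float, prevalence_pct: float) -> float:
    """How much denser positives are among flagged patients than in the
    population: precision / prevalence (both in %)."""
    if prevalence_pct <= 0:
        raise ValueError("prevalence must be > 0")
    return precision_pct / prevalence_pct


def workload_estimate(
    n_flagged: int, minutes_per_patient: float = REVIEW_MINUTES_PER_PATIENT
) -> float:
    """Physician review hours implied by a flagged-patient count."""
    if n_flagged < 0:
        raise ValueError("n_flagged must be >= 0")
    return n_flagged * minutes_per_patient / 60.0


# --- repeated-CV driver ------------------------------------------------------

@dataclass
class CVReport:
    """Everything one repeated-CV evaluation produced."""

    runs: pd.DataFrame  # one row per (rep, fold) with the metric suite
    predictions: pd.DataFrame  # patient_id, rep, fold, score, predicted, s_label
    pr_points: list[tuple[float, float]] = field(default_factory=list)

    def summary(self) -> dict[str, MetricSummary]:
        out = {}
        for name in METRIC_NAMES:
            values = self.runs[name].to_numpy()
            if np.isnan(values).all():
                continue
            out[name] = summarize_metric(values)
        return out

    def profile(self, bin_width: float = 0.1) -> pd.DataFrame:
        return binned_pr_profile(self.pr_points, bin_width)

    def consensus(self) -> pd.DataFrame:
        truth = (
            self.predictions.drop_duplicates("patient_id")
            .set_index("patient_id")["s_label"]
            .to_dict()
        )
        return consensus_classify(self.predictions, truth)


def run_cv(
    matrix: FeatureMatrix,
    plan: CVPlan,
    variant: str = "baseline",
    estimator=None,
    threshold: float = DEFAULT_DECISION_THRESHOLD,
    seed: int = 0,
    refilter_per_fold: bool = True,
) -> CVReport:
    """Evaluate one model variant under a repeated stratified CV plan.

    All feature-engineering fits happen inside training folds: the prevalence
    filter is re-applied on training rows, decile bin edges are fitted on the
    training controls, and PU holdout/spy draws use per-run seeds derived from
    ``seed``. Validation folds are only ever transformed and scored.
    """
    frame, schema = matrix.frame, matrix.schema
    s = matrix.labels.to_numpy()
    ids = frame.index.to_numpy()
    rng = np.random.default_rng(seed)
    run_rows, pred_rows, pr_points = [], [], []
    for rep, fold in product(range(plan.reps), range(plan.k)):
        fold_of = plan.assignments[rep]
        val_mask = fold_of == fold
        train_mask = ~val_mask
        X_train, X_val = frame.loc[train_mask], frame.loc[val_mask]
        s_train, s_val = s[train_mask], s[val_mask]

        if refilter_per_fold:
            retained = prevalence_filter(X_train, s_train, schema)
            X_train, X_val = X_train[retained], X_val[retained]
        agg_cols = [c for c in X_train.columns if schema[c] == "aggregate"]
        if agg_cols:
            binner = DecileBinner(columns=agg_cols).fit(X_train, s_train)
            X_train, X_val = binner.transform(X_train), binner.transform(X_val)

        run_seed = int(rng.integers(0, 2**31 - 1))
        model = make_variant(
            variant,
            estimator=clone(estimator) if estimator is not None else None,
            random_state=run_seed,
        )
        model.fit(X_train, s_train)
        scores = model.predict_proba(X_val)[:, 1]

        metrics = compute_metrics(s_val, scores, threshold)
        run_rows.append({"rep": rep, "fold": fold, **metrics})
        pr_points.extend(pr_curve_points(s_val, scores))
        pred = (scores >= threshold).astype(int)
        for pid, sc, pr, sl in zip(ids[val_mask], scores, pred, s_val):
            pred_rows.append(
                {
                    "patient_id": pid,
                    "rep": rep,
                    "fold": fold,
                    "score": float(sc),
                    "predicted": int(pr),
                    "s_label": int(sl),
                }
            )
    return CVReport(
        runs=pd.DataFrame(run_rows),
        predictions=pd.DataFrame(pred_rows),
        pr_points=pr_points,
    )
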