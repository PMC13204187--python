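"""Univariate effect estimation: class-balanced logistic odds ratios, BH-FDR
control, and volcano-table construction.

Each feature is tested on its raw scale (binning is a modeling device, not a
statistical one) with a single-predictor logistic regression under balanced
class weights ``w_class = n_total / (2 n_class)`` and a Wald p-value. For a
binary predictor the balanced-weight MLE slope equals the log cross-product
ratio of the 2x2 table, so class weighting leaves the OR unchanged — a
property the test suite verifies against a brute-force likelihood maximizer.

Untestable features (zero variance, single-class labels) yield flagged
results with missing OR rather than exceptions, and are excluded from the BH
multiplicity count m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .constants import FDR_ALPHA, VOLCANO_LOG2_OR_THRESHOLD


@dataclass
class UnivariateResult:
    feature: str
    odds_ratio: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False
    flag: str = ""  # nonempty when the feature was untestable

    @property
    def log2_or(self) -> float:
        return math.log2(self.odds_ratio) if self.odds_ratio > 0 else float("nan")


def balanced_class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-observation weights n_total / (2 n_class)."""
    labels = np.asarray(labels)
    n = labels.size
    w = np.empty(n, dtype=float)
    for cls in (0, 1):
        mask = labels == cls
        w[mask] = n / (2.0 * mask.sum())
    return w


def balanced_logistic_or(
    feature_values: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """(odds_ratio, Wald p-value) from a single-predictor logistic fit with
    balanced class weighting.

    Returns (nan, nan) for untestable input — constant feature or single-class
    labels — so batch runs stay alive; callers can inspect the flag via
    :func:`univariate_table`.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    if x.size == 0 or np.unique(y).size < 2 or np.nanstd(x) == 0:
        return float("nan"), float("nan")
    X = sm.add_constant(x)
    weights = balanced_class_weights(y.astype(int))
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=weights).fit()
    except Exception:
        return float("nan"), float("nan")
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    if not np.isfinite(slope) or not np.isfinite(p):
        return float("nan"), float("nan")
    # quasi-separated features produce enormous slopes; cap so the OR stays
    # a finite (if extreme) number rather than overflowing
    return float(math.exp(np.clip(slope, -50.0, 50.0))), p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    monotonicity enforced, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_table(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Per-feature balanced-logistic OR with BH adjustment across the testable
    features (untestable ones carry a flag and do not enter m)."""
    labels = np.asarray(labels)
    results: list[UnivariateResult] = []
    for col in matrix.columns:
        or_, p = balanced_logistic_or(matrix[col].to_numpy(dtype=float), labels)
        flag = "" if np.isfinite(p) else "untestable"
        results.append(UnivariateResult(col, or_, p, flag=flag))
    testable = [r for r in results if not r.flag]
    if testable:
        adjusted = bh_adjust([r.p_value for r in testable])
        for r, padj in zip(testable, adjusted):
            r.p_adjusted = float(padj)
            r.significant = bool(padj < alpha)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "log2_or": [r.log2_or for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
            "flag": [r.flag for r in results],
        }
    )


def volcano_table(
    results: pd.DataFrame,
    log2_or_threshold: float = VOLCANO_LOG2_OR_THRESHOLD,
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Volcano-plot rows: effect_flag marks |log2 OR| >= 0.585 (OR outside
    [0.67, 1.5]) at adjusted p strictly below alpha."""
    out = results[["feature", "log2_or"]].copy()
    out["neg_log10_p_adjusted"] = -np.log10(results["p_adjusted"])
    out["effect_flag"] = (
        (results["log2_or"].abs() >= log2_or_threshold)
        & (results["p_adjusted"] < alpha)
    ).fillna(False)
    return out


def compare_partitions(
    matrix: pd.DataFrame, partition_labels: Sequence[int], alpha: float = FDR_ALPHA
) -> pd.DataFrame:
    """Rerun the univariate machinery with an arbitrary binary partition as the
    outcome — e.g. consensus false positives vs true negatives."""
    labels = np.asarray(partition_labels)
    if not ((labels == 1).sum() >= 2 and (labels == 0).sum() >= 2):
        raise ValueError("both partition cells need at least two members")
    return univariate_table(matrix, labels, alpha)
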