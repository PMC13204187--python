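"""Positive-unlabeled wrappers over pluggable base learners.

Two classical PU strategies for screening with incomplete labels:

* **Elkan-Noto calibration** — under the SCAR assumption (labeled positives
  selected completely at random from all positives), a non-traditional
  classifier trained to separate labeled positives from the unlabeled mixture
  satisfies ``g(x) = c * p(y=1|x)``, with ``c`` the label frequency. ``c`` is
  estimated as the mean score of a held-out set of labeled positives and the
  wrapper rescales scores by ``1/c`` (capped at 1). The transform is monotone,
  so rankings — and hence AP/AUROC — are unchanged; only the probability
  scale and the position of a fixed decision threshold move.

* **Spy reliable-negative mining** — a two-step method: a fraction of labeled
  positives is planted among the unlabeled ("spies"), a first-stage model is
  fit, and the spy score distribution sets a threshold below which unlabeled
  samples are deemed reliable negatives (the noise tolerance is the fraction
  of spies allowed to fall below the threshold). A second-stage model is then
  fit on all labeled positives versus the reliable negatives only; the
  remaining unlabeled samples are excluded from the fit and only scored at
  prediction time.

The spy stages and the supervised baseline pass class-balancing sample
weights (inverse class frequency) to the base learner; the Elkan-Noto first
stage is unweighted because its calibration constant is only meaningful for
an uncorrected probability estimate. Both wrappers are scikit-learn
estimators:
``fit(X, s)`` takes the *observed* PU label (1 = labeled positive,
0 = unlabeled), ``predict_proba``/``predict`` behave as usual.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

from .constants import DEFAULT_DECISION_THRESHOLD
from .features import WoEEncoder

_EPS = 1e-6


# --- base-learner adapters ---------------------------------------------------

def make_learner(name: str, random_state: int | None = None):
    """Construct a base-learner adapter by name.

    ``logistic_bins`` is the dependency-light default: missing-as-category
    one-hot encoding of the binned features followed by L2 logistic
    regression. ``lightgbm`` / ``xgboost`` use the boosted-tree libraries with
    native missing-value handling and deliberately strong regularization
    (shallow trees, few rounds) suited to tiny positive cohorts.
    ``random_forest_woe`` applies Weight-of-Evidence encoding before a random
    forest, which cannot consume the missing sentinel natively.
    """
    if name == "logistic_bins":
        return Pipeline(
            [
                ("impute", SimpleImputer(strategy="constant", fill_value=-1.0)),
                ("onehot", OneHotEncoder(handle_unknown="ignore")),
                ("clf", LogisticRegression(max_iter=2000, C=1.0)),
            ]
        )
    if name == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=150,
            max_depth=4,
            num_leaves=15,
            learning_rate=0.05,
            min_child_samples=5,
            reg_lambda=1.0,
            random_state=random_state,
            verbose=-1,
        )
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=150,
            max_depth=4,
            learning_rate=0.05,
            reg_lambda=1.0,
            random_state=random_state or 0,
            verbosity=0,
            eval_metric="logloss",
        )
    if name == "random_forest_woe":
        return Pipeline(
            [
                ("woe", WoEEncoder()),
                (
                    "clf",
                    RandomForestClassifier(
                        n_estimators=200, max_depth=6, random_state=random_state
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown learner {name!r}")


def balanced_sample_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weights: w_i = n / (2 n_class(y_i))."""
    y = np.asarray(y)
    n = y.size
    w = np.empty(n, dtype=float)
    for cls in np.unique(y):
        mask = y == cls
        w[mask] = n / (2.0 * mask.sum())
    return w


def fit_adapter(estimator, X, y, sample_weight=None):
    """Fit a bare estimator or a Pipeline whose final step is named ``clf``,
    routing sample weights appropriately."""
    if sample_weight is None:
        return estimator.fit(X, y)
    if isinstance(estimator, Pipeline):
        return estimator.fit(X, y, clf__sample_weight=sample_weight)
    return estimator.fit(X, y, sample_weight=sample_weight)


def predict_scores(estimator, X) -> np.ndarray:
    """Positive-class scores in [0, 1]."""
    return np.asarray(estimator.predict_proba(X))[:, 1]


def gain_importance(estimator) -> pd.Series | None:
    """Base-learner gain/impurity feature importances where available."""
    est = estimator.steps[-1][1] if isinstance(estimator, Pipeline) else estimator
    imp = getattr(est, "feature_importances_", None)
    if imp is None:
        return None
    return pd.Series(np.asarray(imp, dtype=float))


class BalancedClassifier(ClassifierMixin, BaseEstimator):
    """Supervised baseline: the base learner fitted with balanced sample
    weights, treating unlabeled as negative. The reference point the PU
    wrappers are compared against."""

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.array([0, 1])
        self.estimator_ = clone(self.estimator) if self.estimator is not None else make_learner("logistic_bins")
        fit_adapter(self.estimator_, X, y, balanced_sample_weights(y))
        return self

    def predict_proba(self, X):
        s = predict_scores(self.estimator_, X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= DEFAULT_DECISION_THRESHOLD).astype(int)


# --- Elkan-Noto --------------------------------------------------------------

class ElkanNotoClassifier(ClassifierMixin, BaseEstimator):
    """Label-frequency calibrated PU classifier.

    Fitted attributes: ``estimator_`` (base fitted on labeled-positive vs
    unlabeled, excluding the holdout), ``c_hat_`` (mean holdout score, the
    label-frequency estimate, in (0, 1]) and ``holdout_indices_`` (positional
    indices of the held-out labeled positives).

    The first-stage fit is deliberately *unweighted*: the calibration constant
    is only the label frequency when the base learner estimates the plain
    conditional probability P(s=1|x); class-balancing weights would inflate
    every score in the positive region and with it the estimate of c. Class
    imbalance is instead handled downstream by the 1/c rescaling itself, which
    moves the operating point exactly as a prior correction would.
    """

    def __init__(
        self,
        estimator=None,
        holdout_frac: float = 0.1,
        random_state: int | None = None,
    ):
        self.estimator = estimator
        self.holdout_frac = holdout_frac
        self.random_state = random_state

    def fit(self, X, s):
        s = np.asarray(s)
        pos = np.flatnonzero(s == 1)
        if pos.size < 10:
            raise ValueError(
                f"need at least 10 labeled positives for a meaningful holdout, got {pos.size}"
            )
        rng = np.random.default_rng(self.random_state)
        n_holdout = max(1, math.ceil(self.holdout_frac * pos.size))
        if n_holdout >= pos.size:
            raise ValueError("holdout would consume every labeled positive")
        holdout = rng.choice(pos, size=n_holdout, replace=False)
        self.holdout_indices_ = np.sort(holdout)

        train_mask = np.ones(s.size, dtype=bool)
        train_mask[self.holdout_indices_] = False
        X_train = _take(X, train_mask)
        y_train = s[train_mask]
        base = clone(self.estimator) if self.estimator is not None else make_learner("logistic_bins")
        fit_adapter(base, X_train, y_train)  # unweighted: g(x) must estimate P(s=1|x)
        self.estimator_ = base

        holdout_scores = predict_scores(base, _take(X, self.holdout_indices_))
        c_hat = float(np.mean(holdout_scores))
        if c_hat <= _EPS:
            raise ValueError(
                f"estimated label frequency {c_hat:.3g} <= {_EPS}: the base learner "
                "assigns no probability mass to held-out positives (uninformative fit)"
            )
        self.c_hat_ = min(c_hat, 1.0)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        raw = predict_scores(self.estimator_, X)
        cal = np.minimum(1.0, raw / self.c_hat_)
        return np.column_stack([1.0 - cal, cal])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= DEFAULT_DECISION_THRESHOLD).astype(int)

    def to_sidecar(self) -> dict:
        return {
            "method": "elkan_noto",
            "c_hat": self.c_hat_,
            "holdout_indices": self.holdout_indices_.tolist(),
        }


# --- Spy ---------------------------------------------------------------------

class SpyClassifier(ClassifierMixin, BaseEstimator):
    """Two-step spy-based PU classifier.

    Fitted attributes: ``estimator_`` (the second-stage model),
    ``threshold_t_`` (the ceil(noise_tol * n_spies)-th smallest spy score),
    ``spy_indices_`` and ``reliable_negative_indices_`` (positional). Reliable
    negatives are the non-spy unlabeled samples scoring strictly below the
    threshold in the first stage.
    """

    def __init__(
        self,
        estimator=None,
        spy_frac: float = 0.1,
        noise_tol: float = 0.2,
        random_state: int | None = None,
    ):
        self.estimator = estimator
        self.spy_frac = spy_frac
        self.noise_tol = noise_tol
        self.random_state = random_state

    def fit(self, X, s):
        s = np.asarray(s)
        pos = np.flatnonzero(s == 1)
        unl = np.flatnonzero(s == 0)
        if pos.size < 10:
            raise ValueError(
                f"need at least 10 labeled positives to plant spies, got {pos.size}"
            )
        if unl.size < 1:
            raise ValueError("need at least 1 unlabeled sample")
        rng = np.random.default_rng(self.random_state)
        n_spies = math.ceil(self.spy_frac * pos.size)
        if n_spies >= pos.size:
            raise ValueError("spy fraction would consume every labeled positive")
        spies = np.sort(rng.choice(pos, size=n_spies, replace=False))
        self.spy_indices_ = spies

        # stage 1: remaining positives vs (unlabeled + spies)
        y1 = s.copy()
        y1[spies] = 0
        stage1 = clone(self.estimator) if self.estimator is not None else make_learner("logistic_bins")
        fit_adapter(stage1, X, y1, balanced_sample_weights(y1))
        spy_scores = np.sort(predict_scores(stage1, _take(X, spies)))
        k = max(1, math.ceil(self.noise_tol * n_spies))
        self.threshold_t_ = float(spy_scores[k - 1])

        unl_scores = predict_scores(stage1, _take(X, unl))
        rn = unl[unl_scores < self.threshold_t_]
        if rn.size == 0:
            raise ValueError(
                "no unlabeled sample scored below the spy threshold "
                f"t={self.threshold_t_:.3g}: the first-stage learner cannot rank the "
                "unlabeled pool against spies — try a larger noise tolerance or a "
                "stronger base learner"
            )
        self.reliable_negative_indices_ = np.sort(rn)

        # stage 2: all original labeled positives (spies returned) vs reliable negatives
        idx = np.concatenate([pos, self.reliable_negative_indices_])
        y2 = np.concatenate([np.ones(pos.size, dtype=int), np.zeros(rn.size, dtype=int)])
        final = clone(self.estimator) if self.estimator is not None else make_learner("logistic_bins")
        fit_adapter(final, _take(X, idx), y2, balanced_sample_weights(y2))
        self.estimator_ = final
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        scores = predict_scores(self.estimator_, X)
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= DEFAULT_DECISION_THRESHOLD).astype(int)

    def to_sidecar(self) -> dict:
        return {
            "method": "spy",
            "threshold_t": self.threshold_t_,
            "spy_indices": self.spy_indices_.tolist(),
            "reliable_negative_indices": self.reliable_negative_indices_.tolist(),
        }


def _take(X, indexer):
    """Row selection that works for DataFrames and arrays with either a
    boolean mask or positional indices."""
    if isinstance(X, pd.DataFrame):
        return X.iloc[indexer]
    return np.asarray(X)[indexer]


PU_VARIANTS = ("baseline", "elkan_noto", "spy")


def make_variant(
    variant: str,
    estimator=None,
    random_state: int | None = None,
    holdout_frac: float = 0.1,
    spy_frac: float = 0.1,
    noise_tol: float = 0.2,
):
    """Wrap a base learner in the requested classification strategy."""
    if variant == "baseline":
        return BalancedClassifier(estimator=estimator)
    if variant == "elkan_noto":
        return ElkanNotoClassifier(
            estimator=estimator, holdout_frac=holdout_frac, random_state=random_state
        )
    if variant == "spy":
        return SpyClassifier(
            estimator=estimator,
            spy_frac=spy_frac,
            noise_tol=noise_tol,
            random_state=random_state,
        )
    raise ValueError(f"unknown variant {variant!r}; expected one of {PU_VARIANTS}")
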