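"""Evaluation framework: CV plans, metrics, PR profiles, consensus, arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import average_precision_score

from pmfscreen.evaluation import (
    average_precision,
    binned_pr_profile,
    compute_metrics,
    consensus_classify,
    consensus_venn,
    enrichment_factor,
    make_repeated_stratified_folds,
    pr_curve_points,
    run_cv,
    summarize_metric,
    venn_counts,
    workload_estimate,
)
from pmfscreen.pu import make_learner


def ap_threshold_sweep(y, s):
    """Brute-force AP: explicit confusion counts at every unique threshold."""
    y, s = np.asarray(y), np.asarray(s)
    ap, prev_r = 0.0, 0.0
    for t in np.sort(np.unique(s))[::-1]:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        p = tp / pred.sum()
        r = tp / (y == 1).sum()
        ap += (r - prev_r) * p
        prev_r = r
    return ap


class TestCVPlan:
    def test_exact_stratification_one_positive_per_fold(self):
        labels = np.r_[np.ones(10), np.zeros(90)]
        plan = make_repeated_stratified_folds(labels, k=10, reps=3, seed=0)
        for fold_of in plan.assignments:
            pos_per_fold = np.bincount(fold_of[labels == 1], minlength=10)
            assert (pos_per_fold == 1).all()

    def test_partition_and_stratification_grid(self, rng):
        for _ in range(10):
            n = int(rng.integers(40, 200))
            k = int(rng.integers(2, 8))
            n_pos = int(rng.integers(k, max(k + 1, n // 4)))
            reps = int(rng.integers(1, 4))
            labels = rng.permutation(np.r_[np.ones(n_pos), np.zeros(n - n_pos)])
            plan = make_repeated_stratified_folds(labels, k=k, reps=reps, seed=int(rng.integers(1e6)))
            for fold_of in plan.assignments:
                assert fold_of.size == n
                assert set(fold_of) == set(range(k))  # every patient in exactly one fold
                pos_counts = np.bincount(fold_of[labels == 1], minlength=k)
                assert pos_counts.max() - pos_counts.min() <= 1

    def test_same_seed_same_plan(self):
        labels = np.r_[np.ones(12), np.zeros(88)]
        a = make_repeated_stratified_folds(labels, k=4, reps=2, seed=5)
        b = make_repeated_stratified_folds(labels, k=4, reps=2, seed=5)
        for fa, fb in zip(a.assignments, b.assignments):
            np.testing.assert_array_equal(fa, fb)

    def test_fewer_positives_than_folds_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            make_repeated_stratified_folds(np.r_[np.ones(3), np.zeros(97)], k=10)


class TestAveragePrecision:
    def test_worked_example(self):
        assert average_precision([1, 0, 1], [0.9, 0.8, 0.7]) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert average_precision([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_single_class_is_missing(self):
        assert math.isnan(average_precision([1, 1], [0.5, 0.6]))

    def test_matches_brute_force_and_sklearn_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() in (0, n):
                continue
            s = rng.random(n).round(1)  # heavy ties
            ap = average_precision(y, s)
            assert ap == pytest.approx(ap_threshold_sweep(y, s), abs=1e-12)
            assert ap == pytest.approx(average_precision_score(y, s), abs=1e-12)

    def test_random_scores_approach_prevalence(self, rng):
        n, pi = 20_000, 0.3
        y = (rng.random(n) < pi).astype(int)
        s = rng.random(n)
        assert average_precision(y, s) == pytest.approx(pi, abs=0.02)

    def test_auroc_equals_mann_whitney(self, rng):
        from pmfscreen.evaluation import compute_metrics

        for _ in range(20):
            n = int(rng.integers(20, 150))
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            s = rng.random(n).round(1)
            auroc = compute_metrics(y, s)["auroc"]
            u = stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
            assert auroc == pytest.approx(u / (y.sum() * (n - y.sum())), abs=1e-12)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert all(m[k] == 1.0 for k in ("ap", "auroc", "f1", "precision", "recall", "specificity"))

    def test_all_negative_predictions(self):
        m = compute_metrics([1, 0, 0], [0.1, 0.2, 0.3])
        assert m["recall"] == 0.0
        assert m["specificity"] == 1.0
        assert math.isnan(m["precision"])  # 0/0 stays missing
        assert math.isnan(m["f1"])

    def test_confusion_counts_at_half_threshold(self):
        # scores (0.9, 0.8, 0.7) with truth (1, 0, 1): all predicted positive
        m = compute_metrics([1, 0, 1], [0.9, 0.8, 0.7], threshold=0.5)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == 1.0
        assert m["specificity"] == 0.0

    def test_single_class_truth_flagged(self):
        m = compute_metrics([1, 1], [0.5, 0.9])
        assert all(math.isnan(v) for v in m.values())


class TestSummaries:
    def test_constant_vector_collapses(self):
        s = summarize_metric([0.4, 0.4, 0.4])
        assert s.ci_low == s.median == s.ci_high == 0.4

    def test_percentile_oracle_1_to_100(self):
        s = summarize_metric(np.arange(1.0, 101.0))
        assert s.median == 50.5
        assert s.ci_low == pytest.approx(3.475)
        assert s.ci_high == pytest.approx(97.525)

    def test_missing_excluded(self):
        s = summarize_metric([float("nan"), 1.0, 3.0])
        assert s.median == 2.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            summarize_metric([float("nan")])


class TestPRProfile:
    def test_two_point_bin_median(self):
        profile = binned_pr_profile([(0.15, 0.8), (0.12, 0.6)])
        row = profile.iloc[1]  # the [0.1, 0.2) bin
        assert row["recall_bin_low"] == pytest.approx(0.1)
        assert row["median_precision"] == pytest.approx(0.7)
        assert row["n_points"] == 2

    def test_empty_bins_reported(self):
        profile = binned_pr_profile([(0.95, 0.5)])
        assert profile["n_points"].sum() == 1
        assert (profile["n_points"] == 0).sum() == 9

    def test_matches_groupby_oracle(self, rng):
        points = [(float(r), float(p)) for r, p in rng.random((500, 2))]
        profile = binned_pr_profile(points)
        df = pd.DataFrame(points, columns=["recall", "precision"])
        df["bin"] = np.minimum((df["recall"] / 0.1).astype(int), 9)
        expected = df.groupby("bin")["precision"].median()
        for b, med in expected.items():
            assert profile.loc[b, "median_precision"] == pytest.approx(med)

    def test_pr_points_consistent_with_ap(self, rng):
        y = (rng.random(100) < 0.3).astype(int)
        s = rng.random(100)
        points = pr_curve_points(y, s)
        recalls = [r for r, _ in points]
        assert recalls == sorted(recalls)
        assert recalls[-1] == 1.0


class TestConsensus:
    def _preds(self, pid, outcomes):
        return pd.DataFrame(
            {
                "patient_id": [pid] * len(outcomes),
                "predicted": outcomes,
            }
        )

    def test_majority_positive_truth_positive_is_tp(self):
        df = self._preds("a", [1] * 6 + [0] * 4)
        out = consensus_classify(df, {"a": 1})
        assert out["consensus_category"].item() == "TP"

    def test_exact_tie_is_unstable(self):
        df = self._preds("a", [1] * 5 + [0] * 5)
        out = consensus_classify(df, {"a": 1})
        assert out["consensus_category"].item() == "unstable"

    def test_unanimous_negative_truth_positive_is_fn(self):
        df = self._preds("a", [0] * 10)
        out = consensus_classify(df, {"a": 1})
        assert out["consensus_category"].item() == "FN"

    def test_fp_and_tn_for_unlabeled_truth(self):
        df = pd.concat([self._preds("u1", [1, 1, 0]), self._preds("u2", [0, 0, 1])])
        out = consensus_classify(df, {"u1": 0, "u2": 0}).set_index("patient_id")
        assert out.loc["u1", "consensus_category"] == "FP"
        assert out.loc["u2", "consensus_category"] == "TN"


class TestVenn:
    def test_identical_variants_all_in_full_intersection(self):
        regions = venn_counts({"a": {1, 2, 3}, "b": {1, 2, 3}})
        assert regions == {("a", "b"): 3}

    def test_disjoint_sets(self):
        regions = venn_counts({"a": {1, 2, 3}, "b": {4, 5, 6, 7}})
        assert regions == {("a",): 3, ("b",): 4}

    def test_regions_partition_union(self, rng):
        sets = {
            name: set(rng.integers(0, 50, size=20).tolist()) for name in ("x", "y", "z")
        }
        regions = venn_counts(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_mismatched_universes_rejected(self):
        a = pd.DataFrame({"patient_id": ["p1"], "consensus_category": ["FP"]})
        b = pd.DataFrame({"patient_id": ["p2"], "consensus_category": ["FP"]})
        with pytest.raises(ValueError, match="universe"):
            consensus_venn({"a": a, "b": b}, "FP")


class TestScreeningArithmetic:
    def test_enrichment_published_numbers(self):
        assert enrichment_factor(20.81, 0.061) == pytest.approx(341.1, abs=0.05)

    def test_enrichment_identity_and_error(self):
        assert enrichment_factor(0.061, 0.061) == 1.0
        with pytest.raises(ValueError):
            enrichment_factor(10.0, 0.0)

    @pytest.mark.parametrize("n,hours", [(15, 3.75), (0, 0.0), (4, 1.0)])
    def test_workload(self, n, hours):
        assert workload_estimate(n) == hours

    def test_negative_flagged_rejected(self):
        with pytest.raises(ValueError):
            workload_estimate(-1)


class TestRunCV:
    def test_fold_safe_run_covers_every_patient(self, small_matrix):
        labels = small_matrix.labels.to_numpy()
        plan = make_repeated_stratified_folds(labels, k=5, reps=1, seed=3)
        report = run_cv(
            small_matrix, plan, variant="baseline",
            estimator=make_learner("logistic_bins"), seed=3,
        )
        assert len(report.runs) == 5
        assert sorted(report.predictions["patient_id"].unique()) == sorted(
            small_matrix.frame.index
        )
        assert report.predictions.groupby("patient_id").size().eq(1).all()
        summary = report.summary()
        assert 0.5 <= summary["auroc"].median <= 1.0
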