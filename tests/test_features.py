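"""Feature engineering: aggregation, binning, filtering, WoE encoding."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmfscreen.features import (
    DecileBinner,
    WoEEncoder,
    aggregate_series,
    apply_bins,
    build_feature_matrix,
    fit_bins,
    load_phewas_mapping,
    map_phewas,
    prevalence_filter,
)


class TestAggregateSeries:
    def test_three_point_series_matches_direct_formulas(self):
        agg = aggregate_series([1, 2, 3])
        assert agg == {
            "p25": 1.5,
            "p50": 2.0,
            "p75": 2.5,
            "min": 1.0,
            "max": 3.0,
            "variance": 1.0,
            "first_last_absdiff": 2.0,
            "monotonic_increase": 1.0,
        }

    def test_singleton(self):
        agg = aggregate_series([5])
        assert agg["p25"] == agg["p50"] == agg["p75"] == agg["min"] == agg["max"] == 5.0
        assert agg["variance"] == 0.0
        assert agg["first_last_absdiff"] == 0.0
        assert agg["monotonic_increase"] == 0.0  # tie rule: not an increase

    def test_decreasing_series(self):
        agg = aggregate_series([3, 1])
        assert agg["first_last_absdiff"] == 2.0
        assert agg["monotonic_increase"] == 0.0

    def test_empty_series_is_all_missing(self):
        agg = aggregate_series([])
        assert all(math.isnan(v) for v in agg.values())

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.1, 1e4), min_size=1, max_size=30))
    def test_order_statistics_inequality(self, values):
        agg = aggregate_series(values)
        assert agg["min"] <= agg["p25"] <= agg["p50"] <= agg["p75"] <= agg["max"]
        assert agg["variance"] >= 0
        assert agg["first_last_absdiff"] >= 0


class TestBinning:
    def test_first_edge_of_1_to_100(self):
        edges = fit_bins(np.arange(1, 101))
        assert edges[0] == pytest.approx(10.9)
        assert len(edges) == 9

    def test_constant_feature_maps_everything_to_one_interval(self):
        edges = fit_bins([7.0] * 20)
        assert (edges == 7.0).all()
        assert apply_bins(7.0, edges) == 0  # equal to edge -> lower interval

    def test_too_few_control_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_bins(np.arange(9))

    def test_apply_bins_extremes_and_ties(self):
        edges = np.arange(1.0, 10.0)  # 1..9
        assert apply_bins(0.5, edges) == 0
        assert apply_bins(99.0, edges) == 9
        assert apply_bins(3.0, edges) == 2  # tie goes to the lower interval
        assert math.isnan(apply_bins(float("nan"), edges))

    def test_uniform_sample_gives_near_equal_occupancy(self, rng):
        values = rng.uniform(0, 1, 10_000)
        edges = fit_bins(values)
        bins = np.searchsorted(edges, values, side="left")
        occupancy = np.bincount(bins, minlength=10) / values.size
        assert np.all(np.abs(occupancy - 0.1) <= 0.01)

    def test_binner_fits_on_controls_only(self):
        X = pd.DataFrame({"f": np.r_[np.arange(100.0), np.full(10, 1e6)]})
        y = np.r_[np.zeros(100), np.ones(10)]
        binner = DecileBinner(columns=["f"]).fit(X, y)
        # case values played no role in the edges
        assert binner.edges_["f"][-1] < 100
        out = binner.transform(X)
        assert (out["f"].iloc[-10:] == 9).all()

    def test_all_missing_feature_is_named_in_error(self):
        X = pd.DataFrame({"good": np.arange(20.0), "bad": np.full(20, np.nan)})
        with pytest.raises(ValueError, match="bad"):
            DecileBinner().fit(X, np.zeros(20))


class TestPrevalenceFilter:
    def _setup(self, pos_rate, neg_rate, n_pos=100, n_neg=100):
        rng = np.random.default_rng(0)
        col = np.r_[
            (np.arange(n_pos) < pos_rate * n_pos).astype(float),
            (np.arange(n_neg) < neg_rate * n_neg).astype(float),
        ]
        matrix = pd.DataFrame({"icd10__Z03": col})
        labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
        return matrix, labels, {"icd10__Z03": "binary"}

    def test_rare_in_one_cohort_dropped(self):
        matrix, labels, schema = self._setup(pos_rate=0.80, neg_rate=0.04)
        assert prevalence_filter(matrix, labels, schema) == []

    def test_exactly_five_percent_in_both_kept(self):
        matrix, labels, schema = self._setup(pos_rate=0.05, neg_rate=0.05)
        assert prevalence_filter(matrix, labels, schema) == ["icd10__Z03"]

    def test_ubiquitous_feature_kept(self):
        matrix, labels, schema = self._setup(pos_rate=1.0, neg_rate=1.0)
        assert prevalence_filter(matrix, labels, schema) == ["icd10__Z03"]

    def test_mandatory_aggregates_exempt(self):
        matrix = pd.DataFrame({"PLT_blood_g_l__p50": np.full(40, np.nan)})
        labels = np.r_[np.ones(20), np.zeros(20)]
        schema = {"PLT_blood_g_l__p50": "aggregate"}
        assert prevalence_filter(matrix, labels, schema) == ["PLT_blood_g_l__p50"]

    def test_optional_parameter_aggregates_dropped_with_presence(self):
        n = 40
        matrix = pd.DataFrame(
            {
                "PDW_blood_fl__measured": np.zeros(n),
                "PDW_blood_fl__p50": np.full(n, np.nan),
            }
        )
        labels = np.r_[np.ones(20), np.zeros(20)]
        schema = {"PDW_blood_fl__measured": "binary", "PDW_blood_fl__p50": "aggregate"}
        assert prevalence_filter(matrix, labels, schema) == []


class TestPhewasMapping:
    def test_exact_hit(self):
        assert map_phewas("D64.8", {"D64.8": "anemias"}) == "anemias"

    def test_root_fallback(self):
        assert map_phewas("I10.2", {"I10": "hypertension"}) == "hypertension"

    def test_unmapped_sentinel(self):
        assert map_phewas("K21", {"D64.8": "anemias"}) is None

    def test_conflicting_duplicates_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            load_phewas_mapping([("D64.8", "anemias"), ("D64.8", "other")])

    def test_consistent_duplicates_allowed(self):
        assert load_phewas_mapping([("D64.8", "anemias"), ("D64.8", "anemias")]) == {
            "D64.8": "anemias"
        }


class TestWoE:
    def test_equal_class_proportions_give_zero(self):
        X = pd.DataFrame({"f": ["a"] * 5 + ["b"] * 5 + ["a"] * 50 + ["b"] * 50})
        y = np.r_[np.ones(10), np.zeros(100)]
        enc = WoEEncoder().fit(X, y)
        assert enc.encoding_["f"]["a"] == pytest.approx(0.0)
        assert enc.encoding_["f"]["b"] == pytest.approx(0.0)

    def test_worked_example_with_smoothing(self):
        # positives: 8 of 10 in category a; negatives: 10 of 100; k=2
        X = pd.DataFrame({"f": ["a"] * 8 + ["b"] * 2 + ["a"] * 10 + ["b"] * 90})
        y = np.r_[np.ones(10), np.zeros(100)]
        enc = WoEEncoder().fit(X, y)
        expected = math.log((8.5 / 11) / (10.5 / 101))
        assert enc.encoding_["f"]["a"] == pytest.approx(expected)
        assert enc.encoding_["f"]["a"] == pytest.approx(2.006, abs=5e-4)

    def test_empty_category_is_finite(self):
        X = pd.DataFrame({"f": ["a"] * 10 + ["b"] * 90 + ["a"] * 100})
        y = np.r_[np.ones(100), np.zeros(100)]
        enc = WoEEncoder().fit(X, y)
        assert math.isfinite(enc.encoding_["f"]["b"])

    def test_single_class_labels_rejected(self):
        X = pd.DataFrame({"f": ["a", "b"]})
        with pytest.raises(ValueError, match="both classes"):
            WoEEncoder().fit(X, np.ones(2))

    def test_missing_is_its_own_category_and_unseen_maps_to_zero(self):
        X = pd.DataFrame({"f": [1.0, np.nan, 1.0, np.nan]})
        y = np.array([1, 1, 0, 0])
        enc = WoEEncoder().fit(X, y)
        out = enc.transform(pd.DataFrame({"f": [2.0]}))
        assert out["f"].iloc[0] == 0.0


class TestBuildFeatureMatrix:
    def test_aggregate_column_count_is_22_times_8(self, small_matrix):
        assert len(small_matrix.aggregate_columns) == 176

    def test_full_schema_has_212_columns(self, small_matrix):
        assert small_matrix.frame.shape[1] == 212

    def test_patients_without_codes_have_zero_indicators(self, small_cohort, small_matrix):
        no_code = [
            p.patient_id for p in small_cohort if not any(e.kind == "icd10" for e in p.events)
        ]
        code_cols = [c for c in small_matrix.frame.columns if c.startswith("icd10__")]
        assert no_code, "fixture should include patients without codes"
        assert (small_matrix.frame.loc[no_code, code_cols] == 0).all().all()

    def test_deterministic(self, small_cohort):
        from pmfscreen.cohort import windows_from_cohort
        from pmfscreen.simulate import patients_frame

        windows = windows_from_cohort(small_cohort)
        demo = patients_frame(small_cohort)[["patient_id", "birth_year", "gender"]]
        a = build_feature_matrix(windows, demographics=demo)
        b = build_feature_matrix(windows, demographics=demo)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_order_statistics_hold_rowwise(self, small_matrix):
        f = small_matrix.frame
        for param in ("PLT_blood_g_l", "HGB_blood_g_dl"):
            sub = f[[f"{param}__{s}" for s in ("min", "p25", "p50", "p75", "max")]].dropna()
            arr = sub.to_numpy()
            assert (np.diff(arr, axis=1) >= -1e-12).all()
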