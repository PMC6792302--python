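"""Preprocessing: parsing, alignment, missingness filtering, imputation,
normalization and feature selection."""

import math

import numpy as np
import pytest

from subtypebench import (
    OmicsLayer,
    ParseError,
    PreprocessConfig,
    ValidationError,
    filter_missing,
    impute,
    intersect_samples,
    normalize,
    read_layer,
    select_features,
)
from oracles import knn_impute_bruteforce


def make_layer(values, name="test", samples=None, features=None):
    values = np.asarray(values, dtype=float)
    f, s = values.shape
    return OmicsLayer(
        name=name,
        feature_ids=features or [f"f{i}" for i in range(f)],
        sample_ids=samples or [f"s{j}" for j in range(s)],
        values=values,
    )


class TestReadLayer:
    def test_empty_cell_becomes_missing(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tA\tB\nf1\t1.0\t2.0\nf2\t\t4.0\nf3\t5.0\t6.0\n")
        layer = read_layer(p, "m")
        assert layer.n_missing() == 1
        assert np.isnan(layer.values[1, 0])

    def test_duplicate_sample_header_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("id\tA\tA\nf1\t1\t2\n")
        with pytest.raises(ParseError, match="duplicated sample"):
            read_layer(p)

    def test_duplicate_feature_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("id\tA\tB\nf1\t1\t2\nf1\t3\t4\n")
        with pytest.raises(ParseError, match="duplicated feature"):
            read_layer(p)


class TestIntersectSamples:
    def test_common_samples_in_sorted_order(self):
        la = make_layer([[1, 2, 3]], samples=["A", "B", "C"])
        lb = make_layer([[4, 5, 6]], samples=["D", "C", "B"])
        out = intersect_samples([la, lb])
        assert out[0].sample_ids == out[1].sample_ids == ["B", "C"]
        np.testing.assert_array_equal(out[0].values, [[2, 3]])
        np.testing.assert_array_equal(out[1].values, [[6, 5]])

    def test_identical_sets_canonical_order(self):
        la = make_layer([[1, 2]], samples=["B", "A"])
        lb = make_layer([[3, 4]], samples=["A", "B"])
        out = intersect_samples([la, lb])
        assert out[0].sample_ids == ["A", "B"]
        np.testing.assert_array_equal(out[0].values, [[2, 1]])

    def test_disjoint_sets_rejected(self):
        la = make_layer([[1]], samples=["A"])
        lb = make_layer([[2]], samples=["B"])
        with pytest.raises(ValidationError, match="empty"):
            intersect_samples([la, lb])


class TestFilterMissing:
    cfg = PreprocessConfig()

    def test_feature_over_threshold_dropped(self):
        X = np.ones((2, 10))
        X[0, :3] = np.nan  # 30% missing > 20%
        out = filter_missing(make_layer(X), self.cfg)
        assert out.feature_ids == ["f1"]

    def test_clean_layer_unchanged(self):
        layer = make_layer(np.arange(12.0).reshape(3, 4))
        out = filter_missing(layer, self.cfg)
        np.testing.assert_array_equal(out.values, layer.values)
        assert out.feature_ids == layer.feature_ids

    def test_two_pass_rule_features_then_samples(self):
        # f0 missing in 3/10 samples (30%) -> dropped first; s0 then
        # missing 2/4 of the remaining features (50%) -> dropped too
        X = np.zeros((5, 10))
        X[0, [0, 1, 2]] = np.nan
        X[1, 0] = np.nan
        X[2, 0] = np.nan
        out = filter_missing(make_layer(X), self.cfg)
        assert out.values.shape == (4, 9)
        assert out.feature_ids == ["f1", "f2", "f3", "f4"]
        assert out.sample_ids == [f"s{j}" for j in range(1, 10)]

    def test_idempotent(self, rng):
        # missingness confined to a few features: the feature pass does
        # all the work and a second application must change nothing
        X = rng.normal(size=(20, 15))
        X[0, :8] = np.nan
        X[1, :2] = np.nan
        X[5, 3] = np.nan
        once = filter_missing(make_layer(X), self.cfg)
        twice = filter_missing(once, self.cfg)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.feature_ids == twice.feature_ids
        assert once.sample_ids == twice.sample_ids

    def test_all_features_dropped_rejected(self):
        X = np.full((2, 4), np.nan)
        with pytest.raises(ValidationError):
            filter_missing(make_layer(X), self.cfg)


class TestImpute:
    def test_mean_of_observed(self):
        layer = make_layer([[1.0, 2.0, np.nan, 3.0], [0, 0, 0, 0]])
        out = impute(layer, PreprocessConfig(impute_method="mean"))
        assert out.values[0, 2] == pytest.approx(2.0)

    def test_median_robust_to_outlier(self):
        layer = make_layer([[1.0, 2.0, np.nan, 100.0], [0, 0, 0, 0]])
        out = impute(layer, PreprocessConfig(impute_method="median"))
        assert out.values[0, 2] == pytest.approx(2.0)

    def test_knn_matches_bruteforce(self, rng):
        X = rng.normal(size=(8, 6))
        X[2, 3] = np.nan
        expected = knn_impute_bruteforce(X, 2, 3, k=2)
        out = impute(make_layer(X), PreprocessConfig(impute_method="knn", knn_k=2))
        assert out.values[2, 3] == pytest.approx(expected)
        # everything else untouched
        mask = ~np.isnan(X)
        np.testing.assert_array_equal(out.values[mask], X[mask])

    def test_knn_many_missing_matches_bruteforce(self, rng):
        X = rng.normal(size=(12, 10))
        X[rng.random(X.shape) < 0.1] = np.nan
        out = impute(make_layer(X), PreprocessConfig(impute_method="knn", knn_k=3))
        assert not np.isnan(out.values).any()
        for f, s in zip(*np.nonzero(np.isnan(X))):
            assert out.values[f, s] == pytest.approx(
                knn_impute_bruteforce(X, f, s, k=3)
            )

    def test_feature_with_no_observations_rejected(self):
        X = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValidationError, match="f0"):
            impute(make_layer(X), PreprocessConfig(impute_method="mean"))


class TestNormalize:
    def test_zscore_example(self):
        out = normalize(
            make_layer([[1.0, 2.0, 3.0]]), PreprocessConfig(normalize_method="zscore")
        )
        np.testing.assert_allclose(
            out.values[0], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_zscore_population_moments(self, rng):
        X = rng.normal(2.0, 3.0, size=(10, 25))
        out = normalize(make_layer(X), PreprocessConfig(normalize_method="zscore"))
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=1), 1.0, atol=1e-9)

    def test_zscore_constant_feature_is_zero(self):
        out = normalize(
            make_layer([[5.0, 5.0, 5.0]]), PreprocessConfig(normalize_method="zscore")
        )
        np.testing.assert_array_equal(out.values, [[0.0, 0.0, 0.0]])

    def test_log1p(self):
        out = normalize(
            make_layer([[0.0, np.e - 1]]), PreprocessConfig(normalize_method="log")
        )
        np.testing.assert_allclose(out.values, [[0.0, 1.0]])

    def test_log_rejects_values_at_or_below_minus_one(self):
        with pytest.raises(ValidationError):
            normalize(
                make_layer([[-1.0, 0.0]]), PreprocessConfig(normalize_method="log")
            )

    def test_minmax_and_constant_rule(self):
        out = normalize(
            make_layer([[2.0, 4.0, 6.0], [3.0, 3.0, 3.0]]),
            PreprocessConfig(normalize_method="minmax"),
        )
        np.testing.assert_allclose(out.values[0], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(out.values[1], [0.5, 0.5, 0.5])

    def test_quantile_ranks(self):
        out = normalize(
            make_layer([[10.0, 30.0, 20.0, 40.0]]),
            PreprocessConfig(normalize_method="quantile"),
        )
        np.testing.assert_allclose(out.values[0], [0.125, 0.625, 0.375, 0.875])


class TestSelectFeatures:
    def test_variance_keeps_top_feature(self, rng):
        X = rng.normal(size=(10, 20))
        X[4] *= 10  # clearly the highest variance
        out = select_features(
            make_layer(X), PreprocessConfig(feature_select_method="variance",
                                            feature_select_fraction=0.10)
        )
        assert out.feature_ids == ["f4"]

    def test_mad_zero_ranks_below_positive(self):
        X = np.array([[1.0, 1.0, 9.0], [1.0, 2.0, 3.0]])  # MADs 0 and 1
        out = select_features(
            make_layer(X), PreprocessConfig(feature_select_method="mad",
                                            feature_select_fraction=0.5)
        )
        assert out.feature_ids == ["f1"]

    def test_fraction_one_is_identity(self, rng):
        X = rng.normal(size=(7, 9))
        out = select_features(
            make_layer(X), PreprocessConfig(feature_select_method="variance",
                                            feature_select_fraction=1.0)
        )
        np.testing.assert_array_equal(out.values, X)

    @pytest.mark.parametrize("fraction", [0.1, 0.25, 0.5, 0.9, 1.0])
    @pytest.mark.parametrize("method", ["variance", "mad"])
    def test_output_size_is_ceil(self, rng, fraction, method):
        X = rng.normal(size=(13, 8))
        out = select_features(
            make_layer(X),
            PreprocessConfig(feature_select_method=method,
                             feature_select_fraction=fraction),
        )
        assert out.n_features == math.ceil(fraction * 13)

    def test_pca_scores_shape_and_ids(self, rng):
        X = rng.normal(size=(20, 12))
        out = select_features(
            make_layer(X), PreprocessConfig(feature_select_method="pca",
                                            feature_select_fraction=0.25)
        )
        assert out.feature_ids == ["PC1", "PC2", "PC3", "PC4", "PC5"]
        assert out.values.shape == (5, 12)
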