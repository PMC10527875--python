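"""Shift quantification: standardization, MMD, classifiers, importance, embeddings."""

import numpy as np
import pandas as pd
import pytest

from dsmri.analysis import (
    KernelSpec,
    domain_classification,
    embed_2d,
    feature_importance,
    mmd_distance,
    pairwise_mmd,
    standardize_features,
)
from dsmri.pipeline import FEATURE_NAMES, FeatureTable
from tests.conftest import make_gaussian_table


def table_with_column(values, name="MEAN"):
    """A minimal table whose named feature column holds the given values."""
    n = len(values)
    df = pd.DataFrame(0.0, index=range(n), columns=list(FEATURE_NAMES))
    df[name] = values
    df.insert(0, "scan_id", [f"s{i}" for i in range(n)])
    df["site"] = ["a"] * (n // 2) + ["b"] * (n - n // 2)
    return FeatureTable(df=df, label_cols=("site",))


class TestStandardize:
    def test_population_zscore_hand_values(self):
        out = standardize_features(table_with_column([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            out.df["MEAN"], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_constant_column_maps_to_zero(self):
        out = standardize_features(table_with_column([4.0, 4.0, 4.0]))
        np.testing.assert_array_equal(out.df["MEAN"], 0.0)

    def test_missing_imputed_by_median_then_zscored(self):
        out = standardize_features(table_with_column([1.0, np.nan, 3.0]))
        # impute 2, then z-score {1,2,3}
        np.testing.assert_allclose(
            out.df["MEAN"], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_all_missing_column_maps_to_zero(self):
        out = standardize_features(table_with_column([np.nan, np.nan, np.nan], "CNR"))
        np.testing.assert_array_equal(out.df["CNR"], 0.0)

    def test_single_scan_rejected(self):
        with pytest.raises(ValueError):
            standardize_features(table_with_column([1.0]))


class TestMmd:
    def test_identical_sets_give_zero(self, rng):
        x = rng.normal(size=(12, 5))
        assert mmd_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_closed_form(self):
        x = np.array([[0.0, 0.0]])
        y = np.array([[3.0, 4.0]])
        h = 5.0  # median pairwise distance of the pooled pair
        expected = 2.0 - 2.0 * np.exp(-(25.0) / (2 * h * h))
        assert mmd_distance(x, y) == pytest.approx(expected, rel=1e-12)

    def test_matches_double_loop_kernel_oracle(self, rng):
        a = rng.normal(size=(7, 4))
        b = rng.normal(size=(9, 4)) + 0.5
        pooled = np.vstack([a, b])
        dists = [
            np.linalg.norm(pooled[i] - pooled[j])
            for i in range(len(pooled))
            for j in range(i + 1, len(pooled))
        ]
        h = np.median(dists)

        def k(x, y):
            return np.exp(-np.sum((x - y) ** 2) / (2 * h * h))

        kaa = np.mean([[k(x, y) for y in a] for x in a])
        kbb = np.mean([[k(x, y) for y in b] for x in b])
        kab = np.mean([[k(x, y) for y in b] for x in a])
        expected = kaa + kbb - 2 * kab
        assert mmd_distance(a, b) == pytest.approx(expected, rel=1e-9)

    def test_symmetry(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(8, 3)) + 1.0
        assert mmd_distance(a, b) == pytest.approx(mmd_distance(b, a), rel=1e-12)

    def test_strictly_increases_with_planted_mean_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(40, 6))
        other = rng.normal(size=(40, 6))
        kernel = KernelSpec(bandwidth=2.0)  # fixed bandwidth isolates the shift effect
        values = [
            mmd_distance(base, other + shift, kernel) for shift in (0.0, 1.0, 2.0, 4.0)
        ]
        assert values[0] < values[1] < values[2] < values[3]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            mmd_distance(np.zeros((3, 2)), np.zeros((3, 4)))

    def test_fixed_bandwidth_kernel_spec(self):
        with pytest.raises(ValueError):
            KernelSpec(bandwidth=-1.0)


class TestPairwiseMmd:
    def test_matrix_structure_and_oracle_agreement(self):
        table = make_gaussian_table(15, n_domains=3, shift=2.0, seed=4)
        matrix = pairwise_mmd(table, "site")
        assert np.allclose(np.diag(matrix), 0.0)
        assert np.allclose(matrix, matrix.T)
        # elementwise recomputation from standardized features
        std = standardize_features(table)
        x = std.feature_matrix()
        y = std.labels("site")
        for a in matrix.index:
            for b in matrix.columns:
                if a == b:
                    continue
                direct = mmd_distance(x[y == a], x[y == b])
                assert matrix.loc[a, b] == pytest.approx(direct, rel=1e-12)


class TestDomainClassification:
    def test_disjoint_supports_classify_almost_perfectly(self):
        table = make_gaussian_table(50, shift=8.0, seed=0)
        for clf in ("svm_linear", "random_forest"):
            assert domain_classification(table, "site", clf, seed=0) >= 0.95

    def test_identical_distributions_stay_near_chance(self):
        accs = [
            domain_classification(
                make_gaussian_table(100, shift=0.0, seed=s), "site", "svm_linear", seed=s
            )
            for s in range(10)
        ]
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_label_permutation_collapses_to_chance(self):
        table = make_gaussian_table(40, shift=8.0, seed=2)
        rng = np.random.default_rng(0)
        df = table.df.copy()
        df["site"] = rng.permutation(df["site"].to_numpy())
        permuted = FeatureTable(df=df, label_cols=("site",))
        acc = domain_classification(permuted, "site", "svm_linear", seed=0)
        assert abs(acc - 0.5) <= 0.15

    def test_single_class_rejected(self):
        table = make_gaussian_table(20, seed=0)
        df = table.df.copy()
        df["site"] = "only"
        with pytest.raises(ValueError, match="2 label classes"):
            domain_classification(FeatureTable(df=df, label_cols=("site",)), "site")

    def test_class_smaller_than_fold_count_is_named(self):
        table = make_gaussian_table(20, seed=0)
        df = table.df.copy()
        df.loc[df.index[:37], "site"] = "big"
        df.loc[df.index[37:], "site"] = "tiny"
        with pytest.raises(ValueError, match="tiny"):
            domain_classification(FeatureTable(df=df, label_cols=("site",)), "site")

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="classifier"):
            domain_classification(make_gaussian_table(10, seed=0), "site", "mlp")


class TestFeatureImportance:
    def test_planted_single_shifted_feature_ranks_first(self):
        table = make_gaussian_table(40, shift=5.0, shifted_features=("HFR",), seed=1)
        ranking = feature_importance(table, "site", seed=1)
        assert ranking[0][0] == "HFR"

    def test_null_design_has_no_dominant_feature(self):
        for s in range(10):
            ranking = feature_importance(
                make_gaussian_table(40, shift=0.0, seed=s), "site", seed=s
            )
            assert ranking[0][1] < 0.15

    def test_ranking_is_permutation_with_unit_mass(self):
        ranking = feature_importance(make_gaussian_table(20, shift=1.0, seed=3), "site")
        names = [f for f, _ in ranking]
        assert sorted(names) == sorted(FEATURE_NAMES)
        assert sum(s for _, s in ranking) == pytest.approx(1.0)
        assert all(b <= a for (_, a), (_, b) in zip(ranking, ranking[1:]))


class TestEmbed2d:
    def test_output_shape_and_determinism(self):
        table = make_gaussian_table(20, shift=3.0, seed=5)
        for method in ("tsne", "umap"):
            first = embed_2d(table, method, seed=11)
            again = embed_2d(table, method, seed=11)
            assert first.shape == (40, 2)
            np.testing.assert_array_equal(first, again)

    def test_separated_domains_have_high_silhouette(self):
        from sklearn.metrics import silhouette_score

        table = make_gaussian_table(30, n_domains=3, shift=6.0, seed=6)
        labels = table.labels("site")
        for method in ("tsne", "umap"):
            coords = embed_2d(table, method, seed=0)
            assert silhouette_score(coords, labels) >= 0.3

    def test_too_few_scans_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            embed_2d(make_gaussian_table(2, seed=0), "tsne")
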