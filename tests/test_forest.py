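import numpy as np
import pandas as pd
import pytest

import phenoforest as pf
from phenoforest.forest import (
    ForestConfig,
    compute_proximity,
    fit_supervised_forest,
    fit_unsupervised_forest,
    grow_tree,
    make_synthetic_contrast,
    oob_evaluate,
    permutation_importance,
)
from .conftest import proximity_oracle, trace_row_through_tree


def _grow(X, y, mtry=None, seed=0, min_node_size=1):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    cfg = ForestConfig(n_trees=1, mtry=mtry, min_node_size=min_node_size, seed=seed)
    kinds = np.zeros(X.shape[1], dtype=np.int64)
    return grow_tree(X, y, kinds, int(y.max()) + 1, cfg,
                     np.random.default_rng(seed))


def _blobs(n_per, centers, sigma, rng, p=2):
    X = np.vstack([rng.normal(c, sigma, size=(n_per, p)) for c in centers])
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y


class TestGrowTree:
    def test_separable_1d_threshold_and_zero_training_error(self):
        X = np.array([[1.0], [2.0], [9.0], [10.0]])
        y = np.array([0, 0, 1, 1])
        tree = _grow(X, y, mtry=1)
        root_thr = tree.threshold[0]
        assert 2.0 < root_thr < 9.0
        assert (tree.predict(X) == y).all()

    def test_pure_labels_single_leaf(self):
        tree = _grow(np.array([[1.0], [2.0], [3.0]]), np.array([1, 1, 1]))
        assert tree.n_nodes == 1
        assert tree.feature[0] == -1

    def test_xor_needs_depth_two_and_fits(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        tree = _grow(X, y, mtry=2)
        assert (tree.predict(X) == y).all()
        # root plus at least one further split level
        assert tree.n_leaves >= 3

    @pytest.mark.parametrize("seed", range(5))
    def test_root_split_matches_exhaustive_gini_enumeration(self, seed):
        """With mtry = p, the chosen root split must equal the best
        (variable, midpoint) candidate by exhaustive Gini search."""
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 6, size=(20, 3)).astype(float)
        y = (X[:, 0] + rng.normal(0, 1.5, 20) > 3).astype(np.int64)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        tree = _grow(X, y, mtry=3, seed=seed)

        def weighted_gini(mask):
            out = 0.0
            for side in (mask, ~mask):
                if side.sum() == 0:
                    return np.inf
                p1 = y[side].mean()
                out += side.sum() * 2 * p1 * (1 - p1)
            return out / len(y)

        best = np.inf
        for j in range(3):
            for u in np.unique(X[:, j])[:-1]:
                uu = np.unique(X[:, j])
                thr = (u + uu[uu > u][0]) / 2
                best = min(best, weighted_gini(X[:, j] <= thr))
        j, thr = tree.feature[0], tree.threshold[0]
        assert weighted_gini(X[:, j] <= thr) == pytest.approx(best, abs=1e-12)

    def test_constant_features_mixed_labels_become_majority_leaf(self):
        X = np.ones((5, 2))
        y = np.array([0, 0, 0, 1, 1])
        tree = _grow(X, y)
        assert tree.n_nodes == 1
        assert tree.leaf_class[0] == 0


class TestSupervisedForest:
    def test_same_seed_identical_oob_predictions(self, rng):
        X, y = _blobs(30, [0.0, 3.0], 1.0, rng)
        cfg = ForestConfig(n_trees=25, seed=9)
        r1 = oob_evaluate(fit_supervised_forest(X, y, cfg), X, y)
        r2 = oob_evaluate(fit_supervised_forest(X, y, cfg), X, y)
        assert r1.error_rate == r2.error_rate
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_well_separated_classes_low_oob_error(self, rng):
        X, y = _blobs(50, [0.0, 10.0], 0.1, rng)
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=100, seed=1))
        assert oob_evaluate(forest, X, y).error_rate < 0.02

    def test_permuted_labels_oob_error_near_half(self, rng):
        X = rng.normal(size=(200, 4))
        y = np.repeat([0, 1], 100)
        rng.shuffle(y)
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=150, seed=2))
        assert 0.4 <= oob_evaluate(forest, X, y).error_rate <= 0.6

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="classes"):
            fit_supervised_forest(X, np.zeros(10, dtype=int),
                                  ForestConfig(n_trees=5, seed=0))


class TestSyntheticContrast:
    def test_values_drawn_from_column_marginals(self, rng):
        X = rng.normal(size=(40, 3))
        X_aug, y = make_synthetic_contrast(X, rng)
        assert X_aug.shape == (80, 3)
        assert (y[:40] == 0).all() and (y[40:] == 1).all()
        for j in range(3):
            assert set(X_aug[40:, j]) <= set(X[:, j])

    def test_constant_column_stays_constant(self, rng):
        X = np.column_stack([np.full(20, 7.0), rng.normal(size=20)])
        X_aug, _ = make_synthetic_contrast(X, rng)
        assert (X_aug[:, 0] == 7.0).all()

    def test_breaks_correlation_between_columns(self, rng):
        z = rng.normal(size=1000)
        X = np.column_stack([z, z])  # perfectly correlated
        X_aug, _ = make_synthetic_contrast(X, rng)
        synth_corr = np.corrcoef(X_aug[1000:, 0], X_aug[1000:, 1])[0, 1]
        assert abs(synth_corr) < 0.1


class TestUnsupervisedForest:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 3))
        cfg = ForestConfig(n_trees=20, seed=4)
        P1 = compute_proximity(fit_unsupervised_forest(X, cfg), X).values
        P2 = compute_proximity(fit_unsupervised_forest(X, cfg), X).values
        assert (P1 == P2).all()

    def test_real_vs_synthetic_separable_on_tight_blobs(self, rng):
        # several dimensions: a synthetic (marginal-resampled) row then
        # rarely recreates a coherent real blob point
        X, _ = _blobs(40, [0.0, 8.0], 0.3, rng, p=5)
        forest = fit_unsupervised_forest(X, ForestConfig(n_trees=100, seed=5))
        y = np.repeat([0, 1], len(X))
        X_aug, _ = make_synthetic_contrast(X, np.random.default_rng(0))
        # OOB error of the real-vs-synthetic task on the forest's own data
        from phenoforest.forest import _substream

        X_aug, y = make_synthetic_contrast(X, _substream(5, 1))
        assert oob_evaluate(forest, X_aug, y).error_rate < 0.20

    def test_proximity_defined_over_original_rows_only(self, rng):
        X = rng.normal(size=(25, 2))
        forest = fit_unsupervised_forest(X, ForestConfig(n_trees=10, seed=6))
        P = compute_proximity(forest, X)
        assert P.n == 25


class TestProximity:
    def test_duplicated_row_has_proximity_one(self, rng):
        X, y = _blobs(10, [0.0, 4.0], 0.5, rng)
        X[3] = X[0]  # exact duplicate follows identical paths
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=30, seed=7))
        P = compute_proximity(forest, X)
        assert P.values[0, 3] == 1.0

    def test_matches_pair_trace_oracle(self, rng):
        X, y = _blobs(15, [0.0, 3.0], 1.0, rng)
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=10, seed=8))
        P = compute_proximity(forest, X)
        assert np.allclose(P.values, proximity_oracle(forest, X), atol=1e-12)

    def test_within_blob_exceeds_between_blob(self, rng):
        X, y = _blobs(20, [0.0, 6.0], 0.5, rng)
        forest = fit_unsupervised_forest(X, ForestConfig(n_trees=80, seed=9))
        P = compute_proximity(forest, X).values
        within = np.concatenate([P[:20, :20].ravel(), P[20:, 20:].ravel()])
        between = P[:20, 20:].ravel()
        assert within.mean() > between.mean()

    def test_round_trip_csv(self, rng, tmp_path):
        X, y = _blobs(5, [0.0, 3.0], 0.5, rng)
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=5, seed=10))
        P = compute_proximity(forest, X, ids=[f"s{i}" for i in range(10)])
        P.to_csv(tmp_path / "prox.csv")
        Q = pf.ProximityMatrix.from_csv(tmp_path / "prox.csv")
        assert np.allclose(P.values, Q.values)


class TestOOBEvaluation:
    def test_single_tree_oob_is_complement_of_inbag(self, rng):
        X, y = _blobs(20, [0.0, 4.0], 0.5, rng)
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=1, seed=11))
        oob_rows = forest.inbag[0] == 0
        result = oob_evaluate(forest, X, y)
        assert result.n_covered == oob_rows.sum()
        assert result.n_never_oob == (~oob_rows).sum()

    def test_confusion_rows_sum_to_covered_class_counts(self, rng):
        X, y = _blobs(25, [0.0, 2.0, 5.0], 0.8, rng)
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=40, seed=12))
        result = oob_evaluate(forest, X, y)
        assert result.confusion.to_numpy().sum() == result.n_covered
        # with 40 trees every row is OOB somewhere with near certainty
        assert result.n_never_oob == 0
        assert (result.confusion.sum(axis=1).to_numpy()
                == np.bincount(y)).all()


class TestPermutationImportance:
    def test_constant_variable_importance_exactly_zero(self, rng):
        X, y = _blobs(25, [0.0, 3.0], 0.5, rng, p=1)
        X = np.column_stack([X, np.full(len(X), 4.2)])
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=30, seed=13))
        rep = permutation_importance(forest, X, y)
        assert rep.table.loc[1, "mean_decrease_accuracy"] == 0.0

    def test_informative_variable_ranks_first_noise_near_zero(self, rng):
        n = 60
        signal = np.concatenate([rng.normal(0, 0.5, n), rng.normal(4, 0.5, n)])
        noise = rng.normal(size=(2 * n, 3))
        X = np.column_stack([noise[:, 0], signal, noise[:, 1:]])
        y = np.repeat([0, 1], n)
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=80, seed=14))
        rep = permutation_importance(forest, X, y)
        assert rep.top(1) == ["x1"]
        for j in (0, 2, 3):
            row = rep.table.iloc[j]
            assert abs(row["mean_decrease_accuracy"]) <= 3 * row["se"] + 1e-9

    def test_null_calibration_with_permuted_labels(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.permutation(np.repeat([0, 1], 30))
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=80, seed=15))
        rep = permutation_importance(forest, X, y)
        for _, row in rep.table.iterrows():
            assert abs(row["mean_decrease_accuracy"]) <= 3 * row["se"] + 1e-9

    def test_deterministic_given_seed(self, rng):
        X, y = _blobs(20, [0.0, 3.0], 1.0, rng)
        forest = fit_supervised_forest(X, y, ForestConfig(n_trees=20, seed=16))
        t1 = permutation_importance(forest, X, y).table
        t2 = permutation_importance(forest, X, y).table
        pd.testing.assert_frame_equal(t1, t2)


class TestCategoricalSplits:
    def test_categorical_three_levels_split_by_subset(self):
        # level 1 belongs with level 0 by label; exhaustive subset search
        X = np.array([[0], [0], [1], [1], [2], [2]], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1])
        cfg = ForestConfig(n_trees=1, mtry=1, seed=0)
        kinds = np.array([3], dtype=np.int64)
        tree = grow_tree(X, y, kinds, 2, cfg, np.random.default_rng(0))
        assert (tree.predict(X) == y).all()
        mask = tree.cat_mask[0]
        left = {l for l in range(3) if (mask >> l) & 1}
        assert left in ({0, 1}, {2})

    def test_mixed_type_cohort_encoding(self, tiny_cohort):
        X, kinds, names = pf.encode_features(tiny_cohort)
        assert X.shape == (4, len(names))
        assert kinds[names.index("gender")] == 2
        assert kinds[names.index("cftr_group")] == 3
        assert kinds[names.index("fev1_pct")] == 0
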