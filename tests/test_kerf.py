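import math

import numpy as np
import pytest

from krfbho.errors import ValidationError
from krfbho.kerf import (
    KerfParams,
    KerfTree,
    KerfForest,
    feature_importances,
    fit_kerf,
    fit_kerf_matrix,
    forest_from_json,
    forest_to_json,
    kerf_predict,
    rank_and_filter,
    rff_transform,
)
from krfbho.preprocessing import CONTINUOUS, FeatureTable

from conftest import make_planted_table


def eq4_reference(forest, query):
    """Literal kernel-forest double sum: average over trees of
    sum_i Q_i * 1[x_i in cell(query)] / |cell(query)|."""
    total = 0.0
    for tree in forest.trees:
        leaf = tree.leaf_for(np.asarray(query, dtype=float))
        rows = tree.leaf_rows.get(leaf, np.empty(0, dtype=int))
        if rows.size:
            total += sum(forest.responses[i] / rows.size for i in rows)
    return total / len(forest.trees)


class TestRffTransform:
    def test_kernel_one_at_zero_distance(self):
        x = np.array([[0.3, -0.7]])
        z = rff_transform(np.vstack([x, x]), rff_dims=256, gamma=1.0, seed=0)
        assert float(z[0] @ z[1]) == pytest.approx(float(z[0] @ z[0]))

    def test_kernel_estimate_near_rbf_value(self):
        # ||x-y||^2 = 1, gamma=1 -> kernel e^-1; Monte-Carlo over seeds
        x = np.array([0.0, 0.0])
        y = np.array([1.0, 0.0])
        ests = []
        for seed in range(30):
            z = rff_transform(np.vstack([x, y]), 4096, gamma=1.0, seed=seed)
            ests.append(float(z[0] @ z[1]))
        se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - math.exp(-1)) < 3 * se + 1e-9

    def test_shape_and_determinism(self, rng):
        X = rng.normal(0, 1, (7, 3))
        a = rff_transform(X, 64, gamma=0.5, seed=42)
        b = rff_transform(X, 64, gamma=0.5, seed=42)
        assert a.shape == (7, 64)
        np.testing.assert_array_equal(a, b)


class TestFit:
    def test_single_stump(self, planted_table):
        forest = fit_kerf(planted_table, KerfParams(n_trees=1, max_depth=1, seed=0))
        assert len(forest.trees) == 1
        assert len(forest.trees[0].leaf_rows) <= 2

    def test_leaves_partition_training_rows(self, planted_table):
        forest = fit_kerf(planted_table, KerfParams(n_trees=5, seed=3))
        n = planted_table.n_samples
        for tree in forest.trees:
            all_rows = np.sort(np.concatenate(list(tree.leaf_rows.values())))
            np.testing.assert_array_equal(all_rows, np.arange(n))

    def test_same_seed_identical_forests(self, planted_table):
        params = KerfParams(n_trees=4, seed=9)
        f1 = fit_kerf(planted_table, params)
        f2 = fit_kerf(planted_table, params)
        assert forest_to_json(f1) == forest_to_json(f2)

    def test_zero_features_rejected(self):
        with pytest.raises(ValidationError):
            fit_kerf_matrix(np.empty((5, 0)), np.zeros(5), KerfParams())

    def test_leaf_budget_respected(self, planted_table):
        forest = fit_kerf(
            planted_table, KerfParams(n_trees=3, leaf_target=4, seed=1)
        )
        for tree in forest.trees:
            assert len(tree.leaf_rows) <= 4


class TestPredict:
    def test_single_leaf_returns_global_mean(self):
        y = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        tree = KerfTree([-1], [math.nan], [-1], [-1], {0: np.arange(5)})
        forest = KerfForest([tree], y, KerfParams(n_trees=1), n_features=2)
        assert kerf_predict(forest, [123.0, -4.0]) == pytest.approx(y.mean())

    def test_identical_trees_average_to_single_tree(self):
        y = np.array([0.0, 1.0, 1.0])
        tree = KerfTree(
            [0, -1, -1], [0.5, math.nan, math.nan], [1, -1, -1], [2, -1, -1],
            {1: np.array([0]), 2: np.array([1, 2])},
        )
        single = KerfForest([tree], y, KerfParams(n_trees=1), 1)
        triple = KerfForest([tree] * 3, y, KerfParams(n_trees=3), 1)
        q = [0.9]
        assert kerf_predict(triple, q) == pytest.approx(kerf_predict(single, q))

    def test_hand_built_two_tree_value(self):
        # responses (0,0,1,1); tree A splits {0,1} | {2,3}; tree B {0} | {1,2,3}
        y = np.array([0.0, 0.0, 1.0, 1.0])
        tree_a = KerfTree(
            [0, -1, -1], [1.5, math.nan, math.nan], [1, -1, -1], [2, -1, -1],
            {1: np.array([0, 1]), 2: np.array([2, 3])},
        )
        tree_b = KerfTree(
            [0, -1, -1], [0.5, math.nan, math.nan], [1, -1, -1], [2, -1, -1],
            {1: np.array([0]), 2: np.array([1, 2, 3])},
        )
        forest = KerfForest([tree_a, tree_b], y, KerfParams(n_trees=2), 1)
        # query x=2: tree A cell {2,3} mean 1; tree B cell {1,2,3} mean 2/3
        expected = 0.5 * (1.0 + 2.0 / 3.0)
        assert kerf_predict(forest, [2.0]) == pytest.approx(expected)
        assert kerf_predict(forest, [2.0]) == pytest.approx(
            eq4_reference(forest, [2.0])
        )

    def test_predictions_within_response_range(self, planted_table):
        forest = fit_kerf(planted_table, KerfParams(n_trees=10, seed=2))
        preds = forest.predict(planted_table.values)
        assert preds.min() >= 0.0 and preds.max() <= 1.0

    def test_dimension_mismatch_rejected(self, planted_table):
        forest = fit_kerf(planted_table, KerfParams(n_trees=1, seed=0))
        with pytest.raises(ValidationError):
            kerf_predict(forest, [0.0])

    def test_matches_reference_on_random_forests(self, rng):
        for trial in range(10):
            n = int(rng.integers(10, 50))
            d = int(rng.integers(1, 5))
            X = rng.normal(0, 1, (n, d))
            y = rng.integers(0, 2, n).astype(float)
            table = FeatureTable(
                [f"f{j}" for j in range(d)], [CONTINUOUS] * d, X, y.astype(int)
            )
            forest = fit_kerf(table, KerfParams(n_trees=3, seed=trial))
            for q in rng.normal(0, 1.5, (5, d)):
                assert kerf_predict(forest, q) == pytest.approx(
                    eq4_reference(forest, q), abs=1e-10
                )

    def test_consistency_on_step_function(self):
        # 1-D threshold response; prediction error should be small
        gen = np.random.default_rng(7)
        x = gen.uniform(0, 1, 2000)
        y = (x > 0.5).astype(int)
        table = FeatureTable(["x"], [CONTINUOUS], x[:, None], y)
        forest = fit_kerf(table, KerfParams(n_trees=50, seed=7))
        grid = np.linspace(0.01, 0.99, 100)
        preds = forest.predict(grid[:, None])
        mae = np.abs(preds - (grid > 0.5)).mean()
        assert mae < 0.15


class TestImportances:
    def test_unused_feature_scores_zero_and_scores_sum_to_one(self, planted_table):
        values = planted_table.values.copy()
        values[:, -1] = 1.0  # constant column can never be split on
        t = FeatureTable(
            planted_table.column_names, planted_table.column_kinds, values,
            planted_table.target,
        )
        forest = fit_kerf(t, KerfParams(n_trees=10, seed=0))
        ranking = feature_importances(forest)
        assert ranking.scores[-1] == 0.0
        assert ranking.scores.sum() == pytest.approx(1.0)

    def test_no_split_forest_identity_ranking(self):
        y = np.array([0.0, 1.0])
        tree = KerfTree([-1], [math.nan], [-1], [-1], {0: np.arange(2)})
        forest = KerfForest([tree], y, KerfParams(n_trees=1), 3)
        ranking = feature_importances(forest)
        np.testing.assert_array_equal(ranking.scores, np.zeros(3))
        np.testing.assert_array_equal(ranking.order, [0, 1, 2])

    def test_informative_feature_ranks_first(self):
        wins = 0
        for seed in range(20):
            gen = np.random.default_rng(seed)
            x = gen.normal(0, 1, (200, 4))
            y = (x[:, 3] > 0).astype(int)
            table = FeatureTable(
                ["a", "b", "c", "d"], [CONTINUOUS] * 4, x, y
            )
            forest = fit_kerf(table, KerfParams(n_trees=30, seed=seed))
            if feature_importances(forest).order[0] == 3:
                wins += 1
        assert wins >= 18

    def test_rank_and_filter_contract(self, planted_table):
        keep_all = rank_and_filter(planted_table, KerfParams(n_trees=10, seed=1),
                                   planted_table.n_features)
        assert sorted(keep_all) == list(range(planted_table.n_features))
        top = rank_and_filter(planted_table, KerfParams(n_trees=30, seed=1), 4)
        assert len(top) == len(set(top)) == 4
        assert all(0 <= j < planted_table.n_features for j in top)

    def test_rank_and_filter_recovers_single_signal(self):
        hits = 0
        for seed in range(20):
            gen = np.random.default_rng(100 + seed)
            x = gen.normal(0, 1, (200, 5))
            y = (x[:, 2] > 0).astype(int)
            table = FeatureTable(
                [f"f{j}" for j in range(5)], [CONTINUOUS] * 5, x, y
            )
            if rank_and_filter(table, KerfParams(n_trees=30, seed=seed), 1) == [2]:
                hits += 1
        assert hits >= 18


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self):
        table = make_planted_table(n=80, seed=5)
        forest = fit_kerf(table, KerfParams(n_trees=4, rff_dims=16, seed=5))
        clone = forest_from_json(forest_to_json(forest))
        queries = table.values[:10]
        np.testing.assert_allclose(
            forest.predict(queries), clone.predict(queries), atol=1e-12
        )
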