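import numpy as np
import pytest

import ivforest as iv
from ivforest.forest import Forest, ForestParams, fit_regression_forest


def make_xy(n=500, p=4, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, (n, p)).astype(float)
    return x, rng


class TestRegressionForest:
    def test_constant_target_predicts_constant(self):
        x, _ = make_xy(100)
        with pytest.warns(UserWarning, match="constant target"):
            f = fit_regression_forest(x, np.full(100, 3.25),
                                      ForestParams(num_trees=10, seed=1))
        assert np.allclose(f.predict(x), 3.25)

    def test_oob_recovers_group_means(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.integers(0, 2, (n, 3)).astype(float)
        t = x[:, 0] + 0.0  # target equals the first binary covariate
        f = fit_regression_forest(x, t, ForestParams(num_trees=100, seed=3))
        pred = f.predict_oob()
        # oracle: group means are exactly 0 and 1
        assert np.abs(pred[x[:, 0] == 1] - 1.0).max() < 0.05
        assert np.abs(pred[x[:, 0] == 0]).max() < 0.05

    def test_single_leaf_predicts_estimation_half_mean(self):
        rng = np.random.default_rng(4)
        n = 60
        x = rng.integers(0, 2, (n, 2)).astype(float)
        t = rng.random(n)
        f = fit_regression_forest(
            x, t, ForestParams(num_trees=1, min_node_size=n, seed=5))
        tree = f.trees[0]
        assert (tree.feature == -1).all()  # no splits
        expected = t[tree.est_idx].mean()
        assert f.predict(x) == pytest.approx(expected, abs=1e-12)

    def test_full_sample_no_honesty_equals_overall_mean(self):
        x, rng = make_xy(50, seed=6)
        t = rng.random(50)
        f = fit_regression_forest(
            x, t,
            ForestParams(num_trees=3, min_node_size=50, sample_fraction=1.0,
                         honesty=False, seed=7))
        assert np.allclose(f.predict(x), t.mean(), atol=1e-12)


class TestOOB:
    def test_sample_fraction_one_errors(self):
        x, rng = make_xy(40, seed=8)
        f = fit_regression_forest(x, rng.random(40),
                                  ForestParams(num_trees=2, sample_fraction=1.0, seed=1))
        with pytest.raises(ValueError, match="out-of-bag"):
            f.predict_oob()

    def test_every_unit_covered_with_many_trees(self):
        x, rng = make_xy(500, seed=9)
        f = fit_regression_forest(x, rng.random(500),
                                  ForestParams(num_trees=200, seed=2))
        # oracle: direct count of subsample membership
        in_bag = f.in_subsample()
        assert (~in_bag).any(axis=0).all()
        assert np.isfinite(f.predict_oob()).all()

    def test_single_tree_in_bag_unit_flagged(self):
        x, rng = make_xy(50, seed=10)
        f = fit_regression_forest(x, rng.random(50),
                                  ForestParams(num_trees=1, seed=3))
        with pytest.warns(UserWarning, match="every subsample"):
            pred = f.predict_oob()
        in_bag = f.in_subsample()[0]
        assert np.isnan(pred[in_bag]).all()
        assert np.isfinite(pred[~in_bag]).all()


class TestWeights:
    def test_weights_sum_to_one(self):
        x, rng = make_xy(200, seed=11)
        f = fit_regression_forest(x, rng.random(200),
                                  ForestParams(num_trees=30, seed=4))
        for row in (0, 7, 100):
            assert f.weights(x[row]).sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_leaf_single_tree_uniform_over_estimation_half(self):
        x, rng = make_xy(60, seed=12)
        f = fit_regression_forest(x, rng.random(60),
                                  ForestParams(num_trees=1, min_node_size=60, seed=5))
        w = f.weights(x[0])
        est = f.trees[0].est_idx
        assert np.allclose(w[est], 1.0 / len(est))
        mask = np.ones(60, bool)
        mask[est] = False
        assert np.allclose(w[mask], 0.0)

    def test_weight_mass_concentrates_on_own_cluster(self):
        rng = np.random.default_rng(13)
        n = 400
        cluster = np.repeat([0, 1], n // 2)
        x = np.column_stack([cluster, rng.integers(0, 2, n)]).astype(float)
        t = cluster + 0.1 * rng.random(n)
        f = fit_regression_forest(x, t, ForestParams(num_trees=50, seed=6))
        w = f.weights(np.array([0.0, 1.0]))
        assert w[cluster == 0].sum() >= 0.9


class TestHonestyAndDeterminism:
    def test_structure_half_targets_do_not_move_leaf_estimates(self):
        x, rng = make_xy(300, seed=14)
        t = rng.random(300)
        f = fit_regression_forest(x, t, ForestParams(num_trees=5, seed=7))
        before = [v.copy() for v in f.leaf_values]
        t2 = t.copy()
        for tree in f.trees:
            t2_struct = np.setdiff1d(tree.struct_idx, tree.est_idx)
            t2[t2_struct] += 100.0  # poison structure-half targets only
        # recompute leaves tree by tree with each tree's own poisoned copy
        for k, tree in enumerate(f.trees):
            t_k = t.copy()
            only_struct = np.setdiff1d(tree.struct_idx, tree.est_idx)
            t_k[only_struct] = -999.0
            single = Forest(trees=[tree], params=f.params,
                            feature_names=f.feature_names, x_train=f.x_train)
            single.refit_leaves(t_k)
            np.testing.assert_array_equal(
                np.nan_to_num(single.leaf_values[0]), np.nan_to_num(before[k]))

    def test_same_seed_identical_different_seed_different(self):
        x, rng = make_xy(300, seed=15)
        t = rng.random(300)
        fa = fit_regression_forest(x, t, ForestParams(num_trees=10, seed=8))
        fb = fit_regression_forest(x, t, ForestParams(num_trees=10, seed=8))
        fc = fit_regression_forest(x, t, ForestParams(num_trees=10, seed=9))
        np.testing.assert_array_equal(fa.predict(x), fb.predict(x))
        assert any(
            not np.array_equal(ta.subsample, tc.subsample)
            for ta, tc in zip(fa.trees, fc.trees)
        )

    def test_serialisation_round_trip_is_bit_stable(self, tmp_path):
        x, rng = make_xy(150, seed=16)
        t = rng.random(150)
        f = fit_regression_forest(x, t, ForestParams(num_trees=8, seed=10))
        path = tmp_path / "forest.json"
        f.save(path)
        g = Forest.load(path)
        np.testing.assert_array_equal(f.predict(x), g.predict(x))
        np.testing.assert_array_equal(f.predict_oob(), g.predict_oob())


def test_split_constraints_respected():
    x, rng = make_xy(400, seed=17)
    t = rng.random(400)
    params = ForestParams(num_trees=10, min_node_size=30, alpha=0.2, seed=11)
    f = fit_regression_forest(x, t, params)
    for tree in f.trees:
        # recompute structure-node sizes by routing the structure half
        leaf_of = tree.route(f.x_train[tree.struct_idx])
        sizes = np.bincount(leaf_of, minlength=tree.n_nodes)
        # aggregate to every node (children appended after parents)
        for k in range(tree.n_nodes - 1, -1, -1):
            if tree.feature[k] >= 0:
                sizes[k] = sizes[tree.left[k]] + sizes[tree.right[k]]
        for k in range(tree.n_nodes):
            if tree.feature[k] >= 0:
                for child in (tree.left[k], tree.right[k]):
                    assert sizes[child] >= params.min_node_size
                    assert sizes[child] >= np.ceil(params.alpha * sizes[k])
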