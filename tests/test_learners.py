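"""Tree-ensemble stack: brute-force split oracles, importance-recovery
simulations, RFE semantics, boosting properties, and a cross-implementation
sanity check against scikit-learn (oracle only)."""

import numpy as np
import pandas as pd
import pytest

import habitatsurv as hs
from habitatsurv.learners import DEFAULT_GRID, LearnerError, log_loss
from _oracles import best_tree_sse


class TestRegressionTree:
    def test_constant_targets_single_leaf(self):
        X = np.arange(8, dtype=float).reshape(-1, 1)
        tree = hs.fit_regression_tree(X, np.full(8, 3.5))
        assert tree.feature[0] == -1  # root is a leaf
        np.testing.assert_allclose(tree.predict(X), 3.5)

    def test_perfect_single_split(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        r = np.array([0.0, 0.0, 1.0, 1.0])
        tree = hs.fit_regression_tree(X, r, max_depth=1)
        assert 2.0 < tree.threshold[0] < 3.0
        np.testing.assert_allclose(tree.predict(X), r)

    @pytest.mark.parametrize("trial", range(20))
    def test_split_matches_bruteforce_oracle(self, trial):
        """Greedy CART equals exhaustive enumeration at depth 1, and never
        beats the exhaustive optimum at depth 2."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 7))
        X = rng.normal(size=(n, int(rng.integers(1, 4))))
        r = rng.normal(size=n)
        t1 = hs.fit_regression_tree(X, r, max_depth=1)
        sse1 = float(((t1.predict(X) - r) ** 2).sum())
        assert sse1 == pytest.approx(best_tree_sse(X, r, 1), abs=1e-9)
        t2 = hs.fit_regression_tree(X, r, max_depth=2)
        sse2 = float(((t2.predict(X) - r) ** 2).sum())
        assert sse2 >= best_tree_sse(X, r, 2) - 1e-9

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        r = rng.normal(size=20)
        tree = hs.fit_regression_tree(X, r, max_depth=6, min_leaf=4)
        leaves, counts = np.unique(
            np.array([_leaf_of(tree, x) for x in X]), return_counts=True)
        assert counts.min() >= 4

    def test_nonfinite_raises(self):
        X = np.array([[1.0], [np.inf]])
        with pytest.raises(LearnerError):
            hs.fit_regression_tree(X, np.array([0.0, 1.0]))


def _leaf_of(tree, x):
    node = 0
    while tree.feature[node] >= 0:
        node = (tree.left[node] if x[tree.feature[node]]
                <= tree.threshold[node] else tree.right[node])
    return node


class TestRandomForest:
    def test_null_importances_flat(self):
        """With labels independent of every feature, no feature dominates."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 10))
        y = np.tile([0, 1], 30)
        forest = hs.fit_random_forest(X, y, n_trees=200, seed=1)
        imp = forest.importances
        assert imp.max() < 3 * imp.mean()

    def test_informative_feature_recovered(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(80, 10))
            y = (X[:, 0] > 0).astype(int)
            forest = hs.fit_random_forest(X, y, n_trees=100, seed=s)
            hits += int(np.argmax(forest.importances) == 0)
        assert hits >= 19

    def test_importances_normalized(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        y = (X[:, 1] + 0.3 * rng.normal(size=40) > 0).astype(int)
        forest = hs.fit_random_forest(X, y, n_trees=50, seed=0)
        assert np.all(forest.importances >= 0)
        assert forest.importances.sum() == pytest.approx(1.0)

    def test_degenerate_forest_is_single_cart(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        y = (X[:, 2] > 0.2).astype(int)
        forest = hs.fit_random_forest(X, y, n_trees=1, mtry=4,
                                      bootstrap=False, seed=5)
        cart = hs.fit_regression_tree(X, y.astype(float), max_depth=10_000)
        np.testing.assert_allclose(forest.trees[0].predict(X),
                                   cart.predict(X))

    def test_single_class_raises(self):
        with pytest.raises(LearnerError):
            hs.fit_random_forest(np.ones((4, 2)), np.zeros(4))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        y = (X[:, 0] > 0).astype(int)
        a = hs.fit_random_forest(X, y, n_trees=25, seed=9)
        b = hs.fit_random_forest(X, y, n_trees=25, seed=9)
        np.testing.assert_allclose(a.importances, b.importances)
        np.testing.assert_allclose(a.predict_proba(X), b.predict_proba(X))


class TestRfRfe:
    def test_identity_selection(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 5)),
                         columns=list("abcde"))
        y = np.tile([0, 1], 10)
        res = hs.rf_rfe(X, y, n_select=5)
        assert res.selected == list("abcde")
        assert res.elimination_trace == []

    def test_informative_pair_recovered(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(2000 + s)
            X = rng.normal(size=(80, 10))
            y = (X[:, 0] + X[:, 1] > 0).astype(int)
            df = pd.DataFrame(X, columns=[f"x{i}" for i in range(10)])
            res = hs.rf_rfe(df, y, n_select=2, n_trees=100, seed=s)
            hits += int(set(res.selected) == {"x0", "x1"})
        assert hits >= 9

    def test_trace_strictly_decreasing_to_target(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 30))
        y = np.tile([0, 1], 15)
        res = hs.rf_rfe(X, y, n_select=5, step_fraction=0.2, n_trees=20,
                        seed=2)
        counts = [n for _, n in res.elimination_trace]
        assert counts[-1] == 5
        assert all(b < a for a, b in zip([30] + counts, counts))
        assert len(res.selected) == 5
        removed = {nm for rem, _ in res.elimination_trace for nm in rem}
        assert removed.isdisjoint(res.selected)

    def test_n_select_too_large(self):
        with pytest.raises(LearnerError):
            hs.rf_rfe(np.ones((4, 3)), np.array([0, 1, 0, 1]), n_select=4)

    def test_selection_json(self, tmp_path):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        y = np.tile([0, 1], 10)
        res = hs.rf_rfe(X, y, n_select=3, n_trees=10, seed=0)
        res.to_json(tmp_path / "sel.json")
        import json
        d = json.loads((tmp_path / "sel.json").read_text())
        assert len(d["selected"]) == 3


class TestGBoost:
    def test_zero_stages_predicts_prevalence(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        model = hs.fit_gboost(X, y, n_estimators=0)
        np.testing.assert_allclose(model.predict_proba(X), 0.3, atol=1e-9)

    def test_separable_training_accuracy(self):
        X = np.linspace(-2, 2, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        model = hs.fit_gboost(X, y, n_estimators=50, learning_rate=0.5,
                              max_depth=1, subsample=1.0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_training_loss_monotone_at_full_subsample(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        model = hs.fit_gboost(X, y, n_estimators=60, subsample=1.0)
        losses = np.asarray(model.train_loss)
        assert np.all(np.diff(losses) <= 1e-12)
        # independent recomputation from truncated ensembles
        for m in (1, 10, 30, 60):
            p = 1 / (1 + np.exp(-model.decision(X, n_trees=m)))
            assert log_loss(y.astype(float), p) == \
                pytest.approx(losses[m - 1], abs=1e-12)

    def test_probability_monotone_in_score(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        model = hs.fit_gboost(X, y, n_estimators=20)
        score = model.decision(X)
        prob = model.predict_proba(X)
        assert np.array_equal(np.argsort(score), np.argsort(prob))

    def test_shrinkage_stability(self):
        """As the learning rate shrinks with lr*M constant, training
        predictions stabilize."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 4))
        y = (X[:, 0] + X[:, 1] + 0.5 * rng.normal(size=50) > 0).astype(int)
        a = hs.fit_gboost(X, y, n_estimators=100, learning_rate=0.1,
                          max_depth=2).predict_proba(X)
        b = hs.fit_gboost(X, y, n_estimators=200, learning_rate=0.05,
                          max_depth=2).predict_proba(X)
        assert np.max(np.abs(a - b)) < 0.1

    def test_invalid_inputs(self):
        X = np.ones((4, 2))
        y01 = np.array([0, 1, 0, 1])
        with pytest.raises(LearnerError):
            hs.fit_gboost(X, np.zeros(4))
        with pytest.raises(LearnerError):
            hs.fit_gboost(X, y01, learning_rate=1.5)
        with pytest.raises(LearnerError):
            hs.fit_gboost(X, y01, subsample=0.0)

    def test_feature_layout_guard(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)),
                         columns=["a", "b"])
        y = np.tile([0, 1], 5)
        model = hs.fit_gboost(X, y, n_estimators=5)
        with pytest.raises(LearnerError):
            model.predict_proba(X.rename(columns={"b": "c"}))

    def test_serialization_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        y = (X[:, 0] > 0).astype(int)
        model = hs.fit_gboost(X, y, n_estimators=15, seed=4)
        model.save(tmp_path / "model.json")
        loaded = hs.BoostModel.load(tmp_path / "model.json")
        np.testing.assert_allclose(loaded.predict_proba(X),
                                   model.predict_proba(X))

    def test_determinism_with_subsample(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(int)
        a = hs.fit_gboost(X, y, n_estimators=30, subsample=0.7, seed=2)
        b = hs.fit_gboost(X, y, n_estimators=30, subsample=0.7, seed=2)
        np.testing.assert_allclose(a.predict_proba(X), b.predict_proba(X))


class TestTune:
    def test_single_point_grid(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.tile([0, 1], 10)
        cfg = {"learning_rate": 0.2, "max_depth": 2, "n_estimators": 10,
               "subsample": 1.0}
        assert hs.tune_hyperparameters(X, y, [cfg]) == cfg

    def test_tiebreak_prefers_smallest(self):
        X = np.linspace(-3, 3, 24).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        grid = [{"learning_rate": lr, "max_depth": d, "n_estimators": m,
                 "subsample": 1.0}
                for lr in (0.05, 0.1) for d in (1, 2) for m in (50, 100)]
        best = hs.tune_hyperparameters(X, y, grid, seed=1)
        assert best["n_estimators"] == 50
        assert best["max_depth"] == 1
        assert best["learning_rate"] == 0.05

    def test_selected_at_least_as_good_as_worst(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] + rng.normal(size=40) > 0).astype(int)
        grid = [{"learning_rate": 0.1, "max_depth": 1, "n_estimators": 5,
                 "subsample": 1.0},
                {"learning_rate": 0.1, "max_depth": 2, "n_estimators": 50,
                 "subsample": 1.0}]

        def cv_acc(cfg, seed=77):
            from habitatsurv.learners import _stratified_folds
            rng2 = np.random.default_rng(seed)
            folds = _stratified_folds(y, 5, rng2)
            accs = []
            for te in folds:
                tr = np.setdiff1d(np.arange(len(y)), te)
                m = hs.fit_gboost(X[tr], y[tr], **cfg, seed=0)
                accs.append(np.mean(m.predict(X[te]) == y[te]))
            return np.mean(accs)

        best = hs.tune_hyperparameters(X, y, grid, seed=3)
        worst_acc = min(cv_acc(g) for g in grid)
        assert cv_acc(best) >= worst_acc - 1e-9

    def test_empty_grid_raises(self):
        with pytest.raises(LearnerError):
            hs.tune_hyperparameters(np.ones((4, 2)),
                                    np.array([0, 1, 0, 1]), [])

    def test_default_grid_shape(self):
        assert len(DEFAULT_GRID) == 3 * 3 * 3 * 2


class TestSklearnCrossCheck:
    """scikit-learn as an independent reference implementation: test
    accuracies of the from-scratch ensembles must land within 0.1."""

    @pytest.fixture(scope="class")
    def data(self):
        rng = np.random.default_rng(2024)
        X = rng.normal(size=(160, 10))
        logit = X[:, 0] + 0.8 * X[:, 1] - 0.6 * X[:, 2]
        y = (logit + rng.logistic(size=160) * 0.5 > 0).astype(int)
        return (X[:110], y[:110], X[110:], y[110:])

    def test_forest_accuracy(self, data):
        from sklearn.ensemble import RandomForestClassifier
        Xtr, ytr, Xte, yte = data
        mine = hs.fit_random_forest(Xtr, ytr, n_trees=200, seed=0)
        acc_mine = np.mean(mine.predict(Xte) == yte)
        ref = RandomForestClassifier(n_estimators=200, random_state=0)
        ref.fit(Xtr, ytr)
        acc_ref = ref.score(Xte, yte)
        assert abs(acc_mine - acc_ref) <= 0.1

    def test_gboost_accuracy(self, data):
        from sklearn.ensemble import GradientBoostingClassifier
        Xtr, ytr, Xte, yte = data
        mine = hs.fit_gboost(Xtr, ytr, n_estimators=100, learning_rate=0.1,
                             max_depth=2)
        acc_mine = np.mean(mine.predict(Xte) == yte)
        ref = GradientBoostingClassifier(n_estimators=100,
                                         learning_rate=0.1, max_depth=2,
                                         random_state=0)
        ref.fit(Xtr, ytr)
        acc_ref = ref.score(Xte, yte)
        assert abs(acc_mine - acc_ref) <= 0.1
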