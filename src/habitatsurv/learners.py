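"""From-scratch tree-ensemble stack: CART regression trees, random forests
with impurity importances, random-forest recursive feature elimination
(RF-RFE), and gradient boosting of depth-limited regression trees on the
logistic loss.

The boosting classifier is the classical stage-wise additive model: starting
from the prevalence log-odds f0, each stage fits a small regression tree to
the current residuals y - sigmoid(F) on a seeded subsample and replaces every
leaf value with the one-step Newton estimate sum(r) / sum(p(1-p)) over the
leaf, then updates F by learning_rate * tree.  The random forest votes over
bootstrap trees grown with sqrt(p) random candidate features per node; its
normalized total impurity decrease per feature drives the recursive
elimination loop, which drops the weakest ceil(step_fraction * remaining)
features per iteration until exactly ``n_select`` remain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _kernels

_BIG_DEPTH = 10_000      # effectively unlimited tree depth
_NEWTON_FLOOR = 1e-12    # guard for the Newton-step denominator
_LEAF_CLIP = 10.0        # |leaf value| cap for numerical safety


class LearnerError(RuntimeError):
    pass


def _as_matrix(X) -> Tuple[np.ndarray, Optional[List[str]]]:
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=np.float64)), \
            list(X.columns)
    return np.ascontiguousarray(np.asarray(X, dtype=np.float64)), None


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0, 1))):
        raise LearnerError("labels must be coded 0/1")
    if len(classes) < 2:
        raise LearnerError("both classes must be present")
    return y.astype(np.float64)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class RegressionTree:
    """A fitted CART regression tree (parallel node arrays)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    max_depth: int
    min_leaf: int
    n_features: int

    def predict(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        if M.shape[1] != self.n_features:
            raise LearnerError("feature count differs from training")
        return _kernels.predict_tree(M, self.feature, self.threshold,
                                     self.left, self.right, self.value)

    def to_dict(self) -> Dict[str, object]:
        return {"feature": self.feature.tolist(),
                "threshold": self.threshold.tolist(),
                "left": self.left.tolist(), "right": self.right.tolist(),
                "value": self.value.tolist(), "max_depth": self.max_depth,
                "min_leaf": self.min_leaf, "n_features": self.n_features}

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "RegressionTree":
        return cls(feature=np.asarray(d["feature"], np.int64),
                   threshold=np.asarray(d["threshold"], np.float64),
                   left=np.asarray(d["left"], np.int64),
                   right=np.asarray(d["right"], np.int64),
                   value=np.asarray(d["value"], np.float64),
                   max_depth=int(d["max_depth"]),
                   min_leaf=int(d["min_leaf"]),
                   n_features=int(d["n_features"]))


def fit_regression_tree(X, r, max_depth: int = 3, min_leaf: int = 1,
                        ) -> RegressionTree:
    """Greedy variance-reduction CART fit.

    Deterministic: all features are candidates at every node and split ties
    go to the lowest feature index; thresholds are midpoints of adjacent
    sorted values.
    """
    M, _ = _as_matrix(X)
    r = np.asarray(r, dtype=np.float64)
    if M.shape[0] < 2:
        raise LearnerError("need at least 2 samples")
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(r))):
        raise LearnerError("non-finite values in the training data")
    f, t, l, rt, v, _, _ = _kernels.grow_tree(
        M, r, max_depth, min_leaf, M.shape[1], 0, False)
    return RegressionTree(f, t, l, rt, v, max_depth, min_leaf, M.shape[1])


@dataclass
class ForestModel:
    """Bagged classification trees with normalized impurity importances."""

    trees: List[RegressionTree]
    importances: np.ndarray
    oob_indices: List[np.ndarray]
    feature_names: Optional[List[str]]
    params: Dict[str, object] = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        votes = np.zeros(_as_matrix(X)[0].shape[0])
        for tree in self.trees:
            votes += (tree.predict(X) >= 0.5).astype(np.float64)
        return votes / len(self.trees)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int64)


def fit_random_forest(X, y, n_trees: int = 200, mtry: Optional[int] = None,
                      min_leaf: int = 1, seed: int = 0,
                      bootstrap: bool = True) -> ForestModel:
    """Random forest on binary labels.

    Per tree: bootstrap resample of n, Gini splits over ``mtry`` (default
    floor(sqrt(p))) random candidate features per node, grown until pure or
    ``min_leaf``.  Importances are the per-feature total impurity decrease
    summed over trees and normalized to 1.
    """
    M, names = _as_matrix(X)
    yb = _check_binary(y)
    n, p = M.shape
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))
    mtry = min(mtry, p)
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    trees: List[RegressionTree] = []
    oob: List[np.ndarray] = []
    imp_total = np.zeros(p)
    for _ in range(n_trees):
        if bootstrap:
            boot = rng.integers(0, n, size=n)
        else:
            boot = all_idx
        tree_seed = int(rng.integers(0, 2 ** 31 - 1))
        Xb = np.ascontiguousarray(M[boot])
        f, t, l, r, v, imp, _ = _kernels.grow_tree(
            Xb, yb[boot], _BIG_DEPTH, min_leaf, mtry, tree_seed,
            mtry < p)
        trees.append(RegressionTree(f, t, l, r, v, _BIG_DEPTH, min_leaf, p))
        imp_total += imp
        oob.append(np.setdiff1d(all_idx, boot))
    total = imp_total.sum()
    importances = imp_total / total if total > 0 else imp_total
    return ForestModel(trees=trees, importances=importances,
                       oob_indices=oob, feature_names=names,
                       params={"n_trees": n_trees, "mtry": mtry,
                               "min_leaf": min_leaf, "seed": seed,
                               "bootstrap": bootstrap})


@dataclass
class SelectionResult:
    """Outcome of recursive feature elimination."""

    selected: List[str]
    elimination_trace: List[Tuple[List[str], int]]
    seed: int

    def to_json(self, path) -> None:
        payload = {"selected": self.selected, "seed": self.seed,
                   "elimination_trace": [
                       {"removed": rem, "remaining": n}
                       for rem, n in self.elimination_trace]}
        Path(path).write_text(json.dumps(payload, indent=2))


def rf_rfe(X, y, n_select: int = 60, step_fraction: float = 0.1,
           n_trees: int = 200, mtry: Optional[int] = None,
           min_leaf: int = 1, seed: int = 0) -> SelectionResult:
    """Random-forest recursive feature elimination down to ``n_select``.

    Each iteration refits the forest on the surviving features and drops the
    ceil(step_fraction * remaining) lowest-importance ones (at least 1, never
    overshooting below the target).  Importance ties are broken by feature
    name, earlier names dropped first.
    """
    M, names = _as_matrix(X)
    if names is None:
        names = [f"f{i:04d}" for i in range(M.shape[1])]
    if n_select > M.shape[1]:
        raise LearnerError(
            f"n_select={n_select} exceeds the {M.shape[1]} features")
    if not 0 < step_fraction <= 1:
        raise LearnerError("step_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    remaining = list(names)
    col_of = {nm: j for j, nm in enumerate(names)}
    trace: List[Tuple[List[str], int]] = []
    while len(remaining) > n_select:
        cols = [col_of[nm] for nm in remaining]
        forest = fit_random_forest(
            np.ascontiguousarray(M[:, cols]), y, n_trees=n_trees, mtry=mtry,
            min_leaf=min_leaf, seed=int(rng.integers(0, 2 ** 31 - 1)))
        imp = forest.importances
        k = int(np.ceil(step_fraction * len(remaining)))
        k = max(1, min(k, len(remaining) - n_select))
        order = sorted(range(len(remaining)),
                       key=lambda j: (imp[j], remaining[j]))
        dropped = sorted(remaining[j] for j in order[:k])
        drop_set = set(dropped)
        remaining = [nm for nm in remaining if nm not in drop_set]
        trace.append((dropped, len(remaining)))
    return SelectionResult(selected=remaining, elimination_trace=trace,
                           seed=seed)


@dataclass
class BoostModel:
    """Additive logistic model: sigmoid(f0 + lr * sum of tree outputs)."""

    f0: float
    trees: List[RegressionTree]
    learning_rate: float
    subsample: float
    n_estimators: int
    max_depth: int
    feature_names: Optional[List[str]]
    train_loss: List[float] = field(default_factory=list)

    def decision(self, X, n_trees: Optional[int] = None) -> np.ndarray:
        M, names = _as_matrix(X)
        if self.feature_names is not None:
            if names is not None and names != self.feature_names:
                raise LearnerError("feature layout differs from training")
            if M.shape[1] != len(self.feature_names):
                raise LearnerError("feature count differs from training")
        use = self.trees if n_trees is None else self.trees[:n_trees]
        score = np.full(M.shape[0], self.f0)
        for tree in use:
            score += self.learning_rate * tree.predict(M)
        return score

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.decision(X))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int64)

    def save(self, path) -> None:
        payload = {"f0": self.f0, "learning_rate": self.learning_rate,
                   "subsample": self.subsample,
                   "n_estimators": self.n_estimators,
                   "max_depth": self.max_depth,
                   "feature_names": self.feature_names,
                   "train_loss": self.train_loss,
                   "trees": [t.to_dict() for t in self.trees]}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "BoostModel":
        d = json.loads(Path(path).read_text())
        return cls(f0=d["f0"],
                   trees=[RegressionTree.from_dict(t) for t in d["trees"]],
                   learning_rate=d["learning_rate"],
                   subsample=d["subsample"],
                   n_estimators=d["n_estimators"],
                   max_depth=d["max_depth"],
                   feature_names=d["feature_names"],
                   train_loss=d["train_loss"])


def log_loss(y: np.ndarray, prob: np.ndarray) -> float:
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_gboost(X, y, n_estimators: int = 100, learning_rate: float = 0.1,
               max_depth: int = 2, subsample: float = 1.0,
               min_leaf: int = 1, seed: int = 0) -> BoostModel:
    """Gradient boosting on the logistic loss with Newton leaf updates."""
    M, names = _as_matrix(X)
    yb = _check_binary(y)
    if not 0 < learning_rate <= 1:
        raise LearnerError("learning_rate must be in (0, 1]")
    if not 0 < subsample <= 1:
        raise LearnerError("subsample must be in (0, 1]")
    n = M.shape[0]
    rng = np.random.default_rng(seed)
    prevalence = float(np.clip(yb.mean(), 1e-6, 1 - 1e-6))
    f0 = float(np.log(prevalence / (1 - prevalence)))
    F = np.full(n, f0)
    trees: List[RegressionTree] = []
    loss_hist: List[float] = []
    n_sub = max(2, int(round(subsample * n)))
    for _ in range(n_estimators):
        if subsample < 1.0:
            sub = np.sort(rng.choice(n, size=n_sub, replace=False))
        else:
            sub = np.arange(n)
        p_sub = _sigmoid(F[sub])
        resid = yb[sub] - p_sub
        Xs = np.ascontiguousarray(M[sub])
        f, t, l, r, v, _, leaf_of = _kernels.grow_tree(
            Xs, resid, max_depth, min_leaf, M.shape[1], 0, False)
        # Newton step per leaf: sum(residual) / sum(p(1-p)), guarded + capped
        hess = p_sub * (1 - p_sub)
        for leaf in np.unique(leaf_of):
            members = leaf_of == leaf
            denom = max(hess[members].sum(), _NEWTON_FLOOR)
            gamma = resid[members].sum() / denom
            v[leaf] = float(np.clip(gamma, -_LEAF_CLIP, _LEAF_CLIP))
        tree = RegressionTree(f, t, l, r, v, max_depth, min_leaf, M.shape[1])
        F = F + learning_rate * tree.predict(M)
        trees.append(tree)
        loss_hist.append(log_loss(yb, _sigmoid(F)))
    return BoostModel(f0=f0, trees=trees, learning_rate=learning_rate,
                      subsample=subsample, n_estimators=n_estimators,
                      max_depth=max_depth, feature_names=names,
                      train_loss=loss_hist)


def predict_proba(model: BoostModel, X) -> np.ndarray:
    """Per-sample probability of the positive class, in (0, 1)."""
    return model.predict_proba(X)


DEFAULT_GRID: List[Dict[str, float]] = [
    {"learning_rate": lr, "max_depth": d, "n_estimators": m, "subsample": s}
    for lr in (0.05, 0.1, 0.3) for d in (1, 2, 3) for m in (50, 100, 200)
    for s in (0.8, 1.0)
]


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> List[np.ndarray]:
    folds: List[List[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        for i, m in enumerate(members):
            folds[i % k].append(int(m))
    return [np.asarray(sorted(f), dtype=np.int64) for f in folds if f]


def tune_hyperparameters(X, y, grid: Optional[Sequence[Dict]] = None,
                         inner_folds: int = 5, seed: int = 0,
                         ) -> Dict[str, float]:
    """Pick boosting hyperparameters by stratified inner cross-validation.

    Best mean accuracy wins; ties prefer the smaller
    (n_estimators, max_depth, learning_rate, subsample).
    """
    grid = list(DEFAULT_GRID if grid is None else grid)
    if not grid:
        raise LearnerError("hyperparameter grid is empty")
    M, names = _as_matrix(X)
    yb = _check_binary(y).astype(np.int64)
    rng = np.random.default_rng(seed)
    k = min(inner_folds, int((yb == 0).sum()), int((yb == 1).sum()))
    k = max(2, k)
    folds = _stratified_folds(yb, k, rng)
    results = []
    for cfg in grid:
        accs = []
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(len(yb)), test_idx)
            if len(np.unique(yb[train_idx])) < 2:
                continue
            model = fit_gboost(M[train_idx], yb[train_idx],
                               seed=int(rng.integers(0, 2 ** 31 - 1)),
                               **cfg)
            pred = model.predict(M[test_idx])
            accs.append(float(np.mean(pred == yb[test_idx])))
        mean_acc = float(np.mean(accs)) if accs else 0.0
        results.append((mean_acc, cfg))
    best = max(
        results,
        key=lambda t: (t[0], -t[1]["n_estimators"], -t[1]["max_depth"],
                       -t[1]["learning_rate"], -t[1].get("subsample", 1.0)))
    return dict(best[1])
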