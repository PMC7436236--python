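"""Bagged regression-tree ensemble for sample-wise vGRF regression.

The estimator is a random forest in the classic bagging form: each of the
(default 50) trees is grown on a bootstrap resample of the training rows,
splits greedily maximize variance reduction over a random subset of
ceil(p/3) candidate features per node, growth stops when a node holds fewer
than twice the minimum leaf size (default 5) or has zero target variance,
and the ensemble prediction is the arithmetic mean of the tree outputs.

Two engines share this contract:

* ``engine="sklearn"`` (default) fits :class:`sklearn.ensemble.
  RandomForestRegressor` with the equivalent hyperparameters and exports its
  trees into the package's own flat arrays;
* ``engine="bespoke"`` is a self-contained NumPy implementation kept as the
  reference for the exact stopping and split rules above.

Either way the result is a :class:`ForestModel` holding plain arrays, so
prediction and JSON (de)serialization are engine-independent and the model
round-trips through its serialized form exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = ["Tree", "ForestModel", "fit_forest", "predict",
           "model_to_json", "model_from_json", "save_model", "load_model"]


@dataclass
class Tree:
    """Flat binary regression tree; leaves have feature == -1."""

    feature: np.ndarray       # (n_nodes,) int, split feature or -1 at leaves
    threshold: np.ndarray     # (n_nodes,) float, x[f] <= thr goes left
    left: np.ndarray          # (n_nodes,) int child ids, -1 at leaves
    right: np.ndarray
    value: np.ndarray         # (n_nodes,) float, node mean target

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(X.shape[0], dtype=np.int64)
        feat = self.feature[idx]
        active = feat >= 0
        while np.any(active):
            rows = np.nonzero(active)[0]
            f = self.feature[idx[rows]]
            go_left = X[rows, f] <= self.threshold[idx[rows]]
            nxt = np.where(go_left, self.left[idx[rows]], self.right[idx[rows]])
            idx[rows] = nxt
            active[rows] = self.feature[nxt] >= 0
        return self.value[idx]

    def n_leaves(self) -> int:
        return int(np.sum(self.feature < 0))


@dataclass
class ForestModel:
    n_trees: int
    min_leaf: int
    rng_seed: int
    feature_names: List[str]
    trees: List[Tree]
    engine: str = "sklearn"
    # bootstrap row indices per tree; kept in memory for out-of-bag scoring,
    # not serialized
    bootstrap_indices: List[np.ndarray] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def _mtry(n_features: int) -> int:
    return max(1, math.ceil(n_features / 3))


def _build_tree(X: np.ndarray, y: np.ndarray, rows: np.ndarray,
                min_leaf: int, mtry: int, rng: np.random.Generator) -> Tree:
    feature, threshold, left, right, value = [], [], [], [], []

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        return len(feature) - 1

    stack = [(new_node(), rows)]
    while stack:
        node, idx = stack.pop()
        yn = y[idx]
        value[node] = float(yn.mean())
        n = idx.size
        if n < 2 * min_leaf or np.all(yn == yn[0]):
            continue
        feats = rng.choice(X.shape[1], size=min(mtry, X.shape[1]), replace=False)
        Xs = X[np.ix_(idx, feats)]                       # (n, mtry)
        order = np.argsort(Xs, axis=0, kind="stable")
        xs = np.take_along_axis(Xs, order, axis=0)
        ys = yn[order]                                   # (n, mtry)
        csum = np.cumsum(ys, axis=0)
        csum2 = np.cumsum(ys ** 2, axis=0)
        total, total2 = csum[-1], csum2[-1]
        k = np.arange(1, n)[:, None].astype(float)       # left sizes
        left_sse = csum2[:-1] - csum[:-1] ** 2 / k
        right_sse = (total2 - csum2[:-1]) - (total - csum[:-1]) ** 2 / (n - k)
        score = left_sse + right_sse                     # minimize child SSE
        # a split is valid only between distinct x values and with both
        # children >= min_leaf
        valid = xs[1:] > xs[:-1]
        valid[: min_leaf - 1] = False
        valid[n - min_leaf:] = False
        score = np.where(valid, score, np.inf)
        flat = np.argmin(score)
        if not np.isfinite(score.flat[flat]):
            continue
        ki, fj = np.unravel_index(flat, score.shape)
        thr = 0.5 * (xs[ki, fj] + xs[ki + 1, fj])
        f_global = int(feats[fj])
        go_left = X[idx, f_global] <= thr
        li, ri = new_node(), new_node()
        feature[node] = f_global
        threshold[node] = float(thr)
        left[node], right[node] = li, ri
        stack.append((li, idx[go_left]))
        stack.append((ri, idx[~go_left]))

    return Tree(feature=np.asarray(feature, dtype=np.int64),
                threshold=np.asarray(threshold, dtype=float),
                left=np.asarray(left, dtype=np.int64),
                right=np.asarray(right, dtype=np.int64),
                value=np.asarray(value, dtype=float))


def _from_sklearn(est: RandomForestRegressor) -> List[Tree]:
    trees = []
    for dt in est.estimators_:
        t = dt.tree_
        trees.append(Tree(
            feature=np.where(t.children_left < 0, -1, t.feature).astype(np.int64),
            threshold=t.threshold.astype(float),
            left=t.children_left.astype(np.int64),
            right=t.children_right.astype(np.int64),
            value=t.value[:, 0, 0].astype(float),
        ))
    return trees


def fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int = 50,
               min_leaf: int = 5, seed: int = 0,
               feature_names: Sequence[str] | None = None,
               engine: str = "sklearn", bootstrap: bool = True) -> ForestModel:
    """Fit the ensemble; deterministic given (data, seed, engine)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty or malformed training matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite training targets")
    if n_trees < 1 or min_leaf < 1:
        raise ValueError("n_trees and min_leaf must be >= 1")
    names = list(feature_names) if feature_names is not None \
        else [f"f{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")

    boot_idx: List[np.ndarray] | None = None
    if engine == "sklearn":
        est = RandomForestRegressor(
            n_estimators=n_trees,
            min_samples_leaf=min_leaf,
            max_features=_mtry(X.shape[1]),
            bootstrap=bootstrap,
            random_state=seed,
            n_jobs=1,
        )
        est.fit(X, y)
        trees = _from_sklearn(est)
    elif engine == "bespoke":
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        trees, boot_idx = [], []
        for _ in range(n_trees):
            rows = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
            boot_idx.append(rows)
            trees.append(_build_tree(X, y, rows, min_leaf,
                                     _mtry(X.shape[1]), rng))
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return ForestModel(n_trees=n_trees, min_leaf=min_leaf, rng_seed=seed,
                       feature_names=names, trees=trees, engine=engine,
                       bootstrap_indices=boot_idx)


def predict(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Mean over tree outputs, row-aligned with ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError("prediction matrix columns do not match the model")
    out = np.zeros(X.shape[0])
    for tree in model.trees:
        out += tree.predict(X)
    return out / len(model.trees)


def model_to_json(model: ForestModel) -> str:
    doc = {
        "format": "gaitforce-forest-v1",
        "n_trees": model.n_trees,
        "min_leaf": model.min_leaf,
        "rng_seed": model.rng_seed,
        "engine": model.engine,
        "feature_names": model.feature_names,
        "trees": [
            {
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "value": t.value.tolist(),
            }
            for t in model.trees
        ],
    }
    return json.dumps(doc)


def model_from_json(text: str) -> ForestModel:
    doc = json.loads(text)
    if doc.get("format") != "gaitforce-forest-v1":
        raise ValueError("not a serialized forest model")
    trees = [Tree(feature=np.asarray(d["feature"], dtype=np.int64),
                  threshold=np.asarray(d["threshold"], dtype=float),
                  left=np.asarray(d["left"], dtype=np.int64),
                  right=np.asarray(d["right"], dtype=np.int64),
                  value=np.asarray(d["value"], dtype=float))
             for d in doc["trees"]]
    return ForestModel(n_trees=doc["n_trees"], min_leaf=doc["min_leaf"],
                       rng_seed=doc["rng_seed"],
                       feature_names=list(doc["feature_names"]),
                       trees=trees, engine=doc.get("engine", "sklearn"))


def save_model(model: ForestModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> ForestModel:
    with open(path) as fh:
        return model_from_json(fh.read())
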