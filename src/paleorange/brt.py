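"""Boosted regression trees for presence/absence data, written from scratch.

Stagewise gradient boosting on the Bernoulli (logistic) deviance.  The model
is an additive ensemble on the log-odds scale,

    F(x) = F0 + nu * sum_m T_m(x),        p(x) = 1 / (1 + exp(-F(x))),

where F0 is the logit of the observed prevalence, nu is the learning rate and
each T_m is a small regression tree fitted to the negative gradient (the
residual y - p) on a random bag of training rows.  Tree complexity ``tc`` is
the number of internal splits per tree, grown best-first; ``tc=1`` gives
single-split stumps, the setting used throughout the reference analysis
(learning rate 0.1, bag fraction 0.5).

Leaf values are one Newton step on the deviance, sum(residual) / sum(p(1-p))
over the bag rows in the leaf, clipped to +/-4 log-odds so that pure leaves
cannot diverge.  The number of trees is chosen by the holdout rule: the data
are split 80/20 (stratified by label), boosting runs to ``max_trees``, and
the model is truncated at the stage with minimum holdout deviance.

Split candidates are midpoints between consecutive sorted unique in-bag
values of each variable; ties in gain are broken toward the lowest variable
index, then the lowest threshold, making the fit bit-reproducible under a
seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import ClimateStack, covariate_columns

__all__ = [
    "TreeNode",
    "BoostedModel",
    "FitReport",
    "fit_brt",
    "predict_suitability",
    "auc",
    "variable_importance",
    "partial_dependence",
    "pd_optimum",
    "save_model",
    "load_model",
]

LEAF_CLIP = 4.0  # max |log-odds| contribution of a single leaf
_EPS = 1e-12


@dataclass
class TreeNode:
    """Node of a regression tree: a leaf or an internal split.

    Internal nodes route ``x[variable] < split`` to the left child.  ``gain``
    stores the squared-error reduction achieved by the split at fit time (on
    the working residuals), which feeds variable importance.
    """

    variable: int | None = None
    split: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    value: float = 0.0
    gain: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vectorized prediction over an (n, n_vars) matrix."""
        if self.is_leaf:
            return np.full(X.shape[0], self.value)
        out = np.empty(X.shape[0])
        go_left = X[:, self.variable] < self.split
        out[go_left] = self.left.predict(X[go_left])
        out[~go_left] = self.right.predict(X[~go_left])
        return out

    def walk(self):
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value}
        return {
            "variable": self.variable,
            "split": self.split,
            "gain": self.gain,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "variable" not in d:
            return cls(value=d["value"])
        return cls(
            variable=d["variable"],
            split=d["split"],
            gain=d.get("gain", 0.0),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class BoostedModel:
    """Fitted additive ensemble of regression trees on the log-odds scale."""

    intercept: float
    trees: list[TreeNode]
    variables: list[str]
    learning_rate: float
    tree_complexity: int
    bag_fraction: float
    seed: int
    n_trees_used: int = 0
    calibration_rows: np.ndarray | None = None  # (n, n_vars), for partial dependence

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Log-odds F(x) for an (n, n_vars) covariate matrix."""
        F = np.full(X.shape[0], self.intercept)
        for tree in self.trees[: self.n_trees_used]:
            F += self.learning_rate * tree.predict(X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Climatic suitability p(x) in (0, 1)."""
        return _sigmoid(self.decision_function(X))

    def matrix_from_table(self, data: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise ValueError(f"covariates missing from table: {missing}")
        return data[self.variables].to_numpy(dtype=float)


@dataclass
class FitReport:
    """Per-stage deviance paths and holdout evaluation of one fit."""

    train_deviance_path: np.ndarray
    holdout_deviance_path: np.ndarray
    auc_train: float
    auc_test: float
    n_trees_used: int
    seed: int
    split_fractions: tuple[float, float] = (0.8, 0.2)
    still_improving: bool = False  # holdout deviance minimal at max_trees


def _sigmoid(F: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-F))


def _bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.mean(-2.0 * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def _best_split(X: np.ndarray, r: np.ndarray, rows: np.ndarray):
    """Exhaustive best split of ``rows`` minimizing SSE of residuals ``r``.

    Returns (gain, variable, threshold, left_rows, right_rows) or None when no
    admissible split exists.  Candidates are midpoints between consecutive
    distinct sorted values; ties break to the lowest variable index, then the
    lowest threshold.
    """
    n = rows.size
    if n < 2:
        return None
    rr = r[rows]
    total = rr.sum()
    base = total * total / n
    best = None
    for j in range(X.shape[1]):
        xj = X[rows, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        rs = rr[order]
        # boundaries between distinct consecutive values
        distinct = np.nonzero(np.diff(xs) > 0)[0]
        if distinct.size == 0:
            continue
        csum = np.cumsum(rs)
        n_left = distinct + 1
        s_left = csum[distinct]
        gain = s_left**2 / n_left + (total - s_left) ** 2 / (n - n_left) - base
        k = int(np.argmax(gain))  # first max -> lowest threshold
        g = float(gain[k])
        if best is None or g > best[0] + 1e-15:
            thr = 0.5 * (xs[distinct[k]] + xs[distinct[k] + 1])
            left = rows[order[: n_left[k]]]
            right = rows[order[n_left[k] :]]
            best = (g, j, float(thr), left, right)
    return best


def _fit_tree(
    X: np.ndarray, r: np.ndarray, p: np.ndarray, rows: np.ndarray, n_splits: int
) -> TreeNode:
    """Best-first regression tree on residuals with Newton leaf values.

    Grows up to ``n_splits`` internal splits, always expanding the leaf whose
    best split yields the largest SSE reduction.
    """
    root = TreeNode()
    frontier: list[tuple[TreeNode, np.ndarray]] = [(root, rows)]
    candidates = {}
    for _ in range(n_splits):
        # evaluate the best split of every unexpanded leaf (cached)
        best_leaf = None
        for leaf, leaf_rows in frontier:
            if id(leaf) not in candidates:
                candidates[id(leaf)] = _best_split(X, r, leaf_rows)
            cand = candidates[id(leaf)]
            if cand is None:
                continue
            if best_leaf is None or cand[0] > best_leaf[1][0] + 1e-15:
                best_leaf = (leaf, cand, leaf_rows)
        if best_leaf is None:
            break
        leaf, (gain, var, thr, lrows, rrows), leaf_rows = best_leaf
        leaf.variable, leaf.split, leaf.gain = var, thr, gain
        leaf.left, leaf.right = TreeNode(), TreeNode()
        frontier = [(nd, rw) for nd, rw in frontier if nd is not leaf]
        frontier += [(leaf.left, lrows), (leaf.right, rrows)]
    # Newton leaf values on the bag rows that reached each leaf
    for leaf, leaf_rows in frontier:
        num = r[leaf_rows].sum()
        den = (p[leaf_rows] * (1.0 - p[leaf_rows])).sum()
        value = num / den if den > _EPS else np.sign(num) * LEAF_CLIP
        leaf.value = float(np.clip(value, -LEAF_CLIP, LEAF_CLIP))
    return root


def _stratified_split(y: np.ndarray, test_fraction: float, rng: np.random.Generator):
    """Indices (train, test) with per-class proportional allocation."""
    train, test = [], []
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def fit_brt(
    data: pd.DataFrame,
    lr: float = 0.1,
    tree_complexity: int = 1,
    bag_fraction: float = 0.5,
    max_trees: int = 1000,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> tuple[BoostedModel, FitReport]:
    """Fit a boosted-tree suitability model to an occurrence table.

    ``data`` must carry a 0/1 ``label`` column and one numeric column per
    climate variable.  The table is split into training (80%) and testing
    (20%) halves, stratified by label; boosting runs on the training half and
    the returned model is truncated at the stage minimizing holdout deviance.
    Deterministic under ``seed``.
    """
    if not 0 <= lr <= 1:
        raise ValueError("learning rate must lie in [0, 1]")
    if not 0 < bag_fraction <= 1:
        raise ValueError("bag_fraction must lie in (0, 1]")
    if tree_complexity < 1:
        raise ValueError("tree_complexity must be >= 1")
    if max_trees < 1:
        raise ValueError("max_trees must be >= 1")
    variables = covariate_columns(data)
    if not variables:
        raise ValueError("occurrence table has no covariate columns")
    y = data["label"].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("both presence (1) and absence (0) labels are required")
    X = data[variables].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    train_idx, test_idx = _stratified_split(y, test_fraction, rng)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]
    n_train = Xtr.shape[0]
    bag_size = int(np.ceil(bag_fraction * n_train))

    prevalence = ytr.mean()
    F0 = float(np.clip(np.log(prevalence / (1.0 - prevalence)), -LEAF_CLIP, LEAF_CLIP))
    Ftr = np.full(n_train, F0)
    Fte = np.full(Xte.shape[0], F0)

    train_path = [_bernoulli_deviance(ytr, _sigmoid(Ftr))]
    hold_path = [_bernoulli_deviance(yte, _sigmoid(Fte))] if yte.size else [np.nan]
    trees: list[TreeNode] = []
    all_rows = np.arange(n_train)
    for _ in range(max_trees):
        p = _sigmoid(Ftr)
        r = ytr - p
        bag = np.sort(rng.choice(all_rows, size=bag_size, replace=False))
        tree = _fit_tree(Xtr, r, p, bag, tree_complexity)
        trees.append(tree)
        if lr > 0:
            Ftr += lr * tree.predict(Xtr)
            if Xte.shape[0]:
                Fte += lr * tree.predict(Xte)
        train_path.append(_bernoulli_deviance(ytr, _sigmoid(Ftr)))
        hold_path.append(_bernoulli_deviance(yte, _sigmoid(Fte)) if yte.size else np.nan)

    hold = np.asarray(hold_path)
    if yte.size:
        n_used = int(np.argmin(hold))  # stage index == number of trees kept
    else:
        n_used = max_trees
    still_improving = bool(
        yte.size and n_used == max_trees and max_trees > 1 and hold[-1] < hold[-2]
    )
    if still_improving:
        warnings.warn(
            f"holdout deviance still decreasing at max_trees={max_trees}; "
            "consider raising max_trees",
            stacklevel=2,
        )

    model = BoostedModel(
        intercept=F0,
        trees=trees,
        variables=list(variables),
        learning_rate=lr,
        tree_complexity=tree_complexity,
        bag_fraction=bag_fraction,
        seed=seed,
        n_trees_used=n_used,
        calibration_rows=X,
    )
    auc_train = auc(ytr, model.predict_proba(Xtr))
    auc_test = auc(yte, model.predict_proba(Xte)) if yte.size else np.nan
    report = FitReport(
        train_deviance_path=np.asarray(train_path),
        holdout_deviance_path=hold,
        auc_train=auc_train,
        auc_test=auc_test,
        n_trees_used=n_used,
        seed=seed,
        split_fractions=(1.0 - test_fraction, test_fraction),
        still_improving=still_improving,
    )
    return model, report


def predict_suitability(model: BoostedModel, stack: ClimateStack) -> np.ndarray:
    """Project a fitted model onto a climate scenario.

    Returns a suitability grid in [0, 1]; nodata cells propagate as NaN.
    """
    missing = [v for v in model.variables if v not in stack.values]
    if missing:
        raise ValueError(
            f"scenario {stack.scenario_id!r} lacks model variable(s): {missing}"
        )
    valid = ~stack.nodata_mask
    rows, cols = np.nonzero(valid)
    X = np.column_stack([stack.values[v][rows, cols] for v in model.variables])
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = model.predict_proba(X)
    return out


def auc(labels: Sequence[float], scores: Sequence[float]) -> float:
    """Area under the ROC curve by the Mann-Whitney pair-counting identity.

    AUC = (#concordant pairs + tied pairs / 2) / (n1 * n0), computed via the
    rank-sum of the positive class.  Requires both classes.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # average ranks handle ties as half-concordant
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def variable_importance(model: BoostedModel) -> dict[str, float]:
    """Relative influence of each variable, normalized to sum to 100.

    Sums the squared-error reduction of every split of each variable across
    the retained trees, scaled by the squared learning rate; variables never
    split get 0.  An intercept-only model returns all zeros with a warning.
    """
    raw = dict.fromkeys(model.variables, 0.0)
    for tree in model.trees[: model.n_trees_used]:
        for node in tree.walk():
            if not node.is_leaf:
                raw[model.variables[node.variable]] += node.gain * model.learning_rate**2
    total = sum(raw.values())
    if total <= 0:
        warnings.warn("model has no splits: variable importance undefined", stacklevel=2)
        return raw
    return {v: 100.0 * g / total for v, g in raw.items()}


def partial_dependence(
    model: BoostedModel,
    variable: str,
    grid_points: int = 50,
    data: np.ndarray | pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence curve of suitability on one variable.

    For each probe value the variable is clamped across the calibration rows
    and the predicted suitability averaged.  Uses the rows stored at fit time
    unless ``data`` overrides them.
    """
    if variable not in model.variables:
        raise ValueError(f"unknown variable {variable!r}")
    if data is None:
        data = model.calibration_rows
    if data is None:
        raise ValueError("no calibration rows available; pass data=")
    if isinstance(data, pd.DataFrame):
        data = model.matrix_from_table(data)
    X = np.asarray(data, dtype=float)
    j = model.variables.index(variable)
    lo, hi = X[:, j].min(), X[:, j].max()
    probes = np.linspace(lo, hi, grid_points)
    response = np.empty(grid_points)
    for i, v in enumerate(probes):
        Xc = X.copy()
        Xc[:, j] = v
        response[i] = model.predict_proba(Xc).mean()
    return probes, response


def pd_optimum(
    model: BoostedModel,
    variable: str,
    grid_points: int = 50,
    rel_tol: float = 0.02,
    data: np.ndarray | pd.DataFrame | None = None,
) -> float:
    """Estimated niche optimum: centroid of the partial-dependence maximum.

    A suitability model trained on thresholded occupancy has a flat-topped
    response, so the raw argmax of the curve sits at an arbitrary edge of the
    plateau.  The optimum is therefore estimated as the mean probe value over
    all points whose response is within ``rel_tol`` of the maximum.
    """
    probes, response = partial_dependence(model, variable, grid_points, data=data)
    top = response.max()
    plateau = response >= top * (1.0 - rel_tol)
    return float(probes[plateau].mean())


# ---------------------------------------------------------------------------
# serialization: plain JSON with full float precision (bit-exact round trip)

def save_model(path: str | Path, model: BoostedModel) -> None:
    doc = {
        "format": "paleorange-brt-1",
        "intercept": model.intercept,
        "variables": model.variables,
        "learning_rate": model.learning_rate,
        "tree_complexity": model.tree_complexity,
        "bag_fraction": model.bag_fraction,
        "seed": model.seed,
        "n_trees_used": model.n_trees_used,
        "trees": [t.to_dict() for t in model.trees],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> BoostedModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "paleorange-brt-1":
        raise ValueError(f"{path}: not a recognised model file")
    return BoostedModel(
        intercept=doc["intercept"],
        trees=[TreeNode.from_dict(t) for t in doc["trees"]],
        variables=list(doc["variables"]),
        learning_rate=doc["learning_rate"],
        tree_complexity=doc["tree_complexity"],
        bag_fraction=doc["bag_fraction"],
        seed=doc["seed"],
        n_trees_used=doc["n_trees_used"],
    )
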