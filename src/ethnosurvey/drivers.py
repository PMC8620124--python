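"""Classification and regression trees for cultivation-driver analysis.

Binary-outcome classification trees (willingness to cultivate) split
greedily on the Gini impurity decrease; regression trees (maximum acreage,
seedling price) on the between-node sum-of-squares reduction — the "class"
and "anova" methods of the rpart tradition, whose conventional defaults
(minsplit 20, minbucket ceil(minsplit/3), cp 0.01, 10-fold cross-validated
cost-complexity pruning) are kept.

Categorical features are split by bipartitioning their levels.  Levels are
ordered by outcome rate (positive-class rate for classification, mean
response for regression) and only the k-1 order-respecting bipartitions are
scanned; for binary outcomes and squared error this ordering theorem yields
the same optimum as exhaustive search over all 2^(k-1)-1 bipartitions.
Ties in split quality are broken by (feature name, partition) order so the
fitted tree is identical across platforms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "TreeParams",
    "Split",
    "fit_classification_tree",
    "fit_regression_tree",
    "prune_tree",
    "predict_tree",
    "tree_to_text",
]


@dataclass
class TreeParams:
    min_split: int = 20
    min_bucket: int | None = None  # defaults to ceil(min_split / 3)
    complexity: float = 0.01
    max_depth: int = 30
    n_cv_folds: int = 10
    seed: int = 0

    def resolved_min_bucket(self) -> int:
        return self.min_bucket if self.min_bucket is not None \
            else math.ceil(self.min_split / 3)

    def validate(self) -> None:
        if self.resolved_min_bucket() > self.min_split:
            raise ValueError("min_bucket must not exceed min_split")
        if self.complexity < 0:
            raise ValueError("complexity must be non-negative")


@dataclass
class Split:
    feature: str
    kind: str                                  # "numeric" | "categorical"
    threshold: float | None = None             # numeric: left iff x <= threshold
    left_levels: frozenset = frozenset()       # categorical: left iff x in set
    all_levels: frozenset = frozenset()        # levels seen at training time
    majority_left: bool = True                 # routing for unseen levels

    def goes_left(self, value) -> bool | None:
        if self.kind == "numeric":
            return bool(value <= self.threshold)
        if value in self.left_levels:
            return True
        return False

    def describe(self, left: bool) -> str:
        if self.kind == "numeric":
            op = "<=" if left else ">"
            return f"{self.feature} {op} {self.threshold:g}"
        levels = sorted(self.left_levels)
        return (f"{self.feature} in {levels}" if left
                else f"{self.feature} not in {levels}")


@dataclass
class TreeNode:
    prediction: object                 # class label or mean response
    probability: float                 # P(predicted class) — 1.0 for regression
    class_counts: dict | None          # None for regression
    n: int
    n_share: float
    impurity: float                    # Gini (classification) or MSE (regression)
    risk: float                        # misclassified count / SSE, used by pruning
    split: Split | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def subtree_risk(self) -> float:
        return sum(lf.risk for lf in self.leaves())


# ---------------------------------------------------------------------------
# Node statistics
# ---------------------------------------------------------------------------

def _class_stats(y: np.ndarray) -> tuple[object, float, dict, float, float]:
    levels, counts = np.unique(y, return_counts=True)
    order = np.lexsort((levels.astype(str),))  # deterministic
    levels, counts = levels[order], counts[order]
    n = counts.sum()
    best = int(np.argmax(counts))  # argmax takes the first (lexicographic) tie
    pred = levels[best]
    prob = counts[best] / n
    p = counts / n
    gini = float(1.0 - np.sum(p ** 2))
    risk = float(n - counts[best])  # misclassification count
    return pred, float(prob), dict(zip(levels.tolist(), counts.tolist())), gini, risk


def _reg_stats(y: np.ndarray) -> tuple[float, float, float]:
    mean = float(y.mean())
    sse = float(np.sum((y - mean) ** 2))
    return mean, sse / len(y), sse


def _make_leaf(y: np.ndarray, n_root: int, depth: int, classify: bool) -> TreeNode:
    if classify:
        pred, prob, counts, gini, risk = _class_stats(y)
        return TreeNode(pred, prob, counts, len(y), len(y) / n_root, gini,
                        risk, depth=depth)
    mean, mse, sse = _reg_stats(y)
    return TreeNode(mean, 1.0, None, len(y), len(y) / n_root, mse, sse,
                    depth=depth)


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

def _node_impurity_sum(y: np.ndarray, classify: bool) -> float:
    """n * Gini for classification, SSE for regression (the split criterion)."""
    if classify:
        _, counts = np.unique(y, return_counts=True)
        p = counts / counts.sum()
        return float(len(y) * (1.0 - np.sum(p ** 2)))
    return float(np.sum((y - y.mean()) ** 2))


def _positive_rate(y: np.ndarray, positive) -> float:
    return float(np.mean(y == positive))


def _candidate_splits(col: pd.Series, y: np.ndarray, classify: bool,
                      positive) -> list[Split]:
    if pd.api.types.is_numeric_dtype(col):
        vals = np.sort(col.unique().astype(float))
        thresholds = (vals[:-1] + vals[1:]) / 2.0
        return [Split(str(col.name), "numeric", threshold=float(t))
                for t in thresholds]
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        return []
    arr = col.astype(str).to_numpy()
    if classify:
        score = {lv: _positive_rate(y[arr == lv], positive) for lv in levels}
    else:
        score = {lv: float(y[arr == lv].mean()) for lv in levels}
    ordered = sorted(levels, key=lambda lv: (score[lv], lv))
    return [Split(str(col.name), "categorical",
                  left_levels=frozenset(ordered[: i + 1]),
                  all_levels=frozenset(levels))
            for i in range(len(ordered) - 1)]


def _route_mask(split: Split, col: pd.Series) -> np.ndarray:
    if split.kind == "numeric":
        return col.to_numpy(dtype=float) <= split.threshold
    return np.isin(col.astype(str).to_numpy(), sorted(split.left_levels))


def _best_split(X: pd.DataFrame, y: np.ndarray, classify: bool, positive,
                min_bucket: int) -> tuple[Split | None, float]:
    parent = _node_impurity_sum(y, classify)
    best: Split | None = None
    best_gain = 0.0
    for feature in sorted(X.columns.astype(str)):
        col = X[feature]
        for split in _candidate_splits(col, y, classify, positive):
            mask = _route_mask(split, col)
            n_l = int(mask.sum())
            n_r = len(y) - n_l
            if n_l < min_bucket or n_r < min_bucket:
                continue
            gain = parent - (_node_impurity_sum(y[mask], classify)
                             + _node_impurity_sum(y[~mask], classify))
            if gain > best_gain + 1e-12:  # ties keep the earlier candidate
                best, best_gain = split, gain
    return best, best_gain


# ---------------------------------------------------------------------------
# Growing
# ---------------------------------------------------------------------------

def _grow(X: pd.DataFrame, y: np.ndarray, params: TreeParams, classify: bool,
          positive, n_root: int, gain_floor: float, depth: int) -> TreeNode:
    node = _make_leaf(y, n_root, depth, classify)
    if (len(y) < params.min_split or depth >= params.max_depth
            or _node_impurity_sum(y, classify) <= 0):
        return node
    split, gain = _best_split(X, y, classify, positive,
                              params.resolved_min_bucket())
    if split is None or gain < gain_floor - 1e-12:
        return node
    mask = _route_mask(split, X[split.feature])
    split.majority_left = bool(mask.sum() >= (~mask).sum())
    node.split = split
    node.children = (
        _grow(X[mask], y[mask], params, classify, positive, n_root,
              gain_floor, depth + 1),
        _grow(X[~mask], y[~mask], params, classify, positive, n_root,
              gain_floor, depth + 1),
    )
    return node


def _prepare(features, outcome) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.DataFrame(features).reset_index(drop=True)
    if X.shape[1] == 0:
        raise ValueError("empty feature table")
    y = np.asarray(outcome)
    if len(y) != len(X):
        raise ValueError("features and outcome sizes differ")
    return X, y


def fit_classification_tree(features, labels,
                            params: TreeParams | None = None) -> TreeNode:
    """Grow a binary classification tree by greedy Gini splitting.

    Constant labels yield a degenerate single-leaf tree.  The complexity
    parameter acts as a growth floor: a split must reduce the root's Gini
    impurity sum by at least ``complexity`` times it.
    """
    params = params or TreeParams()
    params.validate()
    X, y = _prepare(features, labels)
    classes = np.unique(y.astype(str))
    if len(classes) > 2:
        raise ValueError("only binary outcomes are supported")
    y = y.astype(str)
    positive = sorted(classes)[-1]
    root_impurity = _node_impurity_sum(y, True)
    return _grow(X, y, params, True, positive, len(y),
                 params.complexity * max(root_impurity, 1e-300), 0)


def fit_regression_tree(features, response,
                        params: TreeParams | None = None) -> TreeNode:
    """Grow a regression tree by greedy sum-of-squares splitting."""
    params = params or TreeParams()
    params.validate()
    X, y = _prepare(features, response)
    y = y.astype(float)
    root_sse = _node_impurity_sum(y, False)
    return _grow(X, y, params, False, None, len(y),
                 params.complexity * max(root_sse, 1e-300), 0)


# ---------------------------------------------------------------------------
# Prediction and rendering
# ---------------------------------------------------------------------------

def _route(node: TreeNode, row: pd.Series, notes: list[str]) -> TreeNode:
    while not node.is_leaf:
        split = node.split
        value = row[split.feature]
        if split.kind == "categorical" and str(value) not in split.all_levels:
            notes.append(f"unseen level {value!r} for {split.feature!r}: "
                         f"routed to majority side")
            node = node.children[0] if split.majority_left else node.children[1]
            continue
        left = split.goes_left(value if split.kind == "numeric" else str(value))
        node = node.children[0] if left else node.children[1]
    return node


def predict_tree(tree: TreeNode, rows) -> np.ndarray:
    """Deterministic routing of each row to its leaf prediction.

    Categorical levels never seen at a split are routed to the side that
    held the training majority, with a warning.
    """
    X = pd.DataFrame(rows).reset_index(drop=True)
    notes: list[str] = []
    preds = [_route(tree, X.iloc[i], notes).prediction for i in range(len(X))]
    for note in sorted(set(notes)):
        warnings.warn(note, stacklevel=2)
    return np.asarray(preds)


def predict_leaf(tree: TreeNode, rows) -> list[TreeNode]:
    """The leaf node each row is routed to (for inspecting leaf statistics)."""
    X = pd.DataFrame(rows).reset_index(drop=True)
    notes: list[str] = []
    return [_route(tree, X.iloc[i], notes) for i in range(len(X))]


def tree_to_text(tree: TreeNode) -> str:
    """Indented rule listing: split rule, prediction, probability or mean,
    and percentage of observations at each node."""
    lines: list[str] = []

    def fmt(node: TreeNode, rule: str, indent: int) -> None:
        if node.class_counts is not None:
            desc = (f"class={node.prediction} p={node.probability:.3f}")
        else:
            desc = f"mean={node.prediction:.4g}"
        tag = "leaf" if node.is_leaf else "node"
        lines.append("  " * indent
                     + f"{rule}{tag}: {desc} ({node.n_share * 100:.1f}% of obs)")
        if not node.is_leaf:
            fmt(node.children[0], node.split.describe(True) + " -> ", indent + 1)
            fmt(node.children[1], node.split.describe(False) + " -> ", indent + 1)

    fmt(tree, "", 0)
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cost-complexity pruning
# ---------------------------------------------------------------------------

def _clone(node: TreeNode) -> TreeNode:
    child = None
    if node.children is not None:
        child = (_clone(node.children[0]), _clone(node.children[1]))
    return TreeNode(node.prediction, node.probability,
                    dict(node.class_counts) if node.class_counts else node.class_counts,
                    node.n, node.n_share, node.impurity, node.risk,
                    node.split, child, node.depth)


def _weakest_alpha(node: TreeNode) -> tuple[float, TreeNode]:
    """Minimum g(t) = (R(t) - R(T_t)) / (leaves - 1) over internal nodes."""
    best = (math.inf, node)
    if node.is_leaf:
        return best
    g = (node.risk - node.subtree_risk()) / max(node.n_leaves() - 1, 1)
    best = (g, node)
    for ch in node.children:
        cand = _weakest_alpha(ch)
        if cand[0] < best[0]:
            best = cand
    return best


def _collapse(node: TreeNode) -> None:
    node.children = None
    node.split = None


def _alpha_sequence(tree: TreeNode) -> list[tuple[float, TreeNode]]:
    """Nested subtree sequence [(alpha_k, subtree_k)] from full tree to root."""
    seq = [(0.0, _clone(tree))]
    current = _clone(tree)
    while not current.is_leaf:
        g, node = _weakest_alpha(current)
        _collapse(node)
        seq.append((g, _clone(current)))
    return seq


def _prune_at(tree: TreeNode, alpha: float) -> TreeNode:
    out = _clone(tree)
    while not out.is_leaf:
        g, node = _weakest_alpha(out)
        if g <= alpha + 1e-12:
            _collapse(node)
        else:
            break
    return out


def _holdout_risk(tree: TreeNode, X: pd.DataFrame, y: np.ndarray,
                  classify: bool) -> float:
    leaves = predict_leaf(tree, X)
    if classify:
        return float(sum(lf.prediction != yi for lf, yi in zip(leaves, y.astype(str))))
    return float(sum((float(lf.prediction) - yi) ** 2
                     for lf, yi in zip(leaves, y.astype(float))))


def prune_tree(tree: TreeNode, features, outcome,
               params: TreeParams | None = None) -> TreeNode:
    """Weakest-link cost-complexity pruning with cross-validated selection.

    The subtree sequence is indexed by alpha; ``params.n_cv_folds``-fold
    cross-validation (seeded fold assignment) picks the alpha minimising the
    held-out risk, and the returned subtree is the full tree pruned at the
    larger of that alpha and ``complexity`` times the root risk.  A zero
    complexity returns the tree unchanged; an infinite one returns the
    root-only leaf.
    """
    params = params or TreeParams()
    params.validate()
    if params.complexity == 0:
        return _clone(tree)
    if math.isinf(params.complexity):
        out = _clone(tree)
        _collapse(out)
        return out
    X, y = _prepare(features, outcome)
    classify = tree.class_counts is not None
    seq = _alpha_sequence(tree)
    alphas = [a for a, _ in seq]
    # geometric-mean evaluation points between successive alphas
    evals = [0.0]
    for a, b in zip(alphas[:-1], alphas[1:]):
        evals.append(math.sqrt(max(a, 1e-12) * max(b, 1e-12)))
    rng = np.random.default_rng(params.seed)
    folds = rng.integers(0, params.n_cv_folds, size=len(y))
    cv_risk = np.zeros(len(evals))
    grow = fit_classification_tree if classify else fit_regression_tree
    for k in range(params.n_cv_folds):
        train = folds != k
        if train.all() or not train.any():
            continue
        sub = grow(X[train], y[train], params)
        for i, alpha in enumerate(evals):
            pruned = _prune_at(sub, alpha)
            cv_risk[i] += _holdout_risk(pruned, X[~train], y[~train], classify)
    best_alpha = evals[int(np.argmin(cv_risk))]
    floor = params.complexity * max(tree.risk, 1e-300)
    return _prune_at(tree, max(best_alpha, floor))
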