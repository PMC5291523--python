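"""Regression random forest with variance-reduction variable importance.

Trees are fully grown (split until every leaf has zero impurity or its rows
are indistinguishable) with the squared-error criterion, so node impurity is
the population variance of the node's responses. The importance of the
splitting variable at a node is the decrease in total variance

    IV = n * var_parent - n1 * var_child1 - n2 * var_child2,

where the variance convention is population variance (divide by node count),
making n * var the node's sum of squared deviations and IV exactly additive.
A variable's importance in a tree is the sum of IV over the nodes that split
on it; forest importance is the mean over trees. Features never chosen have
importance zero.

Tree growing is delegated to scikit-learn's ``DecisionTreeRegressor``;
bootstrap resampling, per-tree seeding and all importance accounting are done
here, directly from the stored tree arrays, so that per-tree conservation
(sum of feature importances == sum of node IVs) holds exactly and results
are bit-reproducible from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .data_model import ValidationError

_MAX_SEED = 2**31 - 1


@dataclass
class ForestParams:
    """Forest hyperparameters.

    ntree : number of trees (default 1000)
    mtry : candidate features per node; default max(1, p // 3), the usual
        regression-forest convention
    bootstrap_size : samples drawn per bootstrap (with replacement); default n
    seed : master seed for bootstraps and tree randomness
    """

    ntree: int = 1000
    mtry: int | None = None
    bootstrap_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValidationError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1")

    def resolved_mtry(self, p: int) -> int:
        if self.mtry is None:
            return max(1, p // 3)
        return min(self.mtry, p)


@dataclass
class SplitRecord:
    """One internal node's split bookkeeping for the IV formula."""

    n: int
    n1: int
    n2: int
    var_parent: float
    var_child1: float
    var_child2: float
    feature: int = -1
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        if self.n != self.n1 + self.n2:
            raise ValidationError("child counts must sum to the parent count")
        if self.n1 < 1 or self.n2 < 1:
            raise ValidationError("both children must be non-empty")
        if min(self.var_parent, self.var_child1, self.var_child2) < 0:
            raise ValidationError("variances must be nonnegative")


def split_importance(rec: SplitRecord) -> float:
    """Variance decrease IV = n*var_p - n1*var_c1 - n2*var_c2, floored at 0."""
    iv = rec.n * rec.var_parent - rec.n1 * rec.var_child1 - rec.n2 * rec.var_child2
    return max(0.0, iv)


@dataclass
class Forest:
    """A fitted forest: sklearn trees plus their bootstrap multiplicities."""

    trees: list[DecisionTreeRegressor]
    bootstrap_counts: list[np.ndarray]
    feature_ids: list[str]
    params: ForestParams

    def __len__(self) -> int:
        return len(self.trees)


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    params: ForestParams,
    seed: int,
    sample_weight: np.ndarray | None = None,
) -> DecisionTreeRegressor:
    """Grow one fully grown regression tree on (X, y).

    At each node ``mtry`` features are sampled without replacement and the
    (feature, threshold) pair minimizing weighted child variance is taken;
    recursion stops at zero impurity or indistinguishable rows. Thresholds
    are midpoints between consecutive sorted unique feature values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y must share the sample axis")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    tree = DecisionTreeRegressor(
        criterion="squared_error",
        splitter="best",
        max_features=params.resolved_mtry(X.shape[1]),
        random_state=int(seed) % _MAX_SEED,
    )
    tree.fit(X, y, sample_weight=sample_weight)
    return tree


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    params: ForestParams,
    feature_ids: list[str] | None = None,
) -> Forest:
    """Fit ``ntree`` trees, each on its own bootstrap sample (with replacement).

    Deterministic given ``params.seed``: bootstrap indices and per-tree seeds
    are drawn from a single seeded stream, independent of execution order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    n, p = X.shape
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if p < 1:
        raise ValidationError("need at least 1 feature")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    if len(feature_ids) != p:
        raise ValidationError("feature_ids length must equal the column count")
    boot_n = params.bootstrap_size or n
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    trees: list[DecisionTreeRegressor] = []
    counts_list: list[np.ndarray] = []
    for _ in range(params.ntree):
        idx = rng.integers(0, n, size=boot_n)
        counts = np.bincount(idx, minlength=n).astype(float)
        tree_seed = int(rng.integers(_MAX_SEED))
        trees.append(grow_tree(X, y, params, tree_seed, sample_weight=counts))
        counts_list.append(counts)
    return Forest(trees, counts_list, list(feature_ids), params)


def tree_importance(tree: DecisionTreeRegressor, p: int) -> np.ndarray:
    """Per-feature importance of one tree: sum of node IVs, vectorized.

    sklearn stores, per node, the weighted sample count and the impurity
    (population variance under squared error), so each internal node's IV is
    read off directly as w*var_parent - w1*var_c1 - w2*var_c2.
    """
    t = tree.tree_
    left, right = t.children_left, t.children_right
    internal = left != -1
    w = t.weighted_n_node_samples
    var = t.impurity
    iv = (
        w[internal] * var[internal]
        - w[left[internal]] * var[left[internal]]
        - w[right[internal]] * var[right[internal]]
    )
    np.maximum(iv, 0.0, out=iv)
    out = np.zeros(p)
    np.add.at(out, t.feature[internal], iv)
    return out


def forest_importance(forest: Forest) -> dict[str, float]:
    """Mean over trees of per-tree summed IV, keyed by feature ID."""
    p = len(forest.feature_ids)
    total = np.zeros(p)
    for tree in forest.trees:
        total += tree_importance(tree, p)
    total /= len(forest.trees)
    return dict(zip(forest.feature_ids, total.tolist()))
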