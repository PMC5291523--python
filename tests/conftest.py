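import numpy as np
import pytest

from bwerf import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng):
    """12 samples x 6 genes: g1 drives g0, the rest are independent noise."""
    n = 12
    x = rng.normal(size=(n, 5))
    y = 2.0 * x[:, 0] + 0.1 * rng.normal(size=n)
    values = np.column_stack([y, x])
    return ExpressionMatrix(
        [f"s{i}" for i in range(n)],
        ["g0", "g1", "g2", "g3", "g4", "g5"],
        values,
    )


def weighted_var(y, w):
    """Weighted population variance, the impurity convention used throughout."""
    w = np.asarray(w, float)
    m = np.average(y, weights=w)
    return float(np.average((y - m) ** 2, weights=w))


def retraversal_importance(tree, X, y, counts, p):
    """Independent importance oracle: push the bootstrap sample (with
    multiplicities) down the stored tree and recompute each internal node's
    variance decrease IV = n*var_p - n1*var_c1 - n2*var_c2 from the node
    sample sets, summing per splitting feature."""
    t = tree.tree_
    imp = np.zeros(p)
    mask0 = counts > 0
    stack = [(0, np.flatnonzero(mask0))]
    while stack:
        node, idx = stack.pop()
        if t.children_left[node] == -1:
            continue
        f, thr = t.feature[node], t.threshold[node]
        w = counts[idx]
        left = idx[X[idx, f] <= thr]
        right = idx[X[idx, f] > thr]
        iv = (
            w.sum() * weighted_var(y[idx], w)
            - counts[left].sum() * weighted_var(y[left], counts[left])
            - counts[right].sum() * weighted_var(y[right], counts[right])
        )
        imp[f] += max(0.0, iv)
        stack.append((t.children_left[node], left))
        stack.append((t.children_right[node], right))
    return imp
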