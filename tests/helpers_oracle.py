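"""Independent brute-force regression-tree oracle for forest tests.

Grows a CART-style tree by exhaustive enumeration: at every node all features
and all midpoint thresholds between consecutive sorted unique values are
scored by the summed within-child squared deviation of the target, and the
minimum is taken.  Deliberately simple and slow; used only on tiny datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OracleNode:
    value: float
    feature: int | None = None
    threshold: float | None = None
    left: "OracleNode | None" = None
    right: "OracleNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def build_tree(X: np.ndarray, y: np.ndarray, min_leaf: int = 1) -> OracleNode:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    node = OracleNode(value=float(y.mean()))
    if len(y) < 2 * min_leaf or np.ptp(y) == 0:
        return node
    best = None  # (cost, feature, threshold)
    for j in range(X.shape[1]):
        xs = np.unique(X[:, j])
        for t in (xs[:-1] + xs[1:]) / 2.0:
            left = X[:, j] <= t
            nl = int(left.sum())
            if nl < min_leaf or len(y) - nl < min_leaf:
                continue
            yl, yr = y[left], y[~left]
            cost = float(((yl - yl.mean()) ** 2).sum() + ((yr - yr.mean()) ** 2).sum())
            if best is None or cost < best[0] - 1e-12:
                best = (cost, j, float(t))
    if best is None:
        return node
    _, j, t = best
    left = X[:, j] <= t
    node.feature = j
    node.threshold = t
    node.left = build_tree(X[left], y[left], min_leaf)
    node.right = build_tree(X[~left], y[~left], min_leaf)
    return node


def predict_tree(node: OracleNode, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    out = np.empty(len(X))
    for i, x in enumerate(X):
        n = node
        while not n.is_leaf:
            n = n.left if x[n.feature] <= n.threshold else n.right
        out[i] = n.value
    return out


def _split_cost(X, y, j, t) -> float:
    left = X[:, j] <= t
    yl, yr = y[left], y[~left]
    return float(((yl - yl.mean()) ** 2).sum() + ((yr - yr.mean()) ** 2).sum())


def _best_cost(X, y, min_leaf) -> float | None:
    best = None
    for j in range(X.shape[1]):
        xs = np.unique(X[:, j])
        for t in (xs[:-1] + xs[1:]) / 2.0:
            nl = int((X[:, j] <= t).sum())
            if nl < min_leaf or len(y) - nl < min_leaf:
                continue
            cost = _split_cost(X, y, j, t)
            if best is None or cost < best:
                best = cost
    return best


def verify_node_for_node(tree, X, y, min_leaf: int = 1, node: int = 0, atol: float = 1e-6):
    """Walk a fitted sklearn tree and assert, node for node, that every split
    achieves the exhaustive-enumeration optimum on that node's samples, that
    every node's value is the sample mean, and that leaves are exactly the
    nodes the brute-force builder would refuse to split.

    (Equal-cost splits can differ in the feature chosen, so optimality of the
    cost — not feature identity — is the well-defined node-wise comparison.)
    """
    X = np.asarray(X, dtype=np.float32).astype(float)  # sklearn trains on float32
    y = np.asarray(y, dtype=float)
    assert abs(float(tree.value[node].ravel()[0]) - y.mean()) <= atol, "node value"
    left_id = tree.children_left[node]
    opt = _best_cost(X, y, min_leaf)
    unsplittable = len(y) < 2 * min_leaf or np.ptp(y) == 0 or opt is None
    if left_id == -1:
        assert unsplittable, "sklearn stopped where the oracle would split"
        return
    assert not unsplittable, "sklearn split where the oracle would stop"
    j = int(tree.feature[node])
    t = float(tree.threshold[node])
    cost = _split_cost(X, y, j, t)
    assert cost <= opt + atol, f"node {node}: split cost {cost} > optimum {opt}"
    mask = X[:, j] <= t
    verify_node_for_node(tree, X[mask], y[mask], min_leaf,
                         int(left_id), atol)
    verify_node_for_node(tree, X[~mask], y[~mask], min_leaf,
                         int(tree.children_right[node]), atol)
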