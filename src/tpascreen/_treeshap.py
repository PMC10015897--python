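"""Exact path-dependent Shapley attributions for decision-tree ensembles.

Implements the polynomial-time TreeSHAP recursion (Lundberg et al.,
Nat. Mach. Intell. 2020): for one sample and one tree, a path of unique
features is extended down the tree while tracking, for every path subset
size, the proportion of feature coalitions that flow hot (feature present,
follow the sample) versus cold (feature absent, follow the training cover).
At a leaf, unwinding the path yields each feature's exact Shapley weight
under the tree's cover-conditioned expectation -- the same attribution the
reference TreeExplainer produces in its default (tree-path-dependent) mode.

The recursion is numba-compiled over flat tree arrays; sklearn regressors
(single trees, random forests, gradient-boosted ensembles) are flattened by
:func:`trees_from_sklearn`.  Attributions satisfy additivity exactly:
base value + sum of per-feature phis = model prediction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["TreeArrays", "tree_shap", "trees_from_sklearn", "expected_value"]


@njit
def _extend(pf, pz, po, pw, off, unique_depth, zero_fraction, one_fraction, feature_index):
    pf[off + unique_depth] = feature_index
    pz[off + unique_depth] = zero_fraction
    po[off + unique_depth] = one_fraction
    pw[off + unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[off + i + 1] += one_fraction * pw[off + i] * (i + 1.0) / (unique_depth + 1.0)
        pw[off + i] = zero_fraction * pw[off + i] * (unique_depth - i) / (unique_depth + 1.0)


@njit
def _unwind(pf, pz, po, pw, off, unique_depth, path_index):
    one_fraction = po[off + path_index]
    zero_fraction = pz[off + path_index]
    next_one_portion = pw[off + unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[off + i]
            pw[off + i] = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            next_one_portion = tmp - pw[off + i] * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        else:
            pw[off + i] = pw[off + i] * (unique_depth + 1.0) / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        pf[off + i] = pf[off + i + 1]
        pz[off + i] = pz[off + i + 1]
        po[off + i] = po[off + i + 1]


@njit
def _unwound_sum(pf, pz, po, pw, off, unique_depth, path_index):
    one_fraction = po[off + path_index]
    zero_fraction = pz[off + path_index]
    next_one_portion = pw[off + unique_depth]
    total = 0.0
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one_portion = pw[off + i] - tmp * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        elif zero_fraction != 0.0:
            total += (pw[off + i] / zero_fraction) / ((unique_depth - i) / (unique_depth + 1.0))
    return total


@njit
def _recurse(
    children_left, children_right, feature, threshold, value, cover,
    x, phi,
    node, unique_depth, parent_off,
    parent_zero_fraction, parent_one_fraction, parent_feature_index,
    pf, pz, po, pw,
):
    off = parent_off + unique_depth
    for i in range(unique_depth):
        pf[off + i] = pf[parent_off + i]
        pz[off + i] = pz[parent_off + i]
        po[off + i] = po[parent_off + i]
        pw[off + i] = pw[parent_off + i]
    _extend(pf, pz, po, pw, off, unique_depth,
            parent_zero_fraction, parent_one_fraction, parent_feature_index)

    if children_left[node] < 0:  # leaf
        leaf_value = value[node]
        for i in range(1, unique_depth + 1):
            w = _unwound_sum(pf, pz, po, pw, off, unique_depth, i)
            phi[pf[off + i]] += w * (po[off + i] - pz[off + i]) * leaf_value
        return

    split_feature = feature[node]
    if x[split_feature] <= threshold[node]:
        hot, cold = children_left[node], children_right[node]
    else:
        hot, cold = children_right[node], children_left[node]
    w = cover[node]
    hot_zero_fraction = cover[hot] / w
    cold_zero_fraction = cover[cold] / w
    incoming_zero_fraction = 1.0
    incoming_one_fraction = 1.0

    # undo a previous split on the same feature
    path_index = 0
    while path_index <= unique_depth:
        if pf[off + path_index] == split_feature:
            break
        path_index += 1
    if path_index != unique_depth + 1:
        incoming_zero_fraction = pz[off + path_index]
        incoming_one_fraction = po[off + path_index]
        _unwind(pf, pz, po, pw, off, unique_depth, path_index)
        unique_depth -= 1

    _recurse(children_left, children_right, feature, threshold, value, cover,
             x, phi, hot, unique_depth + 1, off,
             hot_zero_fraction * incoming_zero_fraction, incoming_one_fraction,
             split_feature, pf, pz, po, pw)
    _recurse(children_left, children_right, feature, threshold, value, cover,
             x, phi, cold, unique_depth + 1, off,
             cold_zero_fraction * incoming_zero_fraction, 0.0,
             split_feature, pf, pz, po, pw)


@njit
def _shap_one_tree(children_left, children_right, feature, threshold, value,
                   cover, X, phi_matrix, max_depth):
    n_samples = X.shape[0]
    size = (max_depth + 2) * (max_depth + 3)
    pf = np.empty(size, dtype=np.int64)
    pz = np.empty(size, dtype=np.float64)
    po = np.empty(size, dtype=np.float64)
    pw = np.empty(size, dtype=np.float64)
    for s in range(n_samples):
        _recurse(children_left, children_right, feature, threshold, value,
                 cover, X[s], phi_matrix[s], 0, 0, 0, 1.0, 1.0, -1,
                 pf, pz, po, pw)


class TreeArrays:
    """Flat-array view of one regression tree (leaf values pre-scaled)."""

    def __init__(self, children_left, children_right, feature, threshold,
                 value, cover):
        self.children_left = np.asarray(children_left, dtype=np.int64)
        self.children_right = np.asarray(children_right, dtype=np.int64)
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=np.float64)
        self.value = np.asarray(value, dtype=np.float64)
        self.cover = np.asarray(cover, dtype=np.float64)

    @property
    def max_depth(self) -> int:
        depth = np.zeros(len(self.children_left), dtype=np.int64)
        best = 0
        for node in range(len(self.children_left)):
            left = self.children_left[node]
            if left >= 0:
                depth[left] = depth[node] + 1
                depth[self.children_right[node]] = depth[node] + 1
        if len(depth):
            best = int(depth.max())
        return best

    def expected_value(self) -> float:
        """Cover-weighted mean over leaves = tree expectation at the root."""
        return _expected(self.children_left, self.children_right,
                         self.value, self.cover, 0)


def _expected(cl, cr, value, cover, node) -> float:
    if cl[node] < 0:
        return float(value[node])
    left, right = cl[node], cr[node]
    return (
        cover[left] * _expected(cl, cr, value, cover, left)
        + cover[right] * _expected(cl, cr, value, cover, right)
    ) / cover[node]


def trees_from_sklearn(model) -> tuple[list[TreeArrays], float]:
    """Flatten a fitted sklearn tree model into TreeArrays + base offset.

    Supports DecisionTreeRegressor, RandomForestRegressor and
    GradientBoostingRegressor; leaf values are scaled so the ensemble
    prediction is offset + sum of tree outputs.
    """
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.tree import DecisionTreeRegressor

    def _one(tree, scale):
        t = tree.tree_
        return TreeArrays(
            t.children_left, t.children_right, t.feature, t.threshold,
            t.value[:, 0, 0] * scale, t.weighted_n_node_samples,
        )

    if isinstance(model, DecisionTreeRegressor):
        return [_one(model, 1.0)], 0.0
    if isinstance(model, RandomForestRegressor):
        n = len(model.estimators_)
        return [_one(est, 1.0 / n) for est in model.estimators_], 0.0
    if isinstance(model, GradientBoostingRegressor):
        if model.loss != "squared_error":
            raise ValueError("only squared-error boosting is supported")
        offset = float(np.ravel(model.init_.constant_)[0])
        lr = model.learning_rate
        return [_one(est, lr) for est in model.estimators_[:, 0]], offset
    raise TypeError(
        f"unsupported model type for exact tree attribution: {type(model).__name__}"
    )


def tree_shap(trees: list[TreeArrays], X: np.ndarray, offset: float = 0.0
              ) -> tuple[np.ndarray, float]:
    """Exact attributions for an ensemble; returns (phi [n, p], base value)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros_like(X)
    base = offset
    for t in trees:
        _shap_one_tree(t.children_left, t.children_right, t.feature,
                       t.threshold, t.value, t.cover, X, phi, t.max_depth)
        base += t.expected_value()
    return phi, base


def expected_value(trees: list[TreeArrays], offset: float = 0.0) -> float:
    return offset + sum(t.expected_value() for t in trees)
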