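"""Gini-importance random forest for binary labels.

A single-purpose CART forest used by the embedded step of the stability
selection: 100 trees by default, bootstrap resampling, sqrt feature
sampling at each node, splits chosen by Gini impurity decrease, and mean
decrease in impurity (Gini importance) as the ranking statistic —
per-tree importances are normalized to sum to one and averaged across
trees, matching the convention of sklearn's ``feature_importances_``.

The kernel is numba-compiled because the selection procedure refits the
forest tens of thousands of times on small matrices, where a general
estimator's per-fit overhead dominates by two orders of magnitude. A unit
test cross-checks the importance ranking against
``sklearn.ensemble.RandomForestClassifier`` on planted-signal data.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gini_importances"]


@njit(cache=True)
def _forest_kernel(X, y, n_trees, max_features, seed):  # pragma: no cover - jitted
    n, p = X.shape
    imp_total = np.zeros(p)
    np.random.seed(seed)
    max_nodes = 4 * n + 8
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    vals = np.empty(n)
    ys = np.empty(n, np.int64)
    for _ in range(n_trees):
        idx = np.random.randint(0, n, n)
        top = 0
        stack_lo[top] = 0
        stack_hi[top] = n
        top = 1
        imp = np.zeros(p)
        while top > 0:
            top -= 1
            lo = stack_lo[top]
            hi = stack_hi[top]
            m = hi - lo
            c1 = 0
            for i in range(lo, hi):
                c1 += y[idx[i]]
            c0 = m - c1
            if c1 == 0 or c0 == 0 or m < 2:
                continue
            node_gini = 1.0 - (c0 / m) ** 2 - (c1 / m) ** 2
            perm = np.random.permutation(p)
            best_gain = 0.0
            best_f = -1
            best_thr = 0.0
            examined = 0
            for fi in range(p):
                if examined >= max_features:
                    break
                f = perm[fi]
                for i in range(m):
                    vals[i] = X[idx[lo + i], f]
                    ys[i] = y[idx[lo + i]]
                order = np.argsort(vals[:m])
                if vals[order[0]] == vals[order[m - 1]]:
                    continue  # constant within node: does not count as examined
                examined += 1
                nl = 0
                c1l = 0
                for i in range(m - 1):
                    o = order[i]
                    nl += 1
                    c1l += ys[o]
                    if vals[order[i]] == vals[order[i + 1]]:
                        continue
                    nr = m - nl
                    c1r = c1 - c1l
                    c0l = nl - c1l
                    c0r = nr - c1r
                    gl = 1.0 - (c0l / nl) ** 2 - (c1l / nl) ** 2
                    gr = 1.0 - (c0r / nr) ** 2 - (c1r / nr) ** 2
                    gain = node_gini - (nl / m) * gl - (nr / m) * gr
                    if gain > best_gain + 1e-15:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (vals[order[i]] + vals[order[i + 1]])
            if best_f < 0 or best_gain <= 0.0:
                continue
            imp[best_f] += (m / n) * best_gain
            left = lo
            right = hi - 1
            while left <= right:
                if X[idx[left], best_f] <= best_thr:
                    left += 1
                else:
                    tmp = idx[left]
                    idx[left] = idx[right]
                    idx[right] = tmp
                    right -= 1
            mid = left
            if lo < mid < hi:
                stack_lo[top] = lo
                stack_hi[top] = mid
                top += 1
                stack_lo[top] = mid
                stack_hi[top] = hi
                top += 1
        s = imp.sum()
        if s > 0.0:
            imp_total += imp / s
    return imp_total / n_trees


def gini_importances(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    max_features: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Mean-decrease-in-impurity importances of a seeded bootstrap forest.

    Parameters
    ----------
    X : (n_samples, n_features) float array
    y : (n_samples,) array of 0/1 labels
    n_trees : number of CART trees grown on bootstrap samples
    max_features : features examined per node (default ``round(sqrt(p))``)
    seed : forest seed (bootstrap draws and feature sampling)
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, p) and y must be (n,)")
    if X.shape[1] == 0:
        return np.zeros(0)
    if max_features is None:
        max_features = max(1, int(round(np.sqrt(X.shape[1]))))
    return _forest_kernel(X, y, int(n_trees), int(max_features), int(seed) % (2**31 - 1))
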