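"""Independent oracle implementations shared across test modules.

These are deliberately written from the definitions (direct cost
evaluation, exhaustive scans) and stay independent of the package's
prefix-sum split search.
"""

import numpy as np
import pytest

from mahaforest.forest import mahalanobis_cost


def brute_force_best_split(X, Y, lam, min_leaf=1):
    """Exhaustive scan over every (feature, midpoint) pair, computing child
    costs directly from the definition.  Ties: lowest feature, lowest
    threshold.  Returns (feature, threshold) or None."""
    n, p = X.shape
    parent = mahalanobis_cost(Y, lam)
    best = None
    for f in range(p):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2.0
            left = X[:, f] <= thr
            nl, nr = left.sum(), (~left).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            cost = mahalanobis_cost(Y[left], lam) + mahalanobis_cost(Y[~left], lam)
            if best is None or cost < best[0] - 1e-12:
                best = (cost, f, thr)
    if best is None or not best[0] < parent:
        return None
    return best[1], best[2]


class VarianceTree:
    """Test-local univariate CART with the plain variance (SSE) criterion,
    implemented directly from the definition."""

    def __init__(self, max_depth, min_leaf):
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    def fit(self, X, y):
        self.root = self._build(X, y, 0)
        return self

    def _best(self, X, y):
        n, p = X.shape
        parent = float(((y - y.mean()) ** 2).sum())
        best = None
        for f in range(p):
            vals = np.unique(X[:, f])
            for a, b in zip(vals[:-1], vals[1:]):
                thr = (a + b) / 2.0
                left = X[:, f] <= thr
                nl = left.sum()
                if nl < self.min_leaf or n - nl < self.min_leaf:
                    continue
                yl, yr = y[left], y[~left]
                cost = float(((yl - yl.mean()) ** 2).sum()) + float(
                    ((yr - yr.mean()) ** 2).sum()
                )
                if best is None or cost < best[0]:
                    best = (cost, f, thr)
        if best is None or not best[0] < parent:
            return None
        return best[1], best[2]

    def _build(self, X, y, depth):
        node = {"value": float(y.mean()), "n": len(y)}
        if depth >= self.max_depth or len(y) < 2 * self.min_leaf:
            return node
        s = self._best(X, y)
        if s is None:
            return node
        f, thr = s
        left = X[:, f] <= thr
        node.update(feature=f, threshold=thr)
        node["left"] = self._build(X[left], y[left], depth + 1)
        node["right"] = self._build(X[~left], y[~left], depth + 1)
        return node


def assert_same_structure(node, ref):
    """Recursively compare a fitted package tree with an oracle tree."""
    assert np.allclose(node.value[0], ref["value"])
    assert node.n_samples == ref["n"]
    if "feature" in ref:
        assert node.feature == ref["feature"]
        assert node.threshold == pytest.approx(ref["threshold"])
        assert_same_structure(node.left, ref["left"])
        assert_same_structure(node.right, ref["right"])
    else:
        assert node.is_leaf


def with_exact_sample_cov(rng, n, target):
    """Rows whose sample covariance is exactly `target`."""
    X = rng.normal(size=(n, target.shape[0]))
    X -= X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    X = X @ np.linalg.inv(np.linalg.cholesky(S).T)
    return X @ np.linalg.cholesky(target).T
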