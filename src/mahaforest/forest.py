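"""Multivariate random forests with a Mahalanobis split criterion.

The model jointly predicts a vector of k bounded outcomes (here: five
poverty/malnutrition prevalence rates per survey cluster).  Each tree is a
standard binary regression tree except that the node cost is the sum of
precision-weighted squared deviations from the leaf mean,

    C_L = sum_i (y_i - ybar_L)' Lambda (y_i - ybar_L),

where ``Lambda`` is the precision matrix (inverse residual covariance) of
the outcomes.  With ``Lambda = I`` this reduces to the usual pooled-variance
criterion; with an FGLS-estimated ``Lambda`` the split search operates on
decorrelated outcomes, letting correlated outcomes share splits.

Leaf predictions are componentwise means of the resident outcome vectors,
and the forest prediction is the componentwise average over trees; the
across-tree standard deviation serves as a per-prediction uncertainty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, MultiOutputMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "MahalanobisForestRegressor",
    "IndependentForestRegressor",
    "mahalanobis_cost",
    "best_split",
    "estimate_precision",
    "precision_from_residuals",
]

_MAX_SEED = 2**31 - 1


# ---------------------------------------------------------------------------
# Precision-matrix helpers


def _check_precision(precision: np.ndarray) -> np.ndarray:
    """Validate that ``precision`` is a symmetric positive-definite matrix."""
    lam = np.asarray(precision, dtype=float)
    if lam.ndim == 0:
        lam = lam.reshape(1, 1)
    if lam.ndim != 2 or lam.shape[0] != lam.shape[1]:
        raise ValueError(f"precision matrix must be square, got shape {lam.shape}")
    if not np.allclose(lam, lam.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(lam)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc
    return lam


def _whitener(precision: np.ndarray) -> np.ndarray:
    """Return W with W'W = Lambda so that d'Λd = ||W d||² for deviations d.

    Splitting on W-whitened outcomes with the plain variance criterion is
    then exactly the Mahalanobis criterion.
    """
    chol = np.linalg.cholesky(precision)  # Lambda = L L'
    return chol.T


def mahalanobis_cost(Y: np.ndarray, precision: np.ndarray) -> float:
    """Node cost: sum of squared Mahalanobis deviations from the mean.

    Parameters
    ----------
    Y : ndarray of shape (n, k)
        Outcome vectors resident in the node.
    precision : ndarray of shape (k, k)
        Symmetric positive-definite precision matrix Λ.

    Returns
    -------
    float
        ``sum_i (y_i - ybar)' Λ (y_i - ybar)``; zero iff all rows identical.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ValueError("Y must be a non-empty (n, k) array")
    lam = _check_precision(precision)
    if lam.shape[0] != Y.shape[1]:
        raise ValueError("precision dimension does not match outcome dimension")
    dev = Y - Y.mean(axis=0)
    return float(np.einsum("ij,jk,ik->", dev, lam, dev))


def precision_from_residuals(
    residuals: np.ndarray,
    ridge: float = 1e-6,
    max_condition: float = 1e8,
) -> tuple[np.ndarray, str]:
    """Invert the sample covariance of residual vectors, regularizing if needed.

    The ridge term ``delta * mean(diag(Sigma))`` is added to the diagonal,
    with ``delta`` doubled until the condition number falls below
    ``max_condition``.  All-zero residuals fall back to the identity.

    Returns ``(Lambda, provenance)`` with provenance in
    ``{"estimated", "identity"}``.
    """
    resid = np.atleast_2d(np.asarray(residuals, dtype=float))
    n, k = resid.shape
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} residual rows, got {n}")
    sigma = np.cov(resid, rowvar=False, ddof=1).reshape(k, k)
    mean_diag = float(np.mean(np.diag(sigma)))
    if not np.isfinite(mean_diag) or mean_diag <= 0.0:
        warnings.warn(
            "residuals are all zero (perfect in-sample fit); "
            "falling back to an identity precision matrix",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.eye(k), "identity"
    delta = ridge
    sigma_reg = sigma
    while np.linalg.cond(sigma_reg) >= max_condition:
        sigma_reg = sigma + delta * mean_diag * np.eye(k)
        delta *= 2.0
    lam = np.linalg.inv(sigma_reg)
    lam = 0.5 * (lam + lam.T)
    return lam, "estimated"


def estimate_precision(
    X: np.ndarray,
    Y: np.ndarray,
    n_estimators: int = 2000,
    max_depth: int = 4,
    max_features: float = 1.0 / 3.0,
    bootstrap: bool = True,
    min_samples_leaf: int = 2,
    random_state: Optional[int] = None,
) -> tuple[np.ndarray, str]:
    """FGLS-style precision estimate from univariate-forest training residuals.

    Fits one univariate variance-criterion forest per outcome (same
    hyperparameters as the joint model), collects training residuals
    ``y - yhat``, and inverts their sample covariance (with a small ridge if
    ill-conditioned).  Analogous to feasible generalized least squares: the
    first-stage fits are consistent under independence, and their residual
    covariance estimates the outcome-noise covariance Σ whose inverse Λ then
    drives the joint split criterion.

    Returns ``(Lambda, provenance)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] > 1:
        Y = Y.T
    n, k = Y.shape
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} training rows, got {n}")
    rng = np.random.default_rng(random_state)
    resid = np.empty_like(Y)
    for j in range(k):
        sub_seed = int(rng.integers(0, _MAX_SEED))
        uf = MahalanobisForestRegressor(
            n_estimators=n_estimators,
            max_depth=max_depth,
            max_features=max_features,
            bootstrap=bootstrap,
            min_samples_leaf=min_samples_leaf,
            precision="identity",
            random_state=sub_seed,
        )
        uf.fit(X, Y[:, [j]])
        resid[:, j] = Y[:, j] - uf.predict(X)[:, 0]
    return precision_from_residuals(resid)


# ---------------------------------------------------------------------------
# Split search


def _node_cost_whitened(Z: np.ndarray) -> float:
    """SSE of whitened outcomes about their mean (== Mahalanobis cost)."""
    total = Z.sum(axis=0)
    return float((Z * Z).sum() - (total * total).sum() / Z.shape[0])


def _best_split_whitened(
    X: np.ndarray,
    Z: np.ndarray,
    features: np.ndarray,
    min_samples_leaf: int,
) -> Optional[tuple[int, float, float]]:
    """Exact best (feature, threshold) minimizing summed child cost.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values.  Ties are broken by lowest feature index, then lowest threshold
    (guaranteed by row-major argmin over an ascending feature x ascending
    threshold cost grid).  Returns ``(feature, threshold, total_child_cost)``
    or ``None`` when no candidate strictly reduces the parent cost.
    """
    n = X.shape[0]
    if n < 2 * min_samples_leaf:
        return None
    parent_cost = _node_cost_whitened(Z)
    Xf = X[:, features]  # (n, m)
    order = np.argsort(Xf, axis=0, kind="stable")  # per-feature sort
    xs = np.take_along_axis(Xf, order, axis=0)  # (n, m) sorted values
    # Z gathered per feature ordering: (n, m, k)
    Zs = Z[order, :]
    csum = np.cumsum(Zs, axis=0)  # (n, m, k)
    csq = np.cumsum((Zs * Zs).sum(axis=2), axis=0)  # (n, m)
    tot_sum = csum[-1]  # (m, k)
    tot_sq = csq[-1]  # (m,)

    nl = np.arange(1, n, dtype=float)[:, None]  # (n-1, 1)
    nr = n - nl
    sum_l = csum[:-1]  # (n-1, m, k)
    sq_l = csq[:-1]  # (n-1, m)
    cost_l = sq_l - (sum_l * sum_l).sum(axis=2) / nl
    diff = tot_sum[None, :, :] - sum_l
    cost_r = (tot_sq[None, :] - sq_l) - (diff * diff).sum(axis=2) / nr
    total = cost_l + cost_r  # (n-1, m)

    valid = xs[1:] > xs[:-1]
    if min_samples_leaf > 1:
        pos_ok = (nl >= min_samples_leaf) & (nr >= min_samples_leaf)
        valid = valid & pos_ok
    total = np.where(valid, total, np.inf)

    # row-major over (feature, threshold) so the first minimum honours the
    # tie-break (lowest feature index, then lowest threshold); costs within
    # a tiny relative tolerance of the minimum count as tied so that
    # floating-point noise in the prefix-sum formula cannot flip exact ties
    flat = total.T.reshape(-1)
    m = flat.min()
    if not np.isfinite(m):
        return None
    tol = 1e-10 * max(1.0, abs(m))
    j = int(np.argmax(flat <= m + tol))
    best_cost = flat[j]
    if not best_cost < parent_cost - tol:
        return None
    fi, pos = divmod(j, n - 1)
    threshold = 0.5 * (xs[pos, fi] + xs[pos + 1, fi])
    return int(features[fi]), float(threshold), float(best_cost)


def best_split(
    X: np.ndarray,
    Y: np.ndarray,
    precision: Union[np.ndarray, float],
    candidate_features: Optional[Sequence[int]] = None,
    min_samples_leaf: int = 1,
) -> Optional[tuple[int, float]]:
    """Best axis-aligned split of (X, Y) under the Mahalanobis cost.

    Minimizes left + right child cost over all candidate features and
    midpoints between consecutive distinct sorted values.  Returns
    ``(feature_index, threshold)`` or ``None`` when no split strictly
    reduces the cost or children would violate ``min_samples_leaf``.
    Ties break to the lowest feature index, then the lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    lam = _check_precision(np.asarray(precision, dtype=float))
    Z = Y @ _whitener(lam).T
    if candidate_features is None:
        features = np.arange(X.shape[1])
    else:
        features = np.sort(np.asarray(candidate_features, dtype=int))
    res = _best_split_whitened(X, Z, features, min_samples_leaf)
    if res is None:
        return None
    return res[0], res[1]


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    """One node of a regression tree.

    Leaf payload is the componentwise mean outcome vector and member count;
    internal nodes additionally carry the split and the node cost used for
    impurity-decrease (MDI) bookkeeping.
    """

    value: np.ndarray
    n_samples: int
    cost: float
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {
            "value": self.value.tolist(),
            "n_samples": int(self.n_samples),
            "cost": float(self.cost),
        }
        if not self.is_leaf:
            d["feature"] = int(self.feature)
            d["threshold"] = float(self.threshold)
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            value=np.asarray(d["value"], dtype=float),
            n_samples=int(d["n_samples"]),
            cost=float(d["cost"]),
        )
        if "feature" in d:
            node.feature = int(d["feature"])
            node.threshold = float(d["threshold"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class _Tree:
    root: TreeNode
    sample_indices: np.ndarray = field(repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        k = self.root.value.shape[0]
        out = np.empty((n, k))
        stack = [(self.root, np.arange(n))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if node.is_leaf:
                out[idx] = node.value
            else:
                go_left = X[idx, node.feature] <= node.threshold
                stack.append((node.left, idx[go_left]))
                stack.append((node.right, idx[~go_left]))
        return out


def _grow_tree(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    max_depth: int,
    mtry: int,
    min_samples_leaf: int,
    rng: np.random.Generator,
    bootstrap: bool,
) -> _Tree:
    n, p = X.shape
    if bootstrap:
        sample = rng.integers(0, n, size=n)
    else:
        sample = np.arange(n)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(
            value=Y[idx].mean(axis=0),
            n_samples=idx.size,
            cost=_node_cost_whitened(Z[idx]),
        )
        if depth >= max_depth or idx.size < 2 * min_samples_leaf:
            return node
        if mtry >= p:
            features = np.arange(p)
        else:
            features = np.sort(rng.choice(p, size=mtry, replace=False))
        res = _best_split_whitened(X[idx], Z[idx], features, min_samples_leaf)
        if res is None:
            return node
        f, thr, _ = res
        go_left = X[idx, f] <= thr
        node.feature = f
        node.threshold = thr
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    return _Tree(root=build(sample, 0), sample_indices=sample)


def _tree_importances(tree: _Tree, p: int) -> np.ndarray:
    """Per-feature impurity decrease of one tree.

    Each split on feature x contributes (fraction of the tree's training
    samples reaching the node) x (per-sample normalized cost decrease):
    ``(n_node / N) * (cost_node - cost_left - cost_right) / n_node``.
    """
    imp = np.zeros(p)
    n_total = tree.root.n_samples
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        decrease = node.cost - node.left.cost - node.right.cost
        imp[node.feature] += decrease / n_total
        stack.append(node.left)
        stack.append(node.right)
    return imp


# ---------------------------------------------------------------------------
# Estimators


class MahalanobisForestRegressor(MultiOutputMixin, RegressorMixin, BaseEstimator):
    """Multivariate random forest with a Mahalanobis split criterion.

    Parameters
    ----------
    n_estimators : int, default=2000
        Number of trees T.
    max_depth : int, default=4
        Maximum tree depth d (0 yields single-leaf stumps).
    max_features : float, default=1/3
        Feature downsampling rate dsr: the fraction of features drawn
        (without replacement) as split candidates at each node; at least one
        feature is always drawn.
    bootstrap : bool, default=True
        Grow each tree on its own bootstrap resample of the training rows.
    min_samples_leaf : int, default=2
        Minimum rows per child; splits producing smaller children are
        forbidden.
    precision : {"fgls", "identity"} or array-like of shape (k, k), default="fgls"
        Precision matrix Λ of the split cost.  ``"fgls"`` estimates Λ from
        the residual covariance of per-outcome univariate forests fitted
        with the same hyperparameters; ``"identity"`` uses Λ = I (pooled
        variance criterion); an explicit SPD matrix is used as given.
    random_state : int or None
        Seed controlling bootstrap resampling, per-node feature
        subsampling, and the FGLS stage.

    Attributes
    ----------
    precision_ : ndarray of shape (k, k)
        The precision matrix used for splitting.
    precision_source_ : str
        One of ``"identity"``, ``"estimated"``, ``"given"``.
    estimators_ : list of trees
        The fitted ensemble (with per-tree training-sample bookkeeping).
    feature_importances_ : ndarray of shape (p,)
        Mean decrease in impurity per feature (unnormalized).
    n_features_in_, n_outputs_ : int
    """

    def __init__(
        self,
        n_estimators: int = 2000,
        max_depth: int = 4,
        max_features: float = 1.0 / 3.0,
        bootstrap: bool = True,
        min_samples_leaf: int = 2,
        precision: Union[str, np.ndarray] = "fgls",
        random_state: Optional[int] = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.min_samples_leaf = min_samples_leaf
        self.precision = precision
        self.random_state = random_state

    def _validate_params_(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if not (0.0 < self.max_features <= 1.0):
            raise ValueError("max_features (dsr) must lie in (0, 1]")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")

    def fit(self, X, Y):
        """Fit the forest to features X (n, p) and outcomes Y (n, k)."""
        self._validate_params_()
        X = check_array(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y row counts differ")
        if not np.isfinite(Y).all():
            raise ValueError("Y contains non-finite values; filter missing rows first")
        n, p = X.shape
        k = Y.shape[1]
        rng = np.random.default_rng(self.random_state)
        fgls_seed = int(rng.integers(0, _MAX_SEED))

        if isinstance(self.precision, str):
            if self.precision == "identity":
                lam, source = np.eye(k), "identity"
            elif self.precision == "fgls":
                if n >= k + 2:
                    lam, source = estimate_precision(
                        X,
                        Y,
                        n_estimators=self.n_estimators,
                        max_depth=self.max_depth,
                        max_features=self.max_features,
                        bootstrap=self.bootstrap,
                        min_samples_leaf=self.min_samples_leaf,
                        random_state=fgls_seed,
                    )
                else:
                    warnings.warn(
                        "too few rows for FGLS precision estimation; using identity",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    lam, source = np.eye(k), "identity"
            else:
                raise ValueError(f"unknown precision option {self.precision!r}")
        else:
            lam = _check_precision(self.precision)
            if lam.shape[0] != k:
                raise ValueError("precision dimension does not match outcomes")
            source = "given"

        Z = Y @ _whitener(lam).T
        mtry = max(1, int(self.max_features * p))
        bootstrap = self.bootstrap and n > 1
        self.estimators_ = [
            _grow_tree(
                X, Y, Z, self.max_depth, mtry, self.min_samples_leaf, rng, bootstrap
            )
            for _ in range(self.n_estimators)
        ]
        self.precision_ = lam
        self.precision_source_ = source
        self.n_features_in_ = p
        self.n_outputs_ = k
        return self

    def _tree_predictions(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was trained on "
                f"{self.n_features_in_}"
            )
        return np.stack([t.predict(X) for t in self.estimators_])  # (T, n, k)

    def predict(self, X, return_std: bool = False):
        """Componentwise mean over trees; optionally the across-tree std."""
        per_tree = self._tree_predictions(X)
        mean = per_tree.mean(axis=0)
        if return_std:
            return mean, per_tree.std(axis=0, ddof=0)
        return mean

    @property
    def feature_importances_(self) -> np.ndarray:
        """Mean decrease in impurity: forest-averaged per-feature sums of
        (fraction of samples split on the feature) x (normalized cost
        decrease). Features never split on get 0."""
        check_is_fitted(self, "estimators_")
        per_tree = np.stack(
            [_tree_importances(t, self.n_features_in_) for t in self.estimators_]
        )
        return per_tree.mean(axis=0)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """Versioned plain-dict form of the fitted model (JSON-safe)."""
        check_is_fitted(self, "estimators_")
        return {
            "format": "mahaforest-model",
            "version": 1,
            "params": self.get_params(),
            "precision": self.precision_.tolist(),
            "precision_source": self.precision_source_,
            "n_features_in": self.n_features_in_,
            "n_outputs": self.n_outputs_,
            "trees": [
                {
                    "root": t.root.to_dict(),
                    "sample_indices": t.sample_indices.tolist(),
                }
                for t in self.estimators_
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MahalanobisForestRegressor":
        if d.get("format") != "mahaforest-model":
            raise ValueError("not a mahaforest model dict")
        params = dict(d["params"])
        if isinstance(params.get("precision"), list):
            params["precision"] = np.asarray(params["precision"])
        model = cls(**params)
        model.precision_ = np.asarray(d["precision"], dtype=float)
        model.precision_source_ = d["precision_source"]
        model.n_features_in_ = int(d["n_features_in"])
        model.n_outputs_ = int(d["n_outputs"])
        model.estimators_ = [
            _Tree(
                root=TreeNode.from_dict(t["root"]),
                sample_indices=np.asarray(t["sample_indices"], dtype=int),
            )
            for t in d["trees"]
        ]
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "MahalanobisForestRegressor":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


class IndependentForestRegressor(MultiOutputMixin, RegressorMixin, BaseEstimator):
    """Baseline: one univariate variance-criterion forest per outcome.

    Shares hyperparameters and the API of :class:`MahalanobisForestRegressor`
    but fits the k outcomes independently (the IRF baseline the joint model
    is compared against).
    """

    def __init__(
        self,
        n_estimators: int = 2000,
        max_depth: int = 4,
        max_features: float = 1.0 / 3.0,
        bootstrap: bool = True,
        min_samples_leaf: int = 2,
        random_state: Optional[int] = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, Y):
        X = check_array(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for j in range(Y.shape[1]):
            sub_seed = int(rng.integers(0, _MAX_SEED))
            uf = MahalanobisForestRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                max_features=self.max_features,
                bootstrap=self.bootstrap,
                min_samples_leaf=self.min_samples_leaf,
                precision="identity",
                random_state=sub_seed,
            )
            uf.fit(X, Y[:, [j]])
            self.estimators_.append(uf)
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = Y.shape[1]
        return self

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "estimators_")
        means, stds = [], []
        for uf in self.estimators_:
            if return_std:
                m, s = uf.predict(X, return_std=True)
                stds.append(s[:, 0])
            else:
                m = uf.predict(X)
            means.append(m[:, 0])
        mean = np.column_stack(means)
        if return_std:
            return mean, np.column_stack(stds)
        return mean

    @property
    def feature_importances_(self) -> np.ndarray:
        """Per-feature MDI averaged over the per-outcome forests."""
        check_is_fitted(self, "estimators_")
        return np.mean([uf.feature_importances_ for uf in self.estimators_], axis=0)
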