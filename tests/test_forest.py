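"""Unit and property tests for the multivariate forest core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mahaforest.forest import (
    IndependentForestRegressor,
    MahalanobisForestRegressor,
    best_split,
    estimate_precision,
    mahalanobis_cost,
    precision_from_residuals,
)

from _oracles import (
    VarianceTree,
    assert_same_structure,
    brute_force_best_split,
    with_exact_sample_cov,
)

# ---------------------------------------------------------------------------
# Mahalanobis cost


def test_cost_zero_for_identical_members(rng):
    Y = np.tile(rng.normal(size=3), (6, 1))
    lam = np.eye(3) * 2.0
    assert mahalanobis_cost(Y, lam) == pytest.approx(0.0, abs=1e-12)


def test_cost_univariate_example():
    # deviations +-1 around mean 2, precision 2 -> 2*1 + 2*1 = 4
    assert mahalanobis_cost(np.array([[1.0], [3.0]]), [[2.0]]) == pytest.approx(4.0)


def test_cost_identity_reduces_to_sse_sum():
    Y = np.array([[1.0, 0.0], [3.0, 2.0]])
    assert mahalanobis_cost(Y, np.eye(2)) == pytest.approx(4.0)


def test_cost_rejects_non_pd():
    with pytest.raises(ValueError):
        mahalanobis_cost(np.ones((3, 2)), np.array([[1.0, 2.0], [2.0, 1.0]]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_cost_equals_whitened_sse(seed):
    """Decorrelation identity: d'Λd sums equal the plain SSE of outcomes
    whitened by W with W'W = Λ."""
    r = np.random.default_rng(seed)
    n, k = int(r.integers(2, 20)), int(r.integers(1, 5))
    Y = r.normal(size=(n, k))
    A = r.normal(size=(k, k))
    lam = A @ A.T + np.eye(k) * 0.5
    W = np.linalg.cholesky(lam).T
    Z = Y @ W.T
    sse = float(((Z - Z.mean(axis=0)) ** 2).sum())
    assert mahalanobis_cost(Y, lam) == pytest.approx(sse, abs=1e-10, rel=1e-10)


# ---------------------------------------------------------------------------
# best split


def test_best_split_simple_step():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    Y = np.array([0.0, 0.0, 1.0, 1.0])
    assert best_split(X, Y, [[1.0]]) == (0, 2.5)


def test_best_split_no_gain_on_constant_outcomes():
    X = np.arange(6.0)[:, None]
    Y = np.ones((6, 2))
    assert best_split(X, Y, np.eye(2)) is None


def test_best_split_respects_min_leaf():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    Y = np.array([0.0, 10.0, 10.0, 10.0])
    # best unconstrained split isolates the first row; min_leaf=2 forbids it
    s = best_split(X, Y, [[1.0]], min_samples_leaf=2)
    assert s == (0, 1.5)


@pytest.mark.parametrize("seed", range(40))
def test_best_split_matches_brute_force(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 31))
    p = int(r.integers(1, 6))
    k = int(r.integers(1, 4))
    X = r.normal(size=(n, p))
    Y = r.normal(size=(n, k))
    A = r.normal(size=(k, k))
    lam = A @ A.T + np.eye(k)
    got = best_split(X, Y, lam)
    want = brute_force_best_split(X, Y, lam)
    assert got == want or (
        got is not None
        and want is not None
        and got[0] == want[0]
        and got[1] == pytest.approx(want[1])
    )


# ---------------------------------------------------------------------------
# forest fitting and prediction


def test_depth_zero_forest_predicts_training_mean(rng):
    X = rng.normal(size=(30, 3))
    Y = rng.uniform(size=(30, 2))
    m = MahalanobisForestRegressor(
        n_estimators=5, max_depth=0, bootstrap=False, precision="identity",
        random_state=0,
    ).fit(X, Y)
    pred = m.predict(X[:4])
    assert np.allclose(pred, Y.mean(axis=0))


def test_single_training_row_predicts_that_row(rng):
    X = np.array([[1.0, 2.0]])
    Y = np.array([[0.3, 0.7]])
    m = MahalanobisForestRegressor(
        n_estimators=3, precision="identity", random_state=0
    ).fit(X, Y)
    assert np.allclose(m.predict(np.array([[9.0, -9.0]])), Y)


def test_single_tree_std_is_zero(rng):
    X = rng.normal(size=(20, 2))
    Y = rng.uniform(size=(20, 2))
    m = MahalanobisForestRegressor(
        n_estimators=1, precision="identity", random_state=0
    ).fit(X, Y)
    _, sd = m.predict(X, return_std=True)
    assert np.all(sd == 0.0)


def test_predictions_are_convex_combinations(rng):
    X = rng.normal(size=(50, 4))
    Y = rng.uniform(size=(50, 3))
    m = MahalanobisForestRegressor(
        n_estimators=20, precision="identity", random_state=1
    ).fit(X, Y)
    pred = m.predict(rng.normal(size=(30, 4)))
    assert pred.min() >= Y.min() - 1e-12 and pred.max() <= Y.max() + 1e-12


def test_fit_is_deterministic_given_seed(rng):
    X = rng.normal(size=(40, 5))
    Y = rng.uniform(size=(40, 2))
    p1 = MahalanobisForestRegressor(
        n_estimators=10, precision="identity", random_state=7
    ).fit(X, Y).predict(X)
    p2 = MahalanobisForestRegressor(
        n_estimators=10, precision="identity", random_state=7
    ).fit(X, Y).predict(X)
    assert np.array_equal(p1, p2)


def test_predict_rejects_wrong_feature_count(rng):
    X = rng.normal(size=(20, 3))
    Y = rng.uniform(size=(20, 2))
    m = MahalanobisForestRegressor(
        n_estimators=2, precision="identity", random_state=0
    ).fit(X, Y)
    with pytest.raises(ValueError):
        m.predict(rng.normal(size=(4, 2)))


@pytest.mark.parametrize("scale", [1.0, 0.037, 450.0])
def test_univariate_reduction_matches_variance_forest(scale):
    """With k=1 the joint forest is split-for-split identical to a plain
    variance-criterion univariate forest for any scalar precision, checked
    against an independently coded CART on the same bootstrap samples."""
    r = np.random.default_rng(99)
    for _ in range(25):
        n = int(r.integers(10, 40))
        p = int(r.integers(1, 5))
        X = r.normal(size=(n, p))
        y = r.normal(size=n)
        m = MahalanobisForestRegressor(
            n_estimators=2,
            max_depth=3,
            max_features=1.0,
            min_samples_leaf=1,
            precision=np.array([[scale]]),
            random_state=int(r.integers(0, 1000)),
        ).fit(X, y)
        for tree in m.estimators_:
            idx = tree.sample_indices
            ref = VarianceTree(max_depth=3, min_leaf=1).fit(X[idx], y[idx])
            assert_same_structure(tree.root, ref.root)


def test_total_leaf_cost_monotone_in_depth(rng):
    X = rng.normal(size=(80, 4))
    Y = rng.uniform(size=(80, 3))
    lam = np.eye(3)

    def total_leaf_cost(model):
        tot = 0.0
        stack = [t.root for t in model.estimators_]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                tot += node.cost
            else:
                stack.extend([node.left, node.right])
        return tot

    costs = []
    for d in range(5):
        m = MahalanobisForestRegressor(
            n_estimators=1, max_depth=d, max_features=1.0, bootstrap=False,
            precision=lam, random_state=0,
        ).fit(X, Y)
        costs.append(total_leaf_cost(m))
    assert all(b <= a + 1e-9 for a, b in zip(costs, costs[1:]))


def test_univariate_accuracy_comparable_to_sklearn(rng):
    """Cross-check against an established implementation: on a univariate
    problem our forest should be close to sklearn's RandomForestRegressor."""
    from sklearn.ensemble import RandomForestRegressor

    X = rng.normal(size=(400, 6))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.1 * rng.normal(size=400)
    Xt = rng.normal(size=(200, 6))
    yt = np.sin(Xt[:, 0]) + 0.5 * Xt[:, 1] ** 2

    ours = MahalanobisForestRegressor(
        n_estimators=100, max_depth=8, max_features=1 / 3, precision="identity",
        min_samples_leaf=2, random_state=0,
    ).fit(X, y).predict(Xt)[:, 0]
    theirs = RandomForestRegressor(
        n_estimators=100, max_depth=8, max_features=1 / 3, random_state=0
    ).fit(X, y).predict(Xt)

    def r2(a):
        return 1 - ((yt - a) ** 2).sum() / ((yt - yt.mean()) ** 2).sum()

    assert r2(ours) > r2(theirs) - 0.1


# ---------------------------------------------------------------------------
# precision estimation


def test_precision_recovers_diagonal_inverse(rng):
    target = np.diag([4.0, 0.25])
    resid = with_exact_sample_cov(rng, 50, target)
    lam, src = precision_from_residuals(resid)
    assert src == "estimated"
    assert np.allclose(lam, np.diag([0.25, 4.0]), atol=1e-8)


def test_precision_recovers_correlated_2x2_inverse(rng):
    rho = 0.6
    target = np.array([[1.0, rho], [rho, 1.0]])
    resid = with_exact_sample_cov(rng, 50, target)
    lam, _ = precision_from_residuals(resid)
    want = np.array([[1.0, -rho], [-rho, 1.0]]) / (1 - rho**2)
    assert np.allclose(lam, want, atol=1e-8)


def test_precision_zero_residuals_falls_back_with_warning():
    with pytest.warns(RuntimeWarning):
        lam, src = precision_from_residuals(np.zeros((10, 3)))
    assert src == "identity"
    assert np.array_equal(lam, np.eye(3))


def test_precision_regularizes_collinear_residuals(rng):
    base = rng.normal(size=50)
    resid = np.column_stack([base, base])  # singular covariance
    lam, src = precision_from_residuals(resid)
    assert src == "estimated"
    assert np.all(np.linalg.eigvalsh(lam) > 0)


def test_estimate_precision_zero_residuals_on_constant_outcomes(rng):
    X = rng.normal(size=(30, 3))
    Y = np.tile([0.4, 0.6], (30, 1))
    with pytest.warns(RuntimeWarning):
        lam, src = estimate_precision(X, Y, n_estimators=5, random_state=0)
    assert src == "identity"


def test_estimate_precision_roughly_recovers_noise_covariance(rng):
    # pure-noise outcomes: training residuals approximate the noise draws
    X = rng.normal(size=(600, 4))
    cov = np.array([[1.0, 0.6], [0.6, 1.0]])
    Y = rng.multivariate_normal([0, 0], cov, size=600)
    lam, _ = estimate_precision(
        X, Y, n_estimators=30, max_depth=4, random_state=0
    )
    sigma = np.linalg.inv(lam)
    # residuals shrink noise somewhat (in-sample fit), but correlation survives
    corr = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
    assert corr == pytest.approx(0.6, abs=0.15)


# ---------------------------------------------------------------------------
# MDI importance


def test_mdi_zero_for_unused_feature(rng):
    X = np.column_stack([np.arange(20.0), np.zeros(20)])
    y = (np.arange(20) >= 10).astype(float)
    m = MahalanobisForestRegressor(
        n_estimators=5, max_features=1.0, precision="identity", random_state=0
    ).fit(X, y)
    assert m.feature_importances_[1] == 0.0


def test_mdi_single_root_split_equals_normalized_decrease():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    m = MahalanobisForestRegressor(
        n_estimators=1, max_depth=1, bootstrap=False, max_features=1.0,
        min_samples_leaf=1, precision=np.array([[1.0]]), random_state=0,
    ).fit(X, y)
    # parent SSE = 1.0 over 4 samples, children pure: MDI = (1.0 - 0)/4
    assert m.feature_importances_[0] == pytest.approx(0.25)


def test_mdi_identical_trees_average_to_single_tree_value():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    kw = dict(max_depth=1, bootstrap=False, max_features=1.0,
              min_samples_leaf=1, precision=np.array([[1.0]]))
    one = MahalanobisForestRegressor(n_estimators=1, random_state=0, **kw).fit(X, y)
    many = MahalanobisForestRegressor(n_estimators=7, random_state=0, **kw).fit(X, y)
    assert np.allclose(one.feature_importances_, many.feature_importances_)


# ---------------------------------------------------------------------------
# independent baseline and serialization


def test_independent_forest_matches_manual_per_outcome_fits(rng):
    X = rng.normal(size=(60, 4))
    Y = rng.uniform(size=(60, 2))
    m = IndependentForestRegressor(n_estimators=10, random_state=3).fit(X, Y)
    pred, sd = m.predict(X[:5], return_std=True)
    assert pred.shape == (5, 2) and sd.shape == (5, 2)
    assert np.all(sd >= 0)


def test_model_roundtrip_through_serialization(tmp_path, rng):
    X = rng.normal(size=(40, 3))
    Y = rng.uniform(size=(40, 2))
    m = MahalanobisForestRegressor(
        n_estimators=4, precision="identity", random_state=5
    ).fit(X, Y)
    path = tmp_path / "model.json"
    m.save(path)
    m2 = MahalanobisForestRegressor.load(path)
    assert np.array_equal(m.predict(X), m2.predict(X))
    assert np.array_equal(m.precision_, m2.precision_)
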