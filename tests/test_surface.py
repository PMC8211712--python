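import math

import numpy as np
import pandas as pd
import pytest

from karstrad.simulate import sim_conditioned_tree, sim_regime_traits
from karstrad.surface import (
    SurfaceModel,
    hansen_loglik,
    painting_from_shifts,
)


@pytest.fixture(scope="module")
def tree():
    return sim_conditioned_tree(48, 20.0, lambda1=0.25, seed=21)


def _single_regime_painting(tree):
    return {nd.index: 0 for nd, _, _ in tree.edges()}


def _two_clade_setup(tree, same_optimum=True):
    nodes = [
        nd for nd in tree.nodes("postorder")
        if not nd.is_leaf() and nd.parent_node is not None
    ]
    cands = [nd for nd in nodes if 7 <= len(tree.tipset(nd)) <= 14]
    c1 = cands[0]
    c2 = next(nd for nd in cands if not (tree.tipset(nd) & tree.tipset(c1)))
    shifts = {c1.index: 1, c2.index: 2}
    painting = painting_from_shifts(tree, shifts, 0)
    th = [4.0, -4.0]
    optima = {0: [0.0, 0.0], 1: th, 2: th if same_optimum else [-4.0, 4.0]}
    return shifts, painting, optima


def test_single_regime_equals_plain_ou_likelihood(tree):
    """With one regime the Hansen likelihood collapses to single-optimum OU."""
    paint = _single_regime_painting(tree)
    X, _ = sim_regime_traits(tree, paint, {0: [1.0, -1.0]}, alpha=0.6, sigma2=0.2,
                             root_regime=0, seed=22)
    optima = pd.DataFrame([[1.0, -1.0]], index=[0], columns=X.columns)
    ll = hansen_loglik(tree, X, paint, alpha=[0.6, 0.6], sigma2=[0.2, 0.2],
                       optima=optima, root_regime=0)
    # direct single-optimum OU Gaussian density
    tips = tree.tip_labels
    _, C = tree.vcv(tips)
    T = tree.crown_age
    a = 0.6
    V = 0.2 * np.exp(-2 * a * (T - C)) * (1 - np.exp(-2 * a * C)) / (2 * a)
    ll2 = 0.0
    for j, col in enumerate(X.columns):
        y = X[col][tips].to_numpy() - [1.0, -1.0][j]
        L = np.linalg.cholesky(V + np.eye(len(tips)) * 1e-12)
        r = np.linalg.solve(L, y)
        ll2 += -0.5 * (r @ r + 2 * np.sum(np.log(np.diag(L)))
                       + len(tips) * math.log(2 * math.pi))
    assert ll == pytest.approx(ll2, abs=1e-8)


def test_hansen_matches_path_integral_oracle():
    """Expectations and covariance assembled by numerical quadrature along
    root-to-tip paths reproduce the analytic Hansen likelihood."""
    from karstrad.tree import TimeTree

    t = TimeTree.from_newick("((A:4,B:4):6,(C:8,D:8):2);")
    shifts = {}
    for nd in t.nodes("postorder"):
        if nd.is_leaf() and nd.taxon.label == "A":
            shifts[nd.index] = 1
    paint = painting_from_shifts(t, shifts, 0)
    alpha, sigma2 = 0.37, 0.5
    optima = pd.DataFrame({"x": [1.0, 6.0]}, index=[0, 1])
    X = pd.DataFrame({"x": [5.0, 1.2, 0.4, 2.0]}, index=["A", "B", "C", "D"])
    ll = hansen_loglik(t, X, paint, [alpha], [sigma2], optima, root_regime=0)

    # oracle: quadrature for E[y_i]; covariance by the integral
    # sigma2 * int_0^{shared} exp(-alpha*(t_i - u)) exp(-alpha*(t_j - u)) du
    T = t.crown_age
    tips = sorted(t.tip_labels)
    paths = {}
    for nd in t.nodes("preorder"):
        if nd.parent_node is None:
            nd.path = []
        else:
            nd.path = nd.parent_node.path + [(nd.parent_node.age_my, nd.age_my, nd.index)]
        if nd.is_leaf():
            paths[nd.taxon.label] = nd.path
    mu = {}
    for tip in tips:
        grid_w = math.exp(-alpha * T) * optima.loc[0, "x"]
        for a0, a1, b in paths[tip]:
            th = optima.loc[paint[b], "x"]
            u = np.linspace(a1, a0, 20001)
            grid_w += th * np.trapezoid(alpha * np.exp(-alpha * u), u)
        mu[tip] = grid_w
    _, C = t.vcv(tips)
    V = np.zeros((4, 4))
    for i, ti in enumerate(tips):
        for j, tj in enumerate(tips):
            s = C[i, j]
            u = np.linspace(0, s, 20001)
            # forward time from root: depth u, ages T-u
            integrand = np.exp(-2 * alpha * (T - u))
            V[i, j] = sigma2 * np.trapezoid(integrand, u)
    y = X["x"][tips].to_numpy() - np.array([mu[t_] for t_ in tips])
    L = np.linalg.cholesky(V + np.eye(4) * 1e-12)
    r = np.linalg.solve(L, y)
    ll_oracle = -0.5 * (r @ r + 2 * np.sum(np.log(np.diag(L))) + 4 * math.log(2 * math.pi))
    assert ll == pytest.approx(ll_oracle, abs=1e-6)


def test_large_alpha_expectation_approaches_tip_regime_optimum():
    from karstrad.tree import TimeTree

    t = TimeTree.from_newick("(A:5,B:5);")
    nd_a = next(lf for lf in t.leaves() if lf.taxon.label == "A")
    paint = painting_from_shifts(t, {nd_a.index: 1}, 0)
    X, _ = sim_regime_traits(t, paint, {0: [0.0], 1: [7.0]}, alpha=50.0,
                             sigma2=1e-6, root_regime=0, seed=23)
    assert X.loc["A", "trait1"] == pytest.approx(7.0, abs=0.01)
    assert X.loc["B", "trait1"] == pytest.approx(0.0, abs=0.01)


def test_invalid_alpha_rejected(tree):
    paint = _single_regime_painting(tree)
    optima = pd.DataFrame([[0.0, 0.0]], index=[0], columns=["a", "b"])
    X = pd.DataFrame(np.zeros((tree.n_tips, 2)), index=tree.tip_labels,
                     columns=["a", "b"])
    with pytest.raises(ValueError):
        hansen_loglik(tree, X, paint, [-1.0, 1.0], [1.0, 1.0], optima, 0)


def test_forward_monotone_and_partition_identity(tree):
    shifts, painting, optima = _two_clade_setup(tree)
    X, _ = sim_regime_traits(tree, painting, optima, alpha=0.8, sigma2=0.3,
                             root_regime=0, seed=24)
    res = SurfaceModel(tree, X).fit(max_shifts=6)
    aiccs = [f.aicc for f in res.forward_path]
    assert all(aiccs[i + 1] < aiccs[i] for i in range(len(aiccs) - 1))
    bwd = [f.aicc for f in res.backward_path]
    assert all(bwd[i + 1] <= bwd[i] for i in range(len(bwd) - 1))
    assert res.n_convergent + res.n_unique == res.n_regimes


def test_convergent_clades_merged(tree):
    shifts, painting, optima = _two_clade_setup(tree, same_optimum=True)
    X, _ = sim_regime_traits(tree, painting, optima, alpha=0.8, sigma2=0.3,
                             root_regime=0, seed=25)
    res = SurfaceModel(tree, X).fit(max_shifts=6)
    assert res.n_shifts >= 2
    assert res.n_convergent >= 1


def test_distinct_optima_not_merged(tree):
    shifts, painting, optima = _two_clade_setup(tree, same_optimum=False)
    X, _ = sim_regime_traits(tree, painting, optima, alpha=0.8, sigma2=0.3,
                             root_regime=0, seed=26)
    res = SurfaceModel(tree, X).fit(max_shifts=6)
    assert res.n_regimes >= 3
    assert res.n_unique >= 2
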