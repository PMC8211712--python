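import numpy as np
import pandas as pd
import pytest

from karstrad.simulate import TraitModel, sim_conditioned_tree, sim_traits
from karstrad.traitgeom import (
    contrasts,
    node_height_test,
    pgls_residuals,
    phylo_pca,
    ward_clusters,
)
from karstrad.tree import TimeTree


def star_tree(n, depth=1.0):
    nwk = "(" + ",".join(f"s{i}:{depth}" for i in range(n)) + ");"
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return TimeTree.from_newick(nwk)


class TestContrasts:
    def test_two_tip_hand_value(self):
        t = TimeTree.from_newick("(A:1,B:1);")
        pic = contrasts(t, pd.Series({"A": 3.0, "B": 1.0}))
        assert pic["contrast"].iloc[0] == pytest.approx((3 - 1) / np.sqrt(2), abs=1e-5)
        assert pic["contrast"].iloc[0] == pytest.approx(1.41421, abs=1e-5)

    def test_sum_sq_contrasts_equals_reml_bm_rate(self):
        """Mean squared standardized contrast is the REML BM rate."""
        tree = sim_conditioned_tree(40, 25.0, lambda1=0.15, seed=3)
        sigma2 = 0.07
        X, _ = sim_traits(tree, TraitModel(Sigma=np.eye(1) * sigma2), seed=4)
        pic = contrasts(tree, X["trait1"])
        # identity check: contrasts-based REML estimate equals the GLS REML
        tips = tree.tip_labels
        _, C = tree.vcv(tips)
        y = X["trait1"][tips].to_numpy()
        ones = np.ones(len(tips))
        a = (y @ np.linalg.solve(C, ones)) / (ones @ np.linalg.solve(C, ones))
        reml = ((y - a) @ np.linalg.solve(C, y - a)) / (len(tips) - 1)
        assert np.mean(pic["contrast"] ** 2) == pytest.approx(reml, rel=1e-8)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        t = star_tree(20)
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=20), index=t.tip_labels)
        y = 2 * x + pd.Series(rng.normal(size=20), index=t.tip_labels)
        res = pgls_residuals(t, y, x)
        X = np.column_stack([np.ones(20), x[t.tip_labels]])
        beta, *_ = np.linalg.lstsq(X, y[t.tip_labels], rcond=None)
        ols = y[t.tip_labels] - X @ beta
        assert np.allclose(res[t.tip_labels], ols, atol=1e-10)

    def test_exact_linear_relation_gives_zero_residuals(self, medium_tree):
        x = pd.Series(np.linspace(1, 5, 50), index=medium_tree.tip_labels)
        y = 2 * x
        res = pgls_residuals(medium_tree, y, x)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_intercept_absorbs_constant(self, medium_tree):
        rng = np.random.default_rng(6)
        x = pd.Series(rng.normal(size=50), index=medium_tree.tip_labels)
        y = pd.Series(rng.normal(size=50), index=medium_tree.tip_labels)
        r1 = pgls_residuals(medium_tree, y, x)
        r2 = pgls_residuals(medium_tree, y + 7.5, x)
        assert np.allclose(r1, r2, atol=1e-9)


class TestPhyloPCA:
    def test_star_tree_equals_ordinary_pca(self):
        t = star_tree(30)
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(30, 4)), index=t.tip_labels)
        res = phylo_pca(t, X)
        cov = np.cov(X.to_numpy().T, ddof=1)
        w = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, w, atol=1e-10)

    def test_duplicated_column_collapses_rank(self, medium_tree):
        rng = np.random.default_rng(8)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=50)},
                         index=medium_tree.tip_labels)
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = phylo_pca(medium_tree, X)
        assert len(res.eigenvalues) == 2

    def test_scores_have_zero_gls_mean(self, medium_tree):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(50, 3)), index=medium_tree.tip_labels)
        res = phylo_pca(medium_tree, X)
        tips = list(res.scores.index)
        _, C = medium_tree.vcv(tips)
        ones = np.ones(len(tips))
        Ci1 = np.linalg.solve(C, ones)
        gmean = res.scores.to_numpy().T @ Ci1 / (ones @ Ci1)
        assert np.allclose(gmean, 0.0, atol=1e-10)

    def test_cumulative_variance_monotone(self, medium_tree):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(50, 5)), index=medium_tree.tip_labels)
        res = phylo_pca(medium_tree, X)
        assert np.all(np.diff(res.cumulative_variance) >= -1e-12)
        assert res.cumulative_variance[-1] == pytest.approx(1.0)


class TestNodeHeightTest:
    def test_insufficient_contrasts_rejected(self):
        t = TimeTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            node_height_test(t, pd.Series({"A": 3.0, "B": 1.0}))

    def test_accelerating_rates_detected(self):
        """Smoke-level power check (the full error-rate calibration runs in
        the acceptance suite)."""
        tree = sim_conditioned_tree(50, 30.0, lambda1=0.15, seed=13)
        rng = np.random.default_rng(14)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            X, _ = sim_traits(
                tree, TraitModel(Sigma=np.eye(1) * 0.01, mode="EB", r=0.25), seed=rng
            )
            r = node_height_test(tree, X["trait1"])
            hits += (r.p_value < 0.05) and (r.slope > 0)
        assert hits / n_rep >= 0.7


class TestWard:
    def test_two_blob_recovery(self):
        rng = np.random.default_rng(15)
        A = rng.normal(0, 0.3, size=(15, 2))
        B = rng.normal(8, 0.3, size=(15, 2))
        names = [f"s{i:02d}" for i in range(30)]
        X = pd.DataFrame(np.vstack([A, B]), index=names)
        labels, _ = ward_clusters(X, k=2)
        la = set(labels[names[:15]])
        lb = set(labels[names[15:]])
        assert len(la) == 1 and len(lb) == 1 and la != lb

    def test_k_equals_n_gives_singletons(self):
        X = pd.DataFrame(np.random.default_rng(16).normal(size=(7, 2)),
                         index=[f"s{i}" for i in range(7)])
        labels, _ = ward_clusters(X, k=7)
        assert labels.nunique() == 7

    def test_k_too_large_rejected(self):
        X = pd.DataFrame(np.random.default_rng(17).normal(size=(5, 2)),
                         index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError):
            ward_clusters(X, k=6)

    def test_fixture_nine_morphotypes(self, bundle):
        labels, _ = ward_clusters(bundle.traits.dropna(), k=9)
        assert labels.nunique() == 9
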