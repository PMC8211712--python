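"""Phylogenetic size correction, phylogenetic PCA, the node height test
and Ward clustering of morphotypes.

These are the standard geometry steps that prepare a morphometric table
for the disparity and model-selection analyses: traits are regressed on
body size with GLS under Brownian covariance, the residual space is
summarised with a phylogenetically corrected PCA, rate heterogeneity
through time is screened with the node height test on independent
contrasts, and morphotype groups are delimited by Ward's hierarchical
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .tree import TimeTree

__all__ = [
    "contrasts",
    "pgls_residuals",
    "phylo_pca",
    "PPCAResult",
    "node_height_test",
    "NodeHeightResult",
    "ward_clusters",
]


# ----------------------------------------------------------------------
# independent contrasts
# ----------------------------------------------------------------------
def contrasts(tree: TimeTree, trait: pd.Series) -> pd.DataFrame:
    """Felsenstein's standardized independent contrasts.

    Returns one row per internal node with the contrast value and the
    node height (distance from the root, My).  The tree is pruned to the
    tips present in ``trait``.
    """
    trait = trait.dropna()
    tips = sorted(set(tree.tip_labels) & set(trait.index))
    if len(tips) < 2:
        raise ValueError("need >= 2 tips with data")
    t = tree.prune_to(tips) if len(tips) < tree.n_tips else tree
    x: Dict[int, float] = {}
    v: Dict[int, float] = {}
    rows = []
    for nd in t.nodes("postorder"):
        if nd.is_leaf():
            x[nd.index] = float(trait[nd.taxon.label])
            v[nd.index] = nd.edge_length or 0.0
        else:
            c1, c2 = nd.child_nodes()
            v1, v2 = v[c1.index], v[c2.index]
            pic = (x[c1.index] - x[c2.index]) / np.sqrt(v1 + v2)
            rows.append(
                {
                    "node_height": t.crown_age - nd.age_my,
                    "node_age": nd.age_my,
                    "contrast": pic,
                    "expected_sd": np.sqrt(v1 + v2),
                }
            )
            x[nd.index] = (x[c1.index] / v1 + x[c2.index] / v2) / (1 / v1 + 1 / v2) \
                if v1 > 0 and v2 > 0 else (x[c1.index] + x[c2.index]) / 2
            extra = (v1 * v2 / (v1 + v2)) if (v1 + v2) > 0 else 0.0
            v[nd.index] = (nd.edge_length or 0.0) + extra
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# PGLS size correction
# ----------------------------------------------------------------------
def _gls_fit(C: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    CiX = np.linalg.solve(C, X)
    XtCiX = X.T @ CiX
    if np.linalg.cond(XtCiX) > 1e12:
        raise np.linalg.LinAlgError("singular GLS design")
    return np.linalg.solve(XtCiX, CiX.T @ y)


def pgls_residuals(tree: TimeTree, y: pd.Series, x: pd.Series) -> pd.Series:
    """Residuals of GLS regression of ``y`` on ``x`` (intercept included)
    with Brownian covariance from the tree.

    Used for phylogenetic size correction: y = a trait, x = body length.
    """
    common = sorted(set(tree.tip_labels) & set(y.dropna().index) & set(x.dropna().index))
    if len(common) < 3:
        raise ValueError("need >= 3 shared species")
    t = tree.prune_to(common) if len(common) < tree.n_tips else tree
    _, C = t.vcv(common)
    X = np.column_stack([np.ones(len(common)), x[common].to_numpy(float)])
    yv = y[common].to_numpy(float)
    beta = _gls_fit(C, X, yv)
    return pd.Series(yv - X @ beta, index=common, name=y.name)


# ----------------------------------------------------------------------
# phylogenetic PCA
# ----------------------------------------------------------------------
@dataclass
class PPCAResult:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns = axes
    scores: pd.DataFrame  # species x axes
    cumulative_variance: np.ndarray
    gls_mean: np.ndarray

    def __repr__(self):
        k = min(3, len(self.eigenvalues))
        cv = ", ".join(f"{v:.3f}" for v in self.cumulative_variance[:k])
        return f"<PPCAResult axes={len(self.eigenvalues)} cumvar[:{k}]=({cv})>"


def phylo_pca(tree: TimeTree, traits: pd.DataFrame) -> PPCAResult:
    """Phylogenetically corrected PCA (eigen-analysis of the GLS-estimated
    Brownian trait covariance; scores from GLS-centered data)."""
    data = traits.dropna()
    tips = sorted(set(tree.tip_labels) & set(data.index))
    if len(tips) < 3 or data.shape[1] < 2:
        raise ValueError("need >= 3 species and >= 2 traits")
    t = tree.prune_to(tips) if len(tips) < tree.n_tips else tree
    _, C = t.vcv(tips)
    X = data.loc[tips].to_numpy(float)
    n, p = X.shape
    ones = np.ones(n)
    Ci1 = np.linalg.solve(C, ones)
    a = (X.T @ Ci1) / (ones @ Ci1)  # GLS phylogenetic mean
    Xc = X - a
    R = Xc.T @ np.linalg.solve(C, Xc) / (n - 1)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    rank = int(np.sum(w > w[0] * 1e-12))
    if rank < p:
        import warnings

        warnings.warn(f"rank-deficient trait data: keeping {rank} of {p} axes")
        w, V = w[:rank], V[:, :rank]
    # sign convention: largest-magnitude loading positive
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    scores = pd.DataFrame(
        Xc @ V, index=tips, columns=[f"pPC{i+1}" for i in range(V.shape[1])]
    )
    cum = np.cumsum(w) / np.sum(w)
    return PPCAResult(w, V, scores, cum, a)


# ----------------------------------------------------------------------
# node height test
# ----------------------------------------------------------------------
@dataclass
class NodeHeightResult:
    slope: float
    intercept: float
    p_value: float
    r: float
    data: pd.DataFrame

    def summary(self) -> str:
        return (
            f"node height test: slope={self.slope:.5g} "
            f"(p={self.p_value:.4g}, r={self.r:.3f}, "
            f"n contrasts={len(self.data)})"
        )


def node_height_test(tree: TimeTree, trait: pd.Series) -> NodeHeightResult:
    """Regression of |standardized contrast| on node height.

    A significantly positive slope indicates trait-evolution rates that
    increase toward the present.
    """
    pic = contrasts(tree, trait)
    if len(pic) < 3:
        raise ValueError("need >= 3 contrasts (>= 4 tips)")
    res = stats.linregress(pic["node_height"], np.abs(pic["contrast"]))
    return NodeHeightResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r=float(res.rvalue),
        data=pic.assign(abs_contrast=np.abs(pic["contrast"])),
    )


# ----------------------------------------------------------------------
# Ward clustering
# ----------------------------------------------------------------------
def ward_clusters(traits: pd.DataFrame, k: int = 9) -> Tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering with Ward linkage on Euclidean distances.

    Rows with missing values are dropped; input rows are processed in
    label order so ties break deterministically.  Returns (labels,
    scipy linkage matrix).
    """
    data = traits.dropna().sort_index()
    n = len(data)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} complete species")
    Z = linkage(data.to_numpy(float), method="ward")
    lab = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(lab, index=data.index, name="cluster"), Z
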