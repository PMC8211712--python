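"""Convergent adaptive-peak detection (SURFACE-style stepwise Hansen model).

A Hansen model places Ornstein-Uhlenbeck adaptive peaks (optima) on a
phylogeny: each branch is painted with a regime, a tip's expected trait
value is the alpha-weighted mixture of the optima along its root-to-tip
path, and the covariance is the standard fixed-root OU form.  Traits are
treated as independent given the shared painting, each with its own
attraction alpha and diffusion sigma^2 shared across regimes; optima are
regime- and trait-specific.

The search has two phases.  Forward: starting from a single regime, a new
regime shift is proposed on every branch (applying to the branch and its
unshifted descendants), and the best small-sample AIC (AICc) improvement
is accepted until no addition helps.  Backward: pairs of regimes are
greedily merged onto a shared optimum while AICc keeps dropping.  Regimes
reached by more than one shift after merging are the convergent peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .tree import TimeTree

__all__ = [
    "hansen_loglik",
    "HansenFit",
    "SurfaceModel",
    "SurfaceResult",
]


# ----------------------------------------------------------------------
# painting utilities
# ----------------------------------------------------------------------
def painting_from_shifts(tree: TimeTree, shifts: Dict[int, int], root_regime: int = 0) -> Dict[int, int]:
    """Branch -> regime map implied by a set of shift origins.

    ``shifts`` maps a branch (postorder child-node index) to the regime its
    subtree switches into; deeper shifts override shallower ones.
    """
    painting: Dict[int, int] = {}
    state: Dict[int, int] = {tree.root.index: root_regime}
    for nd in tree.nodes("preorder"):
        if nd.parent_node is None:
            continue
        reg = shifts.get(nd.index, state[nd.parent_node.index])
        painting[nd.index] = reg
        state[nd.index] = reg
    return painting


def _tip_paths(tree: TimeTree) -> Dict[str, List[Tuple[float, float, int]]]:
    """Root-to-tip branch segments (older age, younger age, branch index)."""
    paths: Dict[int, List[Tuple[float, float, int]]] = {tree.root.index: []}
    out = {}
    for nd in tree.nodes("preorder"):
        if nd.parent_node is None:
            continue
        seg = (nd.parent_node.age_my, nd.age_my, nd.index)
        paths[nd.index] = paths[nd.parent_node.index] + [seg]
        if nd.is_leaf():
            out[nd.taxon.label] = paths[nd.index]
    return out


# ----------------------------------------------------------------------
# Hansen likelihood
# ----------------------------------------------------------------------
class _HansenEngine:
    """Caches the tree geometry for repeated likelihood evaluations.

    During the stepwise search, alpha is profiled on a fixed log-spaced
    grid whose Cholesky factors are cached, so each candidate painting
    costs only triangular solves; the final accepted model refines alpha
    continuously from the best grid point.
    """

    ALPHA_GRID = np.exp(np.linspace(math.log(1e-4), math.log(20.0), 16))

    def __init__(self, tree: TimeTree, tips: Sequence[str]):
        self.tree = tree
        self.tips = list(tips)
        _, self.C = tree.vcv(self.tips)  # shared path lengths
        self.T = tree.crown_age
        self.paths = _tip_paths(tree)
        self._chol_cache: Dict[float, np.ndarray] = {}
        self._liy_cache: Dict[Tuple[float, int], np.ndarray] = {}

    def chol(self, alpha: float) -> np.ndarray:
        if alpha not in self._chol_cache:
            V1 = self.ou_corr(alpha)
            self._chol_cache[alpha] = np.linalg.cholesky(
                V1 + np.eye(len(self.tips)) * 1e-12
            )
        return self._chol_cache[alpha]

    def li_y(self, alpha: float, key: int, y: np.ndarray) -> np.ndarray:
        k = (alpha, key)
        if k not in self._liy_cache:
            self._liy_cache[k] = np.linalg.solve(self.chol(alpha), y)
        return self._liy_cache[k]

    def ou_corr(self, alpha: float) -> np.ndarray:
        a = max(alpha, 1e-9)
        return np.exp(-2 * a * (self.T - self.C)) * (1 - np.exp(-2 * a * self.C)) / (2 * a)

    def weights(self, alpha: float, painting: Dict[int, int], regimes: List[int],
                root_regime: int) -> np.ndarray:
        a = max(alpha, 1e-9)
        pos = {r: i for i, r in enumerate(regimes)}
        W = np.zeros((len(self.tips), len(regimes)))
        for i, tip in enumerate(self.tips):
            for a0, a1, b in self.paths[tip]:
                W[i, pos[painting[b]]] += math.exp(-a * a1) - math.exp(-a * a0)
            W[i, pos[root_regime]] += math.exp(-a * self.T)
        return W

    def profile_trait(self, y: np.ndarray, alpha: float, painting, regimes,
                      root_regime, y_key: Optional[int] = None):
        """Profiled (theta, sigma2) and log-likelihood for one trait."""
        n = len(y)
        W = self.weights(alpha, painting, regimes, root_regime)
        try:
            L = self.chol(alpha)
        except np.linalg.LinAlgError:
            return None
        Li_y = self.li_y(alpha, y_key, y) if y_key is not None else np.linalg.solve(L, y)
        Li_W = np.linalg.solve(L, W)
        WtW = Li_W.T @ Li_W
        try:
            theta = np.linalg.solve(WtW + np.eye(W.shape[1]) * 1e-10, Li_W.T @ Li_y)
        except np.linalg.LinAlgError:
            return None
        resid = Li_y - Li_W @ theta
        rss = float(resid @ resid)
        if rss <= 0:
            rss = 1e-300
        sigma2 = rss / n
        logdet = 2 * float(np.sum(np.log(np.diag(L))))
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
        return theta, sigma2, ll


def hansen_loglik(
    tree: TimeTree,
    traits: pd.DataFrame,
    painting: Dict[int, int],
    alpha: Sequence[float],
    sigma2: Sequence[float],
    optima: pd.DataFrame,
    root_regime: Optional[int] = None,
) -> float:
    """Log-likelihood of a fully specified multi-optimum OU model.

    ``optima`` is a regimes x traits table; ``alpha`` and ``sigma2`` are
    per-trait.  Traits are independent given the painting.
    """
    tips = sorted(set(tree.tip_labels) & set(traits.dropna().index))
    eng = _HansenEngine(tree, tips)
    regimes = list(optima.index)
    if root_regime is None:
        root_regime = painting[max(c.index for c in tree.root.child_nodes())]
    Y = traits.loc[tips]
    ll = 0.0
    for j, col in enumerate(traits.columns):
        a, s2 = float(alpha[j]), float(sigma2[j])
        if a <= 0 or s2 <= 0:
            raise ValueError("alpha and sigma2 must be positive")
        V = eng.ou_corr(a) * s2
        W = eng.weights(a, painting, regimes, root_regime)
        mu = W @ optima[col].to_numpy(float)
        y = Y[col].to_numpy(float)
        L = np.linalg.cholesky(V + np.eye(len(tips)) * 1e-12)
        r = np.linalg.solve(L, y - mu)
        ll += -0.5 * (float(r @ r) + 2 * np.sum(np.log(np.diag(L)))
                      + len(tips) * math.log(2 * math.pi))
    return float(ll)


@dataclass
class HansenFit:
    shifts: Dict[int, int]
    painting: Dict[int, int]
    regimes: List[int]
    alpha: np.ndarray
    sigma2: np.ndarray
    optima: pd.DataFrame
    loglik: float
    n_params: int
    aicc: float

    def summary(self) -> str:
        return (
            f"Hansen fit: {len(self.regimes)} regimes, "
            f"{len(self.shifts)} shifts, logL={self.loglik:.3f}, "
            f"AICc={self.aicc:.2f}"
        )


@dataclass
class SurfaceResult:
    forward_path: List[HansenFit]
    backward_path: List[HansenFit]
    fit: HansenFit
    n_shifts: int
    n_regimes: int
    n_convergent: int
    n_unique: int

    def summary(self) -> str:
        return (
            f"SURFACE: {self.n_shifts} shifts -> {self.n_regimes} adaptive peaks "
            f"({self.n_convergent} convergent, {self.n_unique} unique); "
            f"final AICc={self.fit.aicc:.2f}"
        )


class SurfaceModel:
    """Stepwise convergent-peak search on a tree and trait matrix
    (typically the first two phylogenetic PCA axes)."""

    def __init__(self, tree: TimeTree, traits: pd.DataFrame):
        data = traits.dropna()
        tips = sorted(set(tree.tip_labels) & set(data.index))
        if len(tips) < 4:
            raise ValueError("need >= 4 tips with traits")
        self.tree = tree.prune_to(tips) if len(tips) < tree.n_tips else tree
        self.tips = self.tree.tip_labels
        self.Y = data.loc[self.tips]
        self.p = self.Y.shape[1]
        self.eng = _HansenEngine(self.tree, self.tips)

    # -- fit one painting ----------------------------------------------
    def _fit_painting(
        self, shifts: Dict[int, int], root_regime: int = 0, refine: bool = False
    ) -> Optional[HansenFit]:
        painting = painting_from_shifts(self.tree, shifts, root_regime)
        regimes = sorted(set(painting.values()) | {root_regime})
        ll_tot = 0.0
        alphas, sig2s, thetas = [], [], []
        for jcol, col in enumerate(self.Y.columns):
            y = self.Y[col].to_numpy(float)
            best = (-math.inf, None)
            for a in self.eng.ALPHA_GRID:
                res = self.eng.profile_trait(y, a, painting, regimes, root_regime, y_key=jcol)
                if res is not None and res[2] > best[0]:
                    best = (res[2], float(a))
            if best[1] is None:
                return None
            a_hat = best[1]
            if refine:
                def neg(log_a):
                    r = self.eng.profile_trait(
                        y, math.exp(log_a[0]), painting, regimes, root_regime
                    )
                    return -r[2] if r is not None else 1e10

                r = optimize.minimize(
                    neg, [math.log(a_hat)], method="L-BFGS-B",
                    bounds=[(math.log(1e-5), math.log(50.0))],
                )
                if -r.fun > best[0]:
                    a_hat = float(np.exp(r.x[0]))
            res = self.eng.profile_trait(y, a_hat, painting, regimes, root_regime)
            if res is None:
                return None
            theta, s2, ll = res
            alphas.append(a_hat)
            sig2s.append(s2)
            thetas.append(theta)
            ll_tot += ll
        optima = pd.DataFrame(
            np.column_stack(thetas), index=regimes, columns=self.Y.columns
        )
        k_reg = len(regimes)
        n_par = self.p * (2 + k_reg)
        n_eff = len(self.tips) * self.p
        denom = n_eff - n_par - 1
        if denom <= 0:
            return None
        aicc = -2 * ll_tot + 2 * n_par + 2 * n_par * (n_par + 1) / denom
        return HansenFit(dict(shifts), painting, regimes, np.array(alphas),
                         np.array(sig2s), optima, float(ll_tot), n_par, float(aicc))

    # -- forward phase --------------------------------------------------
    def forward(
        self,
        max_shifts: int = 30,
        forward_level: Optional[float] = 0.01,
        verbose: bool = False,
    ) -> List[HansenFit]:
        """Stepwise shift addition.

        A candidate shift is accepted when it both lowers AICc and, with
        ``forward_level`` set, passes a Bonferroni-corrected likelihood-
        ratio gate: because the best of ~#branches candidate positions is
        taken at every step, a raw AICc rule admits spurious regimes on
        homogeneous data, so the improvement 2*dlogL must exceed the
        chi-square(p) quantile at 1 - level / #branches.
        """
        from scipy.stats import chi2

        base = self._fit_painting({})
        path = [base]
        shifts: Dict[int, int] = {}
        next_regime = 1
        branch_ids = [nd.index for nd, _, _ in self.tree.edges()]
        gate = (
            chi2.ppf(1 - forward_level / len(branch_ids), self.p)
            if forward_level is not None
            else 0.0
        )
        while len(shifts) < max_shifts:
            best: Tuple[float, Optional[Dict[int, int]], Optional[HansenFit]] = (
                path[-1].aicc, None, None,
            )
            for b in branch_ids:
                if b in shifts:
                    continue
                cand = dict(shifts)
                cand[b] = next_regime
                fit = self._fit_painting(cand)
                if fit is None or fit.aicc >= best[0] - 1e-9:
                    continue
                if 2 * (fit.loglik - path[-1].loglik) <= gate:
                    continue
                best = (fit.aicc, cand, fit)
            if best[1] is None:
                break
            shifts = best[1]
            path.append(best[2])
            next_regime += 1
            if verbose:
                print(best[2].summary())
        return path

    # -- backward phase --------------------------------------------------
    def backward(self, forward_path: List[HansenFit], verbose: bool = False) -> List[HansenFit]:
        current = forward_path[-1]
        path = [current]
        while True:
            regimes = current.regimes
            best: Tuple[float, Optional[Dict[int, int]]] = (current.aicc, None)
            for i in range(len(regimes)):
                for j in range(i + 1, len(regimes)):
                    a, b = regimes[i], regimes[j]
                    merged = {
                        br: (a if r == b else r) for br, r in current.shifts.items()
                    }
                    root_reg = 0 if 0 != b else a
                    fit = self._fit_painting(merged, root_regime=root_reg)
                    if fit is not None and fit.aicc < best[0] - 1e-9:
                        best = (fit.aicc, merged)
            if best[1] is None:
                break
            current = self._fit_painting(best[1])
            path.append(current)
            if verbose:
                print(current.summary())
        return path

    def fit(
        self,
        max_shifts: int = 30,
        forward_level: Optional[float] = 0.01,
        verbose: bool = False,
    ) -> SurfaceResult:
        fwd = self.forward(max_shifts=max_shifts, forward_level=forward_level, verbose=verbose)
        bwd = self.backward(fwd, verbose=verbose)
        refined = self._fit_painting(bwd[-1].shifts, refine=True)
        final = refined if refined is not None and refined.aicc <= bwd[-1].aicc else bwd[-1]
        # origin counts per regime: the root plus every accepted shift
        origins: Dict[int, int] = {}
        root_reg = final.painting[max(c.index for c in self.tree.root.child_nodes())]
        rr = 0 if 0 in final.regimes else final.regimes[0]
        origins[rr] = origins.get(rr, 0) + 1
        for b, r in final.shifts.items():
            origins[r] = origins.get(r, 0) + 1
        n_regimes = len(final.regimes)
        n_conv = sum(1 for r, c in origins.items() if c > 1)
        n_unique = n_regimes - n_conv
        return SurfaceResult(
            fwd, bwd, final, len(final.shifts), n_regimes, n_conv, n_unique
        )
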