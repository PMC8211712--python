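"""Multivariate trait-evolution models with a fixed-time mode shift.

The model family compares how a small set of (typically 2) trait axes
evolved: single-process Brownian motion (BM), early burst / ACDC (EB,
exponentially time-varying rate) and Ornstein-Uhlenbeck (OU), and
two-phase models in which the mode switches at a fixed shift age (taken
from the diversification analysis, not optimised).  "Independent drift"
gives the second phase its own trait rate matrix.

The among-tip covariance is assembled additively: the phase-1 process
accumulates variance over the part of each shared root-to-MRCA path older
than the shift, the phase-2 process over the part younger than the shift,
each with its own time transform (BM: elapsed time; EB: int exp(r u) du
with u measured from the phase start; OU: the standard fixed-root
ultrametric OU covariance within the phase window).  Trait dimensions
enter as Kronecker products with the rate matrix (a sum of two Kronecker
terms when drift is independent).  The mean vector is profiled by GLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .diversification import akaike_weights
from .tree import TimeTree

__all__ = [
    "TraitModelSpec",
    "TraitModelFit",
    "TraitEvolutionModel",
    "model_covariance",
    "shift_model_family",
    "compare_trait_models",
]

_MODES = ("BM", "EB", "OU")


@dataclass(frozen=True)
class TraitModelSpec:
    """One member of the (possibly shifted) trait-model family."""

    mode1: str
    mode2: Optional[str] = None
    shift_age: Optional[float] = None
    independent_drift: bool = False

    def __post_init__(self):
        if self.mode1 not in _MODES or (self.mode2 is not None and self.mode2 not in _MODES):
            raise ValueError("modes must be BM, EB or OU")
        if (self.mode2 is None) != (self.shift_age is None):
            raise ValueError("two-phase specs need a shift age (and vice versa)")

    @property
    def name(self) -> str:
        long = {"BM": "Brownian motion", "EB": "early burst", "OU": "Ornstein-Uhlenbeck"}
        if self.mode2 is None:
            return long[self.mode1]
        s = f"{long[self.mode1]} to {long[self.mode2]}"
        if self.independent_drift:
            s += " with independent drift"
        return s

    def n_params(self, p: int) -> int:
        k = p * (p + 1) // 2 + p  # Sigma + mean vector
        if self.mode2 is not None and self.independent_drift:
            k += p * (p + 1) // 2
        for mode in (self.mode1, self.mode2):
            if mode == "EB":
                k += 1  # r
            elif mode == "OU":
                k += 1  # alpha
        return k


def _phase_transform(mode: str, shared: np.ndarray, duration: float, r: float, alpha: float) -> np.ndarray:
    """Univariate variance accumulation over the shared path within one
    phase window.  ``shared`` is the shared time within the phase,
    ``duration`` the (common, ultrametric) phase duration along each path."""
    if mode == "BM":
        return shared.copy()
    if mode == "EB":
        if abs(r) < 1e-12:
            return shared.copy()
        return (np.exp(r * shared) - 1.0) / r
    if mode == "OU":
        a = max(alpha, 1e-10)
        return np.exp(-2 * a * (duration - shared)) * (1 - np.exp(-2 * a * shared)) / (2 * a)
    raise ValueError(mode)


def model_covariance(
    tree: TimeTree,
    spec: TraitModelSpec,
    tips: Optional[Sequence[str]] = None,
    r1: float = 0.0,
    alpha1: float = 0.0,
    r2: float = 0.0,
    alpha2: float = 0.0,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-phase univariate covariance matrices (T1, T2) among tips.

    The full trait covariance is ``kron(T1, Sigma) + kron(T2, Sigma2)``
    (T2 is None for single-phase specs).
    """
    tips = list(tips) if tips is not None else tree.tip_labels
    _, C = tree.vcv(tips)  # shared path from root (My)
    T = tree.crown_age
    t_mrca = T - C  # age of each pair's MRCA
    if spec.mode2 is None:
        T1 = _phase_transform(spec.mode1, C, T, r1, alpha1)
        return T1, None
    s = spec.shift_age
    if not (0 < s < T):
        raise ValueError("shift age must lie inside (0, crown age)")
    shared1 = np.maximum(0.0, T - np.maximum(t_mrca, s))
    shared2 = np.maximum(0.0, s - t_mrca)
    T1 = _phase_transform(spec.mode1, shared1, T - s, r1, alpha1)
    T2 = _phase_transform(spec.mode2, shared2, s, r2, alpha2)
    return T1, T2


def _chol_from_theta(theta: np.ndarray, p: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from log-diagonal parameterisation."""
    L = np.zeros((p, p))
    idx = 0
    for i in range(p):
        for j in range(i + 1):
            if i == j:
                L[i, j] = math.exp(theta[idx])
            else:
                L[i, j] = theta[idx]
            idx += 1
    return L


@dataclass
class TraitModelFit:
    spec: TraitModelSpec
    Sigma: np.ndarray
    Sigma2: Optional[np.ndarray]
    r1: float
    alpha1: float
    r2: float
    alpha2: float
    mean: np.ndarray
    loglik: float
    k: int
    aic: float
    converged: bool
    akaike_weight: Optional[float] = None

    def summary(self) -> str:
        return (
            f"{self.spec.name}: logL={self.loglik:.3f}, k={self.k}, "
            f"AIC={self.aic:.2f}"
        )


class TraitEvolutionModel:
    """ML fitting of a trait-evolution spec to tip data (model-object
    style: construct with data, call :meth:`fit`)."""

    def __init__(self, tree: TimeTree, traits: pd.DataFrame, spec: TraitModelSpec):
        data = traits.dropna()
        tips = sorted(set(tree.tip_labels) & set(data.index))
        if len(tips) < 2:
            raise ValueError("need >= 2 tips with complete traits")
        self.tree = tree.prune_to(tips) if len(tips) < tree.n_tips else tree
        self.tips = self.tree.tip_labels
        self.Y = data.loc[self.tips].to_numpy(float)
        self.n, self.p = self.Y.shape
        self.spec = spec

    # -- likelihood ----------------------------------------------------
    def _loglik(self, Sigma, Sigma2, r1, a1, r2, a2) -> Tuple[float, np.ndarray]:
        T1, T2 = model_covariance(
            self.tree, self.spec, self.tips, r1, a1, r2, a2
        )
        V = np.kron(T1, Sigma)
        if T2 is not None:
            V = V + np.kron(T2, Sigma2 if Sigma2 is not None else Sigma)
        n, p = self.n, self.p
        y = self.Y.reshape(-1)  # tip-major ordering matches kron(T, Sigma)
        X = np.kron(np.ones((n, 1)), np.eye(p))
        try:
            Lv = np.linalg.cholesky(V + np.eye(n * p) * 1e-10)
        except np.linalg.LinAlgError:
            return -math.inf, np.zeros(p)
        sol = np.linalg.solve
        Li_y = sol(Lv, y)
        Li_X = sol(Lv, X)
        XtViX = Li_X.T @ Li_X
        try:
            beta = sol(XtViX, Li_X.T @ Li_y)
        except np.linalg.LinAlgError:
            return -math.inf, np.zeros(p)
        resid = Li_y - Li_X @ beta
        logdet = 2 * np.sum(np.log(np.diag(Lv)))
        ll = -0.5 * (resid @ resid + logdet + n * p * math.log(2 * math.pi))
        return float(ll), beta

    def loglik(self, **kw) -> float:
        return self._loglik(
            kw["Sigma"], kw.get("Sigma2"), kw.get("r1", 0.0), kw.get("alpha1", 0.0),
            kw.get("r2", 0.0), kw.get("alpha2", 0.0),
        )[0]

    # -- optimisation --------------------------------------------------
    def fit(self, n_starts: int = 4, maxiter: int = 500) -> TraitModelFit:
        spec, p = self.spec, self.p
        ns = p * (p + 1) // 2
        two_sigma = spec.mode2 is not None and spec.independent_drift
        extras = []  # (name, bounds)
        if spec.mode1 == "EB":
            extras.append(("r1", (-2.0, 2.0)))
        if spec.mode1 == "OU":
            extras.append(("alpha1", (1e-4, 20.0)))
        if spec.mode2 == "EB":
            extras.append(("r2", (-2.0, 2.0)))
        if spec.mode2 == "OU":
            extras.append(("alpha2", (1e-4, 20.0)))

        # starting Sigma: contrasts-free quick estimate from tip variance
        v0 = max(np.var(self.Y, axis=0).mean() / max(self.tree.crown_age, 1e-9), 1e-8)
        theta_sigma0 = []
        for i in range(p):
            for j in range(i + 1):
                theta_sigma0.append(0.5 * math.log(v0) if i == j else 0.0)
        theta_sigma0 = np.array(theta_sigma0)

        def unpack(theta):
            L1 = _chol_from_theta(theta[:ns], p)
            off = ns
            Sigma2 = None
            if two_sigma:
                L2 = _chol_from_theta(theta[off:off + ns], p)
                Sigma2 = L2 @ L2.T
                off += ns
            vals = {"r1": 0.0, "alpha1": 0.0, "r2": 0.0, "alpha2": 0.0}
            for (name, _), v in zip(extras, theta[off:]):
                vals[name] = v
            return L1 @ L1.T, Sigma2, vals

        def neg(theta):
            Sigma, Sigma2, vals = unpack(theta)
            ll, _ = self._loglik(Sigma, Sigma2, vals["r1"], vals["alpha1"],
                                 vals["r2"], vals["alpha2"])
            return -ll if np.isfinite(ll) else 1e10

        bounds = [(-20, 10)] * ns + ([(-20, 10)] * ns if two_sigma else [])
        bounds += [b for _, b in extras]
        # deterministic multi-starts over r / alpha (the rough surfaces)
        start_extras = {
            "r1": [-0.1, -0.5, 0.1, -0.02],
            "r2": [-0.1, -0.5, 0.1, -0.02],
            "alpha1": [0.05, 0.5, 2.0, 0.01],
            "alpha2": [0.05, 0.5, 2.0, 0.01],
        }
        best = (math.inf, None)
        for s_i in range(n_starts):
            x0 = list(theta_sigma0)
            if two_sigma:
                x0 += list(theta_sigma0)
            for name, b in extras:
                x0.append(np.clip(start_extras[name][s_i % 4], *b))
            r = optimize.minimize(
                neg, np.array(x0), method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
            if r.fun < best[0]:
                best = (r.fun, r.x)
            if not extras and s_i == 0:
                break  # BM-only likelihood is smooth; one start suffices
        converged = best[1] is not None and best[0] < 1e9
        Sigma, Sigma2, vals = unpack(best[1]) if converged else (np.eye(p), None, {})
        ll, beta = self._loglik(
            Sigma, Sigma2, vals.get("r1", 0), vals.get("alpha1", 0),
            vals.get("r2", 0), vals.get("alpha2", 0),
        ) if converged else (-math.inf, np.zeros(p))
        k = spec.n_params(p)
        return TraitModelFit(
            spec, Sigma, Sigma2, vals.get("r1", 0.0), vals.get("alpha1", 0.0),
            vals.get("r2", 0.0), vals.get("alpha2", 0.0), beta, ll, k,
            2 * k - 2 * ll, converged,
        )


def shift_model_family(shift_age: float) -> List[TraitModelSpec]:
    """The full comparison set: three single-process models and every
    ordered mode pair with and without independent drift."""
    singles = [TraitModelSpec(m) for m in _MODES]
    pairs = []
    for m1 in _MODES:
        for m2 in _MODES:
            if m1 == m2:
                continue
            for ind in (False, True):
                pairs.append(TraitModelSpec(m1, m2, shift_age, ind))
    return singles + pairs


def compare_trait_models(fits: Sequence[TraitModelFit]) -> pd.DataFrame:
    """AIC table with delta-AIC and Akaike weights (shared definition)."""
    if len(fits) < 1:
        raise ValueError("no fits")
    ok = [f for f in fits if f.converged]
    w = akaike_weights([f.aic for f in ok])
    for f, wi in zip(ok, w):
        f.akaike_weight = float(wi)
    rows = [
        {
            "model": f.spec.name,
            "logLik": f.loglik,
            "params": f.k,
            "AIC": f.aic,
            "AICw": f.akaike_weight if f.converged else np.nan,
            "converged": f.converged,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df
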