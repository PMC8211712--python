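"""Lineage-through-time analysis and birth-death model selection.

Implements the diversification toolkit applied to a chronogram when
screening for an early burst followed by renewed diversification:

* the gamma statistic of node-age concentration with Monte-Carlo
  pure-birth nulls (one-sided, lower tail: the hypothesis is an early
  burst, gamma < 0);
* the constant-rate birth-death likelihood of the branching times,
  conditioned on the crown age and on survival of both crown lineages;
* the diversity-dependent likelihood, where the per-lineage speciation
  rate at standing diversity N is ``max(0, lambda0 - (lambda0-mu) N/K)``,
  computed by numerically integrating the master equation for the number
  of unobserved (eventually extinct) lineages between branching events;
* a family of shifted models in which the parameters (lambda, mu, K)
  change at an age ``t_shift``, fitted by maximum likelihood with the
  shift age profiled over a grid and refined, and compared with Akaike
  weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import expm_multiply

from .tree import TimeTree

__all__ = [
    "gamma_statistic",
    "gamma_from_intervals",
    "GammaResult",
    "gamma_test",
    "crbd_loglik",
    "dd_loglik",
    "DiversificationModelSpec",
    "birth_death_model_family",
    "DiversificationModel",
    "ModelFit",
    "akaike_weights",
    "compare_models",
]


# ======================================================================
# gamma statistic
# ======================================================================
def _intervals(bt: np.ndarray) -> np.ndarray:
    """Inter-event durations g_k (k = 2..n lineages) from branching times."""
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    if np.any(bt <= 0):
        raise ValueError("branching times must be positive ages")
    return np.concatenate([bt[:-1] - bt[1:], bt[-1:]])


def gamma_from_intervals(g: np.ndarray) -> float:
    """Gamma from the durations g_k with exactly k=2..n lineages."""
    g = np.asarray(g, dtype=float)
    n = len(g) + 1
    if n < 3:
        raise ValueError("gamma needs at least 3 tips")
    k = np.arange(2, n + 1)
    kg = k * g
    T = kg.sum()
    cum = np.cumsum(kg)  # cum[i-2] = sum_{k=2}^{i} k g_k
    mean_inner = cum[:-1].mean()  # i runs 2..n-1
    return float((mean_inner - T / 2) / (T * math.sqrt(1.0 / (12 * (n - 2)))))


def gamma_statistic(bt: np.ndarray) -> float:
    """Gamma of a vector of branching times (ages, any order)."""
    return gamma_from_intervals(_intervals(bt))


@dataclass
class GammaResult:
    gamma: float
    p_value: float
    n_null: int
    n_tips: int
    null_gammas: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"gamma = {self.gamma:.4f}, one-sided p = {self.p_value:.4g} "
            f"({self.n_null} pure-birth nulls, n = {self.n_tips})"
        )


def gamma_test(tree_or_bt, n_null: int = 1000, seed=None) -> GammaResult:
    """Monte-Carlo gamma test against pure-birth nulls with the same n.

    Under pure birth the durations with k lineages are independent
    exponentials with rate k*lambda and gamma is invariant to the rate
    scale, so nulls are drawn directly on the interval representation.
    The p-value is one-sided (lower tail, early burst) with the
    (r+1)/(N+1) correction, so it is never exactly 0.
    """
    if isinstance(tree_or_bt, TimeTree):
        bt = tree_or_bt.branching_times()
    else:
        bt = np.asarray(tree_or_bt, dtype=float)
    n = len(bt) + 1
    if n < 3:
        raise ValueError("gamma test needs at least 3 tips")
    if n_null < 100:
        warnings.warn("fewer than 100 nulls: p-value resolution is coarse")
    rng = np.random.default_rng(seed)
    obs = gamma_statistic(bt)
    k = np.arange(2, n + 1)
    nulls = np.empty(n_null)
    for i in range(n_null):
        g = rng.exponential(1.0 / k)
        nulls[i] = gamma_from_intervals(g)
    p = (1.0 + np.sum(nulls <= obs)) / (n_null + 1.0)
    return GammaResult(obs, float(p), n_null, n, nulls)


# ======================================================================
# constant-rate birth-death likelihood
# ======================================================================
def crbd_loglik(bt: np.ndarray, lam: float, mu: float) -> float:
    """Log-likelihood of branching times under constant-rate birth-death,
    conditioned on the crown age and survival of both crown lineages.

    Topology-only combinatorial constants are dropped (consistently across
    all models in this module).
    """
    if not (lam > mu >= 0):
        raise ValueError("requires lambda > mu >= 0")
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    T = bt[0]
    inner = bt[1:]
    n = len(bt) + 1
    r = lam - mu

    def logP(t):  # log P(lineage survives time t)
        return math.log(r) - math.log(lam - mu * math.exp(-r * t))

    def logp1(t):  # log P(exactly one surviving descendant)
        return 2 * logP(t) - r * t

    ll = (n - 2) * math.log(lam)
    ll += sum(logp1(t) for t in inner)
    ll += 2 * logp1(T) - 2 * logP(T)
    return float(ll)


# ======================================================================
# diversity-dependent likelihood (master equation over hidden lineages)
# ======================================================================
def _lambda_N(N, lam0, mu, K):
    if K is None or not np.isfinite(K):
        return np.broadcast_to(lam0, np.shape(N)).astype(float)
    return np.maximum(0.0, lam0 - (lam0 - mu) * np.asarray(N, dtype=float) / K)


def _hidden_generator(k: int, lam0: float, mu: float, K, L: int) -> sparse.csr_matrix:
    """Weight-evolution operator for the hidden-lineage count n = 0..L-1
    with k observed lineages present (dQ/dt = A Q).

    The accounting mirrors the per-lineage D/E equations of state-dependent
    birth-death likelihoods: a hidden lineage is born from a hidden parent
    (rate n*lambda_N) or as either daughter of an observed parent (rate
    2*k*lambda_N); hidden lineages die at rate mu; every lineage, observed
    or hidden, carries the exposure discount (lambda_N + mu), observed
    deaths being forbidden rather than absent.  The operator is therefore
    intentionally non-conservative: it propagates a likelihood weight, not
    a probability distribution.
    """
    n = np.arange(L)
    lam_m = _lambda_N(n + k, lam0, mu, K)
    birth = (n + 2 * k) * lam_m  # A[n+1, n]
    death = n * mu  # A[n-1, n]
    diag = -(n + k) * (lam_m + mu)
    return sparse.diags(
        [death[1:], diag, birth[:-1]], offsets=[1, 0, -1], format="csr"
    )


def _piecewise_loglik(
    bt: np.ndarray,
    phases: Sequence[Tuple[float, float, Optional[float]]],
    shift_age: Optional[float],
    n_max: Optional[int] = None,
    condition: bool = True,
) -> float:
    """Master-equation log-likelihood for a (possibly shifted) diversity-
    dependent process.  ``phases`` is ((lam0,mu,K) old, [(lam0,mu,K) young]).
    """
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    T = bt[0]
    n_tips = len(bt) + 1
    Ks = [p[2] for p in phases if p[2] is not None and np.isfinite(p[2])]
    if n_max is None:
        n_max = int(max(2 * max(Ks) if Ks else 0, n_tips + 100))
        n_max = min(n_max, n_tips + 600)
    def pars(age):
        if shift_age is not None and age < shift_age:
            return phases[1]
        return phases[0]

    mus = [p[1] for p in phases]
    all_pure_birth = all(m == 0 for m in mus)

    # event timeline: node ages (descending, crown first) and the shift
    events = [("node", a) for a in bt[1:]]
    if shift_age is not None and 0 < shift_age < T:
        events.append(("shift", shift_age))
    events.sort(key=lambda e: -e[1])

    loglik = 0.0
    k = 2
    if all_pure_birth:
        # hidden lineages never die, so only the zero-hidden state matters
        ages = np.array([a for _, a in events] + [0.0])
        kinds = np.array([kind == "node" for kind, _ in events] + [False])
        ks = 2 + np.concatenate([[0], np.cumsum(kinds[:-1])])
        starts = np.concatenate([[T], ages[:-1]])
        mids = (starts + ages) / 2
        lam0s = np.empty_like(mids)
        mus = np.empty_like(mids)
        Kvs = np.full_like(mids, np.inf)
        for i, am in enumerate(mids):
            l0, m0, K0 = pars(am)
            lam0s[i], mus[i] = l0, m0
            if K0 is not None:
                Kvs[i] = K0
        lam_seg = np.maximum(0.0, lam0s - (lam0s - mus) * ks / Kvs)
        loglik = -np.sum(ks * lam_seg * (starts - ages))
        node_idx = np.where(kinds)[0]
        l0n, m0n, K0n = (np.empty(len(node_idx)) for _ in range(3))
        for j, i in enumerate(node_idx):
            l0, m0, K0 = pars(ages[i])
            l0n[j], m0n[j] = l0, m0
            K0n[j] = np.inf if K0 is None else K0
        lam_node = np.maximum(0.0, l0n - (l0n - m0n) * (2 + np.arange(len(node_idx))) / K0n)
        if np.any(lam_node <= 0):
            return -math.inf
        loglik += float(np.sum(np.log(lam_node)))
        return float(loglik)

    L = max(n_max - 2, 10)
    Q = np.zeros(L)
    Q[0] = 1.0
    a_prev = T
    for kind, a in events + [("end", 0.0)]:
        dt = a_prev - a
        if dt > 0:
            lam0, mu, K = pars((a_prev + a) / 2)
            A = _hidden_generator(k, lam0, mu, K, L)
            Q = expm_multiply(A * dt, Q)
            Q = np.maximum(Q, 0.0)
            tot = Q.sum()
            if not np.isfinite(tot) or tot <= 0:
                return -math.inf
            if Q[-1] / tot > 1e-8:
                warnings.warn(
                    "probability mass at the truncation boundary exceeds 1e-8; "
                    "increase n_max"
                )
            loglik += math.log(tot)
            Q = Q / tot
        if kind == "node":
            lam0, mu, K = pars(a)
            lam_m = _lambda_N(np.arange(L) + k, lam0, mu, K)
            Q = Q * lam_m
            tot = Q.sum()
            if tot <= 0:
                return -math.inf
            loglik += math.log(tot)
            Q = Q / tot
            k += 1
        a_prev = a
    loglik += math.log(Q[0]) if Q[0] > 0 else -math.inf
    if condition:
        loglik -= _log_survival_both(T, phases, shift_age, n_max)
    return float(loglik)


def _log_survival_both(T, phases, shift_age, n_max) -> float:
    """log P(both crown lineages leave descendants at the present)."""
    mus = [p[1] for p in phases]
    if all(m == 0 for m in mus):
        return 0.0
    Ks = [p[2] for p in phases if p[2] is not None and np.isfinite(p[2])]
    if not Ks and shift_age is None:
        lam0, mu, _ = phases[0]
        r = lam0 - mu
        if r <= 0:
            return -math.inf
        logP = math.log(r) - math.log(lam0 - mu * math.exp(-r * T))
        return 2 * logP
    # joint master equation over descendant counts (n1, n2) of the two
    # crown lineages; n_i = 0 is absorbing
    M = int(min(max(Ks) * 2 if Ks else 0, 80))
    M = max(M, 30)
    idx = lambda i, j: i * (M + 1) + j
    rows, cols, vals = [], [], []

    def build(lam0, mu, K):
        rows.clear(), cols.clear(), vals.clear()
        data = []
        for i in range(M + 1):
            for j in range(M + 1):
                s = idx(i, j)
                N = i + j
                lam = float(_lambda_N(N, lam0, mu, K))
                out = 0.0
                if i > 0 and i < M:
                    data.append((idx(i + 1, j), s, i * lam))
                    out += i * lam
                if j > 0 and j < M:
                    data.append((idx(i, j + 1), s, j * lam))
                    out += j * lam
                if i > 0:
                    data.append((idx(i - 1, j), s, i * mu))
                    out += i * mu
                if j > 0:
                    data.append((idx(i, j - 1), s, j * mu))
                    out += j * mu
                data.append((s, s, -out))
        r, c, v = zip(*data)
        return sparse.csr_matrix((v, (r, c)), shape=((M + 1) ** 2, (M + 1) ** 2))

    P = np.zeros((M + 1) ** 2)
    P[idx(1, 1)] = 1.0
    segs = []
    if shift_age is not None and 0 < shift_age < T:
        segs = [(T - shift_age, phases[0]), (shift_age, phases[1])]
    else:
        segs = [(T, phases[0])]
    for dt, (lam0, mu, K) in segs:
        A = build(lam0, mu, K)
        P = expm_multiply(A * dt, P)
        P = np.maximum(P, 0.0)
    Pm = P.reshape(M + 1, M + 1)
    p_both = float(Pm[1:, 1:].sum())
    if p_both <= 0:
        return -math.inf
    return math.log(p_both)


def dd_loglik(
    bt: np.ndarray, lambda0: float, mu: float, K: float, n_max: Optional[int] = None
) -> float:
    """Diversity-dependent birth-death log-likelihood of branching times,
    conditioned on crown age and survival of both crown lineages."""
    if lambda0 <= 0 or mu < 0 or (K is not None and K <= 1):
        raise ValueError("need lambda0 > 0, mu >= 0, K > 1")
    return _piecewise_loglik(bt, [(lambda0, mu, K)], None, n_max=n_max)


# ======================================================================
# model specs and fitting
# ======================================================================
_PARAMS = ("lambda1", "mu1", "K1", "lambda2", "mu2", "K2", "t_shift")


@dataclass(frozen=True)
class DiversificationModelSpec:
    """One member of the birth-death model family.

    ``free`` lists the parameters estimated by ML; ``ties`` maps post-shift
    parameters to their pre-shift counterparts; ``fixed`` pins parameters
    to constants (e.g. mu1=0 for pure birth, K1=None for no diversity
    dependence).  ``shift`` switches the two-phase process on.
    """

    name: str
    free: Tuple[str, ...]
    ties: Dict[str, str] = field(default_factory=dict)
    fixed: Dict[str, Optional[float]] = field(default_factory=dict)
    shift: bool = False

    def __post_init__(self):
        for p in self.free:
            if p not in _PARAMS:
                raise ValueError(f"unknown parameter {p}")
        seen = set()
        for a, b in self.ties.items():
            if b in self.ties:
                raise ValueError("tying map must be acyclic/flat")

    def resolve(self, values: Dict[str, float]) -> Dict[str, Optional[float]]:
        out: Dict[str, Optional[float]] = {}
        for p in _PARAMS:
            if p in values:
                out[p] = values[p]
            elif p in self.ties:
                out[p] = values.get(self.ties[p], self.fixed.get(self.ties[p]))
            elif p in self.fixed:
                out[p] = self.fixed[p]
            else:
                out[p] = None
        return out

    @property
    def k(self) -> int:
        return len(self.free)


def birth_death_model_family(pure_birth: bool = False) -> List[DiversificationModelSpec]:
    """The shifted diversity-dependent model family.

    With ``pure_birth=True`` extinction is fixed to zero throughout, which
    makes every likelihood evaluation closed-form fast (the empirical
    support for extinction in this system is negligible).
    """
    mu_fix = {"mu1": 0.0} if pure_birth else {}
    mu_free = () if pure_birth else ("mu1",)

    def S(name, free, ties, fixed, shift=True):
        return DiversificationModelSpec(name, tuple(free), dict(ties), dict(fixed), shift)

    models = [
        S("constant rate birth-death", ("lambda1",) + mu_free, {}, {"K1": None, **mu_fix}, shift=False),
        S("diversity dependent, no shift", ("lambda1", "K1") + (() if pure_birth else ("mu1",)), {}, mu_fix, shift=False),
        S("shift in speciation rate", ("lambda1", "K1", "lambda2", "t_shift") + mu_free,
          {"mu2": "mu1", "K2": "K1"}, mu_fix),
        S("shift in speciation rate and carrying capacity",
          ("lambda1", "K1", "lambda2", "K2", "t_shift") + mu_free, {"mu2": "mu1"}, mu_fix),
        S("shift in speciation, extinction and carrying capacity",
          ("lambda1", "K1", "lambda2", "K2", "t_shift") + (("mu1", "mu2") if not pure_birth else ()),
          {} if not pure_birth else {"mu2": "mu1"}, mu_fix),
        S("shift in extinction rate and carrying capacity",
          ("K1", "K2", "t_shift") + (("mu1", "mu2") if not pure_birth else ()),
          {"lambda2": "lambda1", **({"mu2": "mu1"} if pure_birth else {})},
          {**mu_fix, "lambda1": None} if False else mu_fix),
        S("shift in carrying capacity", ("lambda1", "K1", "K2", "t_shift") + mu_free,
          {"lambda2": "lambda1", "mu2": "mu1"}, mu_fix),
    ]
    # the extinction/K-shift row still needs lambda1 free
    models[5] = S(
        "shift in extinction rate and carrying capacity",
        ("lambda1", "K1", "K2", "t_shift") + (("mu1", "mu2") if not pure_birth else ()),
        {"lambda2": "lambda1", **({"mu2": "mu1"} if pure_birth else {})},
        mu_fix,
    )
    return models


@dataclass
class ModelFit:
    spec: DiversificationModelSpec
    params: Dict[str, Optional[float]]
    loglik: float
    k: int
    aic: float
    converged: bool
    akaike_weight: Optional[float] = None

    def summary(self) -> str:
        pars = ", ".join(
            f"{p}={v:.4g}" for p, v in self.params.items() if v is not None
        )
        return (
            f"{self.spec.name}: logL={self.loglik:.3f}, k={self.k}, "
            f"AIC={self.aic:.2f} [{pars}]"
        )


class DiversificationModel:
    """ML fitting of one birth-death spec to a tree's branching times.

    ``fit()`` maximises the likelihood over the spec's free parameters
    using bounded quasi-Newton optimisation from several deterministic
    starts; when the shift age is free it is first profiled on a grid
    (0.5 My steps across the central 90% of the tree depth) and then
    refined locally.
    """

    def __init__(self, tree_or_bt, spec: DiversificationModelSpec, n_max: Optional[int] = None):
        if isinstance(tree_or_bt, TimeTree):
            self.bt = tree_or_bt.branching_times()
        else:
            self.bt = np.sort(np.asarray(tree_or_bt, float))[::-1]
        self.spec = spec
        self.n_max = n_max
        self.T = float(self.bt[0])
        self.n = len(self.bt) + 1

    # -- likelihood of a resolved parameter dict -----------------------
    def loglik(self, full: Dict[str, Optional[float]]) -> float:
        lam1, mu1, K1 = full["lambda1"], full["mu1"] or 0.0, full["K1"]
        if lam1 is None or lam1 <= 0 or mu1 < 0:
            return -math.inf
        if K1 is not None and K1 <= 1:
            return -math.inf
        if not self.spec.shift:
            if K1 is None and mu1 == 0:
                return self._yule_ll(lam1)
            if K1 is None:
                if lam1 <= mu1:
                    return -math.inf
                return crbd_loglik(self.bt, lam1, mu1)
            try:
                return _piecewise_loglik(self.bt, [(lam1, mu1, K1)], None, self.n_max)
            except Exception:
                return -math.inf
        lam2 = full["lambda2"] if full["lambda2"] is not None else lam1
        mu2 = full["mu2"] if full["mu2"] is not None else mu1
        K2 = full["K2"] if full["K2"] is not None else K1
        t = full["t_shift"]
        if t is None or not (0 < t < self.T) or lam2 <= 0 or mu2 < 0:
            return -math.inf
        if K2 is not None and K2 <= 1:
            return -math.inf
        try:
            return _piecewise_loglik(
                self.bt, [(lam1, mu1, K1), (lam2, mu2, K2)], t, self.n_max
            )
        except Exception:
            return -math.inf

    def _yule_ll(self, lam):
        return _piecewise_loglik(self.bt, [(lam, 0.0, None)], None)

    # -- optimisation ---------------------------------------------------
    _BOUNDS = {
        "lambda1": (1e-4, 10.0),
        "lambda2": (1e-4, 10.0),
        "mu1": (0.0, 5.0),
        "mu2": (0.0, 5.0),
        "K1": (None, None),  # filled per tree
        "K2": (None, None),
    }

    def _bounds(self, p):
        if p.startswith("K"):
            return (max(3.0, self.n * 0.3), max(5000.0, self.n * 10.0))
        if p == "t_shift":
            return (0.05 * self.T, 0.95 * self.T)
        return self._BOUNDS[p]

    def _starts(self, n_starts=8):
        lam_hat = max((self.n - 2), 1) / max(np.sum(self.bt[1:]) + 2 * self.T, 1e-9)
        base = {
            "lambda1": lam_hat,
            "lambda2": lam_hat,
            "mu1": 0.0 if "mu1" not in self.spec.free else lam_hat * 0.1,
            "mu2": lam_hat * 0.1,
            "K1": self.n * 1.5,
            "K2": self.n * 1.5,
            "t_shift": self.T / 3,
        }
        mults = [
            dict(),
            {"lambda1": 0.3, "lambda2": 3.0},
            {"lambda1": 3.0, "lambda2": 0.3},
            {"K1": 3.0, "K2": 0.6},
            {"K1": 0.6, "K2": 3.0},
            {"lambda1": 0.5, "K1": 4.0},
            {"lambda2": 5.0},
            {"lambda1": 2.0, "lambda2": 2.0, "K1": 2.0},
        ]
        starts = []
        for m in mults[:n_starts]:
            s = dict(base)
            for key, f in m.items():
                s[key] = s[key] * f
            starts.append(s)
        return starts

    def fit(self, n_starts: int = 8, grid_step: float = 0.5) -> ModelFit:
        spec = self.spec
        free = [p for p in spec.free if p != "t_shift"]
        t_free = "t_shift" in spec.free and spec.shift

        def neg(theta, t_val):
            vals = {p: v for p, v in zip(free, theta)}
            if t_free:
                vals["t_shift"] = t_val
            ll = self.loglik(spec.resolve(vals))
            return -ll if np.isfinite(ll) else 1e10

        bounds = [self._bounds(p) for p in free]
        best = (math.inf, None, None)

        def run_starts(t_val, starts, maxiter=200):
            nonlocal best
            for s in starts:
                x0 = np.array([np.clip(s[p], *self._bounds(p)) for p in free])
                try:
                    r = optimize.minimize(
                        neg, x0, args=(t_val,), method="L-BFGS-B",
                        bounds=bounds, options={"maxiter": maxiter},
                    )
                except Exception:
                    continue
                if r.fun < best[0]:
                    best = (r.fun, dict(zip(free, r.x)), t_val)

        starts = self._starts(n_starts)
        if not t_free:
            run_starts(None, starts)
        else:
            lo, hi = self._bounds("t_shift")
            grid = np.arange(lo, hi + 1e-9, grid_step)
            # coarse profile with cheap optimisation, two starts
            coarse_best = (math.inf, None)
            for t_val in grid:
                saved = best
                best = (math.inf, None, None)
                run_starts(t_val, starts[:1], maxiter=40)
                if best[0] < coarse_best[0]:
                    coarse_best = (best[0], t_val)
                if saved[0] < best[0]:
                    best = saved
            t0 = coarse_best[1] if coarse_best[1] is not None else self.T / 3
            # refinement: t free alongside the other parameters
            def neg_all(theta):
                vals = {p: v for p, v in zip(free, theta[:-1])}
                vals["t_shift"] = theta[-1]
                ll = self.loglik(spec.resolve(vals))
                return -ll if np.isfinite(ll) else 1e10

            for s in starts[: max(4, n_starts // 2)]:
                x0 = np.array(
                    [np.clip(s[p], *self._bounds(p)) for p in free]
                    + [np.clip(t0, lo, hi)]
                )
                try:
                    r = optimize.minimize(
                        neg_all, x0, method="L-BFGS-B",
                        bounds=bounds + [(lo, hi)], options={"maxiter": 300},
                    )
                except Exception:
                    continue
                if r.fun < best[0]:
                    best = (r.fun, dict(zip(free, r.x[:-1])), float(r.x[-1]))

        fun, vals, t_val = best
        converged = vals is not None and np.isfinite(fun) and fun < 1e9
        if not converged:
            full = spec.resolve({})
            return ModelFit(spec, full, -math.inf, spec.k, math.inf, False)
        if t_free:
            vals = dict(vals, t_shift=t_val)
        full = spec.resolve(vals)
        ll = -fun
        aic = 2 * spec.k - 2 * ll
        return ModelFit(spec, full, float(ll), spec.k, float(aic), True)


# ======================================================================
# model comparison
# ======================================================================
def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """exp(-dAIC/2) normalised over the comparison set."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        raise ValueError("empty model set")
    d = a - a.min()
    w = np.exp(-d / 2)
    return w / w.sum()


def compare_models(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """AIC-sorted table with delta-AIC and Akaike weights.

    Non-converged fits are excluded from the weights (reported with NaN).
    """
    if len(fits) == 0:
        raise ValueError("no fits to compare")
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits")
    w = akaike_weights([f.aic for f in ok])
    for f, wi in zip(ok, w):
        f.akaike_weight = float(wi)
    rows = []
    for f in fits:
        row = {"model": f.spec.name, "logLik": f.loglik, "k": f.k, "AIC": f.aic,
               "converged": f.converged, "AICw": f.akaike_weight if f.converged else np.nan}
        row.update({p: f.params.get(p) for p in _PARAMS})
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df
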