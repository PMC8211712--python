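"""Discrete habitat evolution: Mk models, stochastic character maps and
changes-through-time (CTT) analysis.

Habitat use is modelled as a continuous-time Markov chain on a small set
of categories (six in the reference bundle).  The transition rate matrix
Q is estimated by maximum likelihood with Felsenstein pruning; tips with
unknown habitat enter the likelihood with a vector of ones (equal
probability for each state).  Full character histories consistent with
the tips are then drawn by stochastic mapping (conditional node-state
sampling followed by endpoint-conditioned path sampling via
uniformization), and summarised as the mean number of character changes
per unit of branch length in each time bin (the CTT curve), tested
against simulations under the fitted Q with the rank envelope test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import expm

from .envelope import EnvelopeResult, rank_envelope_test
from .tree import TimeTree

__all__ = [
    "MkModel",
    "MkResults",
    "fit_mk",
    "StochasticMap",
    "sample_stochastic_maps",
    "CTTResult",
    "ctt_curve",
    "ctt_null_test",
    "ancestral_state_frequencies",
]

MISSING = {"?", "", "NA", "nan"}


def _tip_vectors(tree: TimeTree, tip_states: pd.Series, states: List[str]) -> Dict[int, np.ndarray]:
    k = len(states)
    pos = {s: i for i, s in enumerate(states)}
    out = {}
    for lf in tree.leaves():
        lab = lf.taxon.label
        v = np.ones(k)
        if lab in tip_states.index:
            s = tip_states[lab]
            if not (pd.isna(s) or str(s) in MISSING):
                v = np.zeros(k)
                v[pos[str(s)]] = 1.0
        out[lf.index] = v
    return out


def _build_Q(theta: np.ndarray, k: int, structure: str) -> np.ndarray:
    Q = np.zeros((k, k))
    if structure == "ER":
        Q[:] = theta[0]
    elif structure == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = theta
        Q = Q + Q.T
    elif structure == "ARD":
        mask = ~np.eye(k, dtype=bool)
        Q[mask] = theta
    else:
        raise ValueError(f"unknown structure {structure!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _n_rates(k: int, structure: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[structure]


class MkModel:
    """Continuous-time Markov (Mk) model of a discrete character.

    Parameters
    ----------
    tree : TimeTree
    tip_states : Series mapping tip label -> state (NaN or "?" = unknown)
    structure : "ER" (equal rates), "SYM" (symmetric, the default: the
        model is time-reversible with a flat root prior) or "ARD".
    states : optional explicit state ordering.
    """

    def __init__(
        self,
        tree: TimeTree,
        tip_states: pd.Series,
        structure: str = "SYM",
        states: Optional[Sequence[str]] = None,
    ):
        self.tree = tree
        self.tip_states = tip_states
        self.structure = structure
        observed = sorted(
            {str(s) for s in tip_states.dropna() if str(s) not in MISSING}
        )
        if states is None:
            self.states = observed
        else:
            self.states = list(states)
            if not set(observed) <= set(self.states):
                raise ValueError("observed states not in provided state list")
        self._n_observed = len(observed)
        self.k = len(self.states)
        if self.k < 2:
            raise ValueError("need at least 2 states")
        self._tipvec = _tip_vectors(tree, tip_states, self.states)
        self.root_prior = np.full(self.k, 1.0 / self.k)

    # -- pruning likelihood --------------------------------------------
    def loglik(self, Q: np.ndarray) -> float:
        ll, _ = self._partials(Q)
        return ll

    def _partials(self, Q: np.ndarray):
        """Scaled partial likelihoods by postorder node index."""
        part: Dict[int, np.ndarray] = {}
        ll = 0.0
        for nd in self.tree.nodes("postorder"):
            if nd.is_leaf():
                part[nd.index] = self._tipvec[nd.index]
                continue
            v = np.ones(self.k)
            for c in nd.child_nodes():
                P = expm(Q * (c.edge_length or 0.0))
                v = v * (P @ part[c.index])
            s = v.sum()
            if s <= 0 or not np.isfinite(s):
                return -math.inf, part
            ll += math.log(s)
            part[nd.index] = v / s
        ll += math.log(float(self.root_prior @ part[self.tree.root.index]))
        return float(ll), part

    def fit(self, n_starts: int = 3) -> "MkResults":
        if self._n_observed < 2:
            raise ValueError("need at least 2 distinct observed states to fit")
        n_par = _n_rates(self.k, self.structure)
        total_len = max(self.tree.total_edge_length(), 1e-9)
        # crude rate scale: one change per total tree length per state pair
        scale = max(self.k / total_len, 1e-6)
        # rates beyond ~20 expected changes on an average branch are
        # indistinguishable (the chain is saturated) and make downstream
        # path sampling pathological; bound the search there
        mean_branch = total_len / max(len(self.tree.edges()), 1)
        upper = min(1e3, 20.0 / max(mean_branch, 1e-9))
        best = (math.inf, None)

        def neg(log_theta):
            Q = _build_Q(np.exp(log_theta), self.k, self.structure)
            ll = self.loglik(Q)
            return -ll if np.isfinite(ll) else 1e10

        for mult in [1.0, 0.2, 5.0][:n_starts]:
            x0 = np.full(n_par, math.log(min(scale * mult, upper)))
            r = optimize.minimize(
                neg, x0, method="L-BFGS-B",
                bounds=[(math.log(1e-8), math.log(upper))] * n_par,
            )
            if r.fun < best[0]:
                best = (r.fun, r.x)
        rates = np.exp(best[1])
        Q = _build_Q(rates, self.k, self.structure)
        return MkResults(self, Q, rates, -best[0])


@dataclass
class MkResults:
    """Fitted Mk model: rate matrix, likelihood, mapping and marginals."""

    model: MkModel
    Q: np.ndarray
    rates: np.ndarray
    loglik: float

    @property
    def states(self) -> List[str]:
        return self.model.states

    @property
    def aic(self) -> float:
        return 2 * len(self.rates) - 2 * self.loglik

    def summary(self) -> str:
        return (
            f"Mk({self.model.structure}) on {self.model.k} states: "
            f"logL={self.loglik:.3f}, AIC={self.aic:.2f}, "
            f"mean rate={self.rates.mean():.4g}/My"
        )

    # -- exact marginal ancestral states -------------------------------
    def ancestral_marginals(self) -> pd.DataFrame:
        """Exact marginal ancestral state probabilities at internal nodes
        (pruning up-messages combined with root-to-node down-messages)."""
        tree, Q, k = self.model.tree, self.Q, self.model.k
        _, part = self.model._partials(Q)
        down: Dict[int, np.ndarray] = {tree.root.index: self.model.root_prior.copy()}
        P_edge: Dict[int, np.ndarray] = {}
        for nd in tree.nodes("preorder"):
            for c in nd.child_nodes():
                P_edge[c.index] = expm(Q * (c.edge_length or 0.0))
            for c in nd.child_nodes():
                msg = down[nd.index].copy()
                for sib in nd.child_nodes():
                    if sib is c:
                        continue
                    msg = msg * (P_edge[sib.index] @ part[sib.index])
                down[c.index] = msg @ P_edge[c.index]
        rows = {}
        for nd in tree.nodes("postorder"):
            if nd.is_leaf():
                continue
            m = down[nd.index] * part[nd.index]
            rows[nd.index] = m / m.sum()
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.states)

    # -- stochastic mapping --------------------------------------------
    def sample_maps(self, n_maps: int = 100, seed=None) -> List["StochasticMap"]:
        return sample_stochastic_maps(self.model.tree, self, n_maps=n_maps, seed=seed)


def fit_mk(
    tree: TimeTree,
    tip_states: pd.Series,
    structure: str = "SYM",
    states: Optional[Sequence[str]] = None,
    n_starts: int = 3,
) -> MkResults:
    """Convenience wrapper: build and fit an :class:`MkModel`."""
    return MkModel(tree, tip_states, structure, states).fit(n_starts=n_starts)


# ======================================================================
# stochastic maps
# ======================================================================
@dataclass
class StochasticMap:
    """One sampled full history: states at nodes and events along branches.

    ``branch_events[i]`` lists (age, from_state, to_state) along the branch
    above postorder node i, ordered from the rootward end tipward (ages
    decreasing).
    """

    states: List[str]
    node_states: Dict[int, str]
    branch_events: Dict[int, List[Tuple[float, str, str]]]

    def n_changes(self) -> int:
        return sum(len(v) for v in self.branch_events.values())

    def change_ages(self) -> np.ndarray:
        return np.array(
            [age for ev in self.branch_events.values() for age, _, _ in ev]
        )


class _BranchSampler:
    """Endpoint-conditioned CTMC path sampling by uniformization, with
    per-branch caching of the transition matrix and jump-chain powers."""

    def __init__(self, Q: np.ndarray, max_jumps: int = 200):
        self.Q = Q
        self.k = Q.shape[0]
        self.omega = float(max(-np.diag(Q).min(), 1e-12) if np.any(np.diag(Q) < 0) else 1e-12)
        self.omega = float(max(-np.diag(Q).min(), 1e-12))
        self.R = np.eye(self.k) + Q / self.omega
        self.max_jumps = max_jumps
        self._cache: Dict[float, Tuple[np.ndarray, List[np.ndarray]]] = {}

    def _for_length(self, L: float):
        if L not in self._cache:
            P = expm(self.Q * L)
            self._cache[L] = (P, [np.eye(self.k)])
        return self._cache[L]

    def _Rpow(self, powers: List[np.ndarray], m: int) -> np.ndarray:
        while len(powers) <= m:
            powers.append(powers[-1] @ self.R)
        return powers[m]

    def sample_path(self, a: int, b: int, L: float, rng) -> List[Tuple[float, int, int]]:
        """Events (time-from-branch-start, from, to) on a branch of length L
        conditioned on starting in a and ending in b."""
        if L <= 0:
            if a != b:
                raise ValueError("zero-length branch with differing endpoints")
            return []
        P, powers = self._for_length(L)
        pab = max(P[a, b], 1e-300)
        # sample the number of uniformization jumps
        u = rng.random() * pab
        m = 0
        acc = 0.0
        log_pois = -self.omega * L
        pois = math.exp(log_pois)
        while m < self.max_jumps:
            acc += pois * self._Rpow(powers, m)[a, b]
            if acc >= u:
                break
            m += 1
            pois *= self.omega * L / m
        # jump times: order statistics of uniforms
        times = np.sort(rng.random(m)) * L
        # jump states by forward sampling conditioned on the endpoint
        seq = [a]
        for i in range(1, m):
            prev = seq[-1]
            w = self.R[prev, :] * self._Rpow(powers, m - i)[:, b]
            s = w.sum()
            if not np.isfinite(s) or s <= 0:
                # numerically degenerate conditioning (near-zero rates):
                # fall back on the unconditioned jump chain
                w = np.maximum(self.R[prev, :], 0.0)
                s = w.sum()
            seq.append(int(rng.choice(self.k, p=w / s)))
        if m > 0:
            seq.append(b)
        events = []
        for t, s0, s1 in zip(times, seq[:-1], seq[1:]):
            if s0 != s1:
                events.append((float(t), s0, s1))
        return events


def sample_stochastic_maps(
    tree: TimeTree, fit: MkResults, n_maps: int = 100, seed=None
) -> List[StochasticMap]:
    """Draw full character histories consistent with the tip data.

    Node states are sampled from their joint conditional distribution
    (pruning pass, then root-to-tip sampling); within-branch histories are
    sampled conditioned on the branch endpoints by uniformization.
    """
    rng = np.random.default_rng(seed)
    Q, k, states = fit.Q, fit.model.k, fit.states
    model = fit.model
    _, part = model._partials(Q)
    sampler = _BranchSampler(Q)
    P_edge: Dict[int, np.ndarray] = {}
    for nd in tree.nodes("preorder"):
        for c in nd.child_nodes():
            P_edge[c.index] = expm(Q * (c.edge_length or 0.0))
    maps = []
    root = tree.root
    for _ in range(n_maps):
        node_state: Dict[int, int] = {}
        w = model.root_prior * part[root.index]
        node_state[root.index] = int(rng.choice(k, p=w / w.sum()))
        events: Dict[int, List[Tuple[float, str, str]]] = {}
        for nd in tree.nodes("preorder"):
            for c in nd.child_nodes():
                sp = node_state[nd.index]
                w = P_edge[c.index][sp, :] * part[c.index]
                sc = int(rng.choice(k, p=w / w.sum()))
                node_state[c.index] = sc
                L = c.edge_length or 0.0
                path = sampler.sample_path(sp, sc, L, rng)
                top_age = nd.age_my
                events[c.index] = [
                    (top_age - t, states[s0], states[s1]) for t, s0, s1 in path
                ]
        maps.append(
            StochasticMap(
                states,
                {i: states[s] for i, s in node_state.items()},
                events,
            )
        )
    return maps


def history_to_map(tree: TimeTree, tips_hist, states: List[str]) -> StochasticMap:
    """Convert a forward-simulation TrueHistory into a StochasticMap."""
    hist = tips_hist
    return StochasticMap(
        states,
        {i: s for i, s in hist.node_values.items()},
        {i: list(ev) for i, ev in hist.branch_events.items()},
    )


# ======================================================================
# changes through time
# ======================================================================
@dataclass
class CTTResult:
    bin_edges: np.ndarray  # ages, descending from crown to 0
    observed: np.ndarray  # mean changes / edge length per bin
    edge_length: np.ndarray  # total edge length per bin
    null_curves: Optional[np.ndarray] = None
    envelope: Optional[EnvelopeResult] = None

    @property
    def verdict(self) -> str:
        if self.envelope is None:
            return "untested"
        return "Non-random" if self.envelope.p_upper < 0.05 else "Random"


def _edge_length_per_bin(tree: TimeTree, edges: np.ndarray) -> np.ndarray:
    out = np.zeros(len(edges) - 1)
    for _, a_child, a_parent in tree.edges():
        for i in range(len(out)):
            hi, lo = edges[i], edges[i + 1]
            out[i] += max(0.0, min(a_parent, hi) - max(a_child, lo))
    return out


def _changes_per_bin(m: StochasticMap, edges: np.ndarray) -> np.ndarray:
    ages = m.change_ages()
    out = np.zeros(len(edges) - 1)
    for a in ages:
        i = int(np.searchsorted(-edges, -a, side="left")) - 1
        i = min(max(i, 0), len(out) - 1)
        out[i] += 1
    return out


def ctt_curve(tree: TimeTree, maps: Sequence[StochasticMap], n_bins: int = 50) -> CTTResult:
    """Mean number of character changes per total branch length per bin."""
    if len(maps) < 1:
        raise ValueError("need at least one map")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    T = tree.crown_age
    edges = np.linspace(T, 0.0, n_bins + 1)
    length = _edge_length_per_bin(tree, edges)
    counts = np.mean([_changes_per_bin(m, edges) for m in maps], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(length > 0, counts / np.maximum(length, 1e-300), 0.0)
    return CTTResult(edges, curve, length)


def ctt_null_test(
    tree: TimeTree,
    fit: MkResults,
    observed: CTTResult,
    n_sims: int = 200,
    seed=None,
    n_maps_per_sim: Optional[int] = None,
    conditioned: bool = True,
) -> CTTResult:
    """Rank-envelope test of the observed CTT curve against the fitted Q.

    Each null replicate simulates tip data forward under Q (root drawn
    from the flat prior).  With ``conditioned=True`` (default) the null
    curve is then built exactly like the observed one - stochastic maps
    conditioned on the simulated tips, averaged - making null and observed
    curves exchangeable under the model.  ``conditioned=False`` instead
    uses each free forward history directly as one null curve.
    """
    from .simulate import sim_discrete

    if n_sims < 100:
        warnings.warn("fewer than 100 null simulations: coarse p resolution")
    rng = np.random.default_rng(seed)
    edges = observed.bin_edges
    nulls = np.empty((n_sims, len(edges) - 1))
    n_inner = n_maps_per_sim or 10
    for i in range(n_sims):
        tips, hist = sim_discrete(tree, fit.Q, states=fit.states, seed=rng)
        if conditioned:
            try:
                refit = MkResults(
                    MkModel(tree, tips, fit.model.structure, states=fit.states),
                    fit.Q, fit.rates, math.nan,
                )
                sim_maps = refit.sample_maps(n_inner, seed=rng)
            except ValueError:  # degenerate: <2 observed states simulated
                sim_maps = [history_to_map(tree, hist, fit.states)]
        else:
            sim_maps = [history_to_map(tree, hist, fit.states)]
        nulls[i] = ctt_curve(tree, sim_maps, len(edges) - 1).observed
    env = rank_envelope_test(observed.observed, nulls)
    return CTTResult(edges, observed.observed, observed.edge_length, nulls, env)


def ancestral_state_frequencies(
    tree: TimeTree, maps: Sequence[StochasticMap]
) -> pd.DataFrame:
    """Empirical node-state frequencies across maps (rows sum to 1)."""
    if not maps:
        raise ValueError("no maps")
    states = maps[0].states
    idx = [nd.index for nd in tree.nodes("postorder") if not nd.is_leaf()]
    counts = pd.DataFrame(0.0, index=idx, columns=states)
    for m in maps:
        for i in idx:
            counts.loc[i, m.node_states[i]] += 1
    return counts / len(maps)
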