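"""Synthetic data with the statistical structure the analyses assume.

The generators here stand in for the empirical inputs of a clade-scale
radiation study: an ultrametric chronogram with a diversification-rate
shift, discrete habitat states evolving under a continuous-time Markov
process, correlated continuous traits under BM/EB/OU (optionally with a
fixed-time regime shift), and geographic coordinates under spherical
Brownian motion.  :func:`make_reference_dataset` assembles a full
study-dimensioned bundle (377 tips, crown age 47 My, a speciation-rate
shift at 15.7 My, six monophyletic focal clades of sizes 28/41/29/41/38/25,
partially missing habitat and trait data) so that every downstream stage
is testable without external data.

All stochastic operations take an explicit seed or ``numpy.random.Generator``;
there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import os
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
import yaml

from .tree import TimeTree, TreeError

__all__ = [
    "SimulationSpec",
    "TrueHistory",
    "ReferenceBundle",
    "sim_tree",
    "sim_conditioned_tree",
    "sim_discrete",
    "sim_traits",
    "sim_regime_traits",
    "make_reference_dataset",
    "write_bundle",
    "read_bundle",
]

CLADE_SIZES = {
    "Pontic": 28,
    "Pannonian": 41,
    "SouthDinaric": 29,
    "WestBalkan": 41,
    "Apennine": 38,
    "NorthDinaric": 25,
}

HABITATS = [
    "fissure",
    "interstitial",
    "cave_lake",
    "cave_stream",
    "shallow_subterranean",
    "specific_chemistry",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationSpec:
    """Parameters of a (possibly diversity-dependent, possibly shifted)
    birth-death process used to generate trees.

    Rates are per lineage per My; the speciation rate at standing
    diversity N is ``max(0, lambda0 - (lambda0 - mu) * N / K)`` when a
    carrying capacity K is set.  ``shift_age`` is an age in My before the
    present at which the process switches to the post-shift parameters.
    """

    lambda0: float
    mu: float = 0.0
    K: Optional[float] = None
    shift_age: Optional[float] = None
    lambda2: Optional[float] = None
    mu2: Optional[float] = None
    K2: Optional[float] = None
    n_tips: Optional[int] = None
    crown_age: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.lambda0 < 0 or self.mu < 0:
            raise ValueError("rates must be non-negative")
        if self.K is not None and self.K <= 1:
            raise ValueError("K must exceed 1")
        if self.n_tips is None and self.crown_age is None:
            raise ValueError("need a target tip count or crown age")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("tip count must be >= 2")

    def rates_at(self, age: float, n_extant: int) -> Tuple[float, float]:
        """(speciation, extinction) per lineage at a given age and diversity."""
        if self.shift_age is not None and age < self.shift_age:
            lam0 = self.lambda2 if self.lambda2 is not None else self.lambda0
            mu = self.mu2 if self.mu2 is not None else self.mu
            K = self.K2 if self.K2 is not None else self.K
        else:
            lam0, mu, K = self.lambda0, self.mu, self.K
        if K is not None:
            lam = max(0.0, lam0 - (lam0 - mu) * n_extant / K)
        else:
            lam = lam0
        return lam, mu


@dataclass
class TrueHistory:
    """Ground truth of a simulation, for recovery tests.

    ``branch_events`` maps a branch (postorder index of its child node) to
    the ordered list of (age, from_state, to_state) events along it;
    ``node_values`` holds true node states/trait values; ``painting`` the
    true regime of each branch where applicable.
    """

    branch_events: Dict[int, List[Tuple[float, object, object]]] = field(default_factory=dict)
    node_values: Dict[int, object] = field(default_factory=dict)
    painting: Optional[Dict[int, object]] = None
    params: Dict[str, object] = field(default_factory=dict)

    def n_events(self) -> int:
        return sum(len(v) for v in self.branch_events.values())


# ======================================================================
# tree simulation
# ======================================================================
class _Lineage:
    __slots__ = ("parent", "birth_time", "death_time", "children", "alive")

    def __init__(self, parent, birth_time):
        self.parent = parent
        self.birth_time = birth_time
        self.death_time = None
        self.children = []
        self.alive = True


def _forward_sim(spec: SimulationSpec, rng: np.random.Generator, horizon: float):
    """One forward pass from 2 crown lineages; returns (lineages, end_time).

    ``horizon`` is the simulation duration (= crown age).  Time runs
    forward from 0 (crown) and ages are horizon - t.
    """
    roots = [_Lineage(None, 0.0), _Lineage(None, 0.0)]
    alive = list(roots)
    t = 0.0
    while alive:
        n = len(alive)
        lam, mu = spec.rates_at(horizon - t, n)
        total = n * (lam + mu)
        if total <= 0:
            t_next = horizon
        else:
            t_next = t + rng.exponential(1.0 / total)
        # a parameter shift can change rates before the next event fires:
        # step to the shift boundary and redraw (memorylessness)
        if spec.shift_age is not None:
            t_shift = horizon - spec.shift_age
            if t < t_shift <= t_next and t_next < horizon:
                t = t_shift
                continue
            if t < t_shift < horizon <= t_next:
                t = t_shift
                continue
        if t_next >= horizon:
            return roots, alive, horizon
        t = t_next
        i = rng.integers(len(alive))
        lin = alive[i]
        if rng.random() < lam / (lam + mu) if (lam + mu) > 0 else True:
            c1, c2 = _Lineage(lin, t), _Lineage(lin, t)
            lin.children = [c1, c2]
            lin.alive = False
            lin.death_time = t
            alive[i] = c1
            alive.append(c2)
        else:
            lin.alive = False
            lin.death_time = t
            alive.pop(i)
    return roots, alive, t


def _forward_sim_to_n(spec: SimulationSpec, rng: np.random.Generator):
    """Forward pass stopped the instant before diversity would leave its
    first visit to the target tip count (so the final inter-event interval
    is a full exponential waiting time, matching the pure-birth null)."""
    n_target = spec.n_tips
    roots = [_Lineage(None, 0.0), _Lineage(None, 0.0)]
    alive = list(roots)
    t = 0.0
    while alive:
        n = len(alive)
        lam, mu = spec.rates_at(math.inf, n)  # target-n mode: no age shift
        total = n * (lam + mu)
        if total <= 0:
            return None
        dt = rng.exponential(1.0 / total)
        if n == n_target:
            return roots, alive, t + dt
        t = t + dt
        i = rng.integers(len(alive))
        lin = alive[i]
        if rng.random() < (lam / (lam + mu)):
            c1, c2 = _Lineage(lin, t), _Lineage(lin, t)
            lin.children = [c1, c2]
            lin.alive = False
            lin.death_time = t
            alive[i] = c1
            alive.append(c2)
        else:
            lin.alive = False
            lin.death_time = t
            alive.pop(i)
    return None


def _lineages_to_tree(roots, end_time: float) -> Optional[TimeTree]:
    """Prune extinct lineages and build the reconstructed TimeTree."""

    def survives(lin) -> bool:
        if lin.alive:
            return True
        return any(survives(c) for c in lin.children)

    if not (survives(roots[0]) and survives(roots[1])):
        return None  # crown did not survive

    counter = [0]

    def build(lin, start_time):
        # returns dendropy node for the surviving part of this lineage
        if lin.alive:
            nd = dendropy.Node(edge_length=end_time - start_time)
            counter[0] += 1
            nd.label_tmp = f"t{counter[0]}"
            return nd
        kids = [c for c in lin.children if survives(c)]
        if len(kids) == 1:
            return build(kids[0], start_time)
        nd = dendropy.Node(edge_length=lin.death_time - start_time)
        for c in kids:
            nd.add_child(build(c, lin.death_time))
        return nd

    root = dendropy.Node(edge_length=None)
    for r in roots:
        root.add_child(build(r, 0.0))
    tree = dendropy.Tree(seed_node=root)
    tns = tree.taxon_namespace
    for lf in tree.leaf_node_iter():
        lf.taxon = tns.new_taxon(label=lf.label_tmp)
    tree.is_rooted = True
    return TimeTree(tree)


def sim_tree(spec: SimulationSpec, seed=None, max_retries: int = 10_000) -> TimeTree:
    """Simulate a reconstructed ultrametric tree under ``spec``.

    Forward birth-death simulation from two crown lineages with extinct
    lineages pruned, conditioned on survival of both crown lineages and,
    when ``spec.n_tips`` is set, on the target tip count (first-passage
    stopping).  Resimulates on failure up to ``max_retries``.
    """
    rng = _rng(spec.seed if seed is None else seed)
    for _ in range(max_retries):
        if spec.n_tips is not None and spec.crown_age is None:
            if spec.shift_age is not None:
                raise ValueError(
                    "age-shifted processes need a crown-age target "
                    "(the shift age is measured from the present)"
                )
            res = _forward_sim_to_n(spec, rng)
            if res is None:
                continue
            roots, alive, end = res
            if len(alive) != spec.n_tips:
                continue
            tt = _lineages_to_tree(roots, end)
            if tt is not None and tt.n_tips == spec.n_tips:
                return tt
        else:
            roots, alive, end = _forward_sim(spec, rng, spec.crown_age)
            tt = _lineages_to_tree(roots, end)
            if tt is None:
                continue
            if spec.n_tips is not None and tt.n_tips != spec.n_tips:
                continue
            return tt
    raise TreeError(f"no acceptable tree in {max_retries} simulations")


# ----------------------------------------------------------------------
# pure-birth trees conditioned on (n, crown age): point-process sampler
# ----------------------------------------------------------------------
def sim_conditioned_tree(
    n_tips: int,
    crown_age: float,
    rate_fn: Optional[Callable[[float], float]] = None,
    shift_age: Optional[float] = None,
    lambda1: float = 0.1,
    lambda2: Optional[float] = None,
    rates: Optional[Sequence[float]] = None,
    change_ages: Optional[Sequence[float]] = None,
    seed=None,
    tip_prefix: str = "t",
) -> TimeTree:
    """Pure-birth tree conditioned on both tip count and crown age.

    Under a time-varying pure-birth process with rate ``lambda(t)`` (t an
    age), the n-2 non-crown node ages conditioned on n tips and crown age T
    are iid with density proportional to ``lambda(t) * exp(-L(t))`` where
    ``L(t)`` is the cumulative rate from the present back to age t.  Ages
    are drawn by piecewise-analytic inversion for piecewise-constant rates
    (either ``lambda1``/``lambda2`` with one ``shift_age``, or ``rates``
    with descending ``change_ages`` for multi-phase histories), and the
    topology by forward random joining.  This sampler powers fixtures that
    must hit exact dimensions.
    """
    rng = _rng(seed)
    if n_tips < 2:
        raise ValueError("n_tips >= 2")
    if rate_fn is None:
        if rates is None:
            if lambda2 is None or shift_age is None:
                rates, change_ages = [lambda1], []
            else:
                rates, change_ages = [lambda1, lambda2], [shift_age]
        rates = [float(r) for r in rates]
        change_ages = sorted(float(a) for a in (change_ages or []))
        if len(change_ages) != len(rates) - 1:
            raise ValueError("need one change age per rate boundary")
        # segment bounds from the present upward; youngest rate last
        bounds = [0.0] + change_ages + [float(crown_age)]
        seg_rates = list(reversed(rates))  # rates given old -> young

        def cum(t):  # integral of rate from 0 (present) back to age t
            tot = 0.0
            for j in range(len(seg_rates)):
                lo, hi = bounds[j], bounds[j + 1]
                if t <= lo:
                    break
                tot += seg_rates[j] * (min(t, hi) - lo)
            return tot

        def inv_cum(v):
            tot = 0.0
            for j in range(len(seg_rates)):
                lo, hi = bounds[j], bounds[j + 1]
                seg = seg_rates[j] * (hi - lo)
                if tot + seg >= v or j == len(seg_rates) - 1:
                    return lo + (v - tot) / max(seg_rates[j], 1e-300)
                tot += seg
            return bounds[-1]

    else:  # numeric fallback for arbitrary rate functions
        grid = np.linspace(0, crown_age, 4097)
        lam_g = np.array([rate_fn(a) for a in grid])
        cums = np.concatenate([[0], np.cumsum((lam_g[1:] + lam_g[:-1]) / 2 * np.diff(grid))])

        def cum(t):
            return float(np.interp(t, grid, cums))

        def inv_cum(v):
            return float(np.interp(v, cums, grid))

    M = 1.0 - math.exp(-cum(crown_age))
    u = rng.uniform(0.0, M, size=n_tips - 2)
    ages = np.array([inv_cum(-math.log1p(-ui)) for ui in u])
    return _tree_from_ages(np.sort(ages)[::-1], crown_age, rng, tip_prefix)


def _tree_from_ages(ages_desc, crown_age, rng, tip_prefix="t") -> TimeTree:
    """Build a random-joining (Yule) topology from given node ages."""
    root = dendropy.Node()
    root.depth = 0.0
    open_lin = []  # nodes awaiting either a split or tip closure
    for _ in range(2):
        c = dendropy.Node()
        c.depth = 0.0
        root.add_child(c)
        open_lin.append(c)
    for age in ages_desc:
        depth = crown_age - age
        i = rng.integers(len(open_lin))
        nd = open_lin[i]
        nd.split_depth = depth
        kids = []
        for _ in range(2):
            c = dendropy.Node()
            c.depth = depth
            nd.add_child(c)
            kids.append(c)
        open_lin[i] = kids[0]
        open_lin.append(kids[1])
    # assign edge lengths
    k = [0]

    def finish(nd, parent_depth):
        if nd.child_nodes():
            d = nd.split_depth if hasattr(nd, "split_depth") else nd.depth
        if not nd.child_nodes():
            nd.edge_length = crown_age - parent_depth
            k[0] += 1
            nd.label_tmp = f"{tip_prefix}{k[0]}"
            return
        nd.edge_length = None if nd.parent_node is None else d - parent_depth
        for c in nd.child_nodes():
            finish(c, d)

    root.split_depth = 0.0
    for c in root.child_nodes():
        finish(c, 0.0)
    tree = dendropy.Tree(seed_node=root)
    tns = tree.taxon_namespace
    for lf in tree.leaf_node_iter():
        lf.taxon = tns.new_taxon(label=lf.label_tmp)
    tree.is_rooted = True
    return TimeTree(tree)


# ======================================================================
# discrete characters
# ======================================================================
def check_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be >= 0")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(Q))):
        raise ValueError("rows of Q must sum to 0")
    return Q


def sim_discrete(
    tree: TimeTree,
    Q: np.ndarray,
    root_dist: Optional[Sequence[float]] = None,
    states: Optional[Sequence[str]] = None,
    seed=None,
) -> Tuple[pd.Series, TrueHistory]:
    """Exact (Gillespie) simulation of a Markov chain along every branch.

    Returns tip states (indexed by tip label) and the full event history.
    """
    rng = _rng(seed)
    Q = check_rate_matrix(Q)
    k = Q.shape[0]
    states = list(states) if states is not None else list(range(k))
    p0 = np.full(k, 1.0 / k) if root_dist is None else np.asarray(root_dist, float)
    p0 = p0 / p0.sum()

    hist = TrueHistory(params={"Q": Q, "states": states})
    node_state: Dict[int, int] = {}
    root = tree.root
    node_state[root.index] = int(rng.choice(k, p=p0))
    for nd in tree.nodes("preorder"):
        if nd.parent_node is None:
            continue
        s = node_state[nd.parent_node.index]
        t0, t1 = nd.parent_node.age_my, nd.age_my  # ages decrease along branch
        events = []
        t = t0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t = t - rng.exponential(1.0 / rate)
            if t <= t1:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s_new = int(rng.choice(k, p=probs))
            events.append((t, states[s], states[s_new]))
            s = s_new
        node_state[nd.index] = s
        hist.branch_events[nd.index] = events
    hist.node_values = {i: states[s] for i, s in node_state.items()}
    tips = pd.Series(
        {lf.taxon.label: states[node_state[lf.index]] for lf in tree.leaves()}
    ).sort_index()
    return tips, hist


# ======================================================================
# continuous traits
# ======================================================================
@dataclass
class TraitModel:
    """Specification of a (possibly two-phase) multivariate trait process.

    ``mode`` one of "BM", "EB", "OU".  For EB/ACDC the per-My rate-change
    exponent ``r`` applies to time since the root (negative r = early
    burst).  For OU, ``alpha`` is the attraction strength and ``theta``
    the optimum vector.  A second phase starting at ``shift_age`` (an age,
    My) may change the mode and parameters.
    """

    Sigma: np.ndarray
    mode: str = "BM"
    r: float = 0.0
    alpha: float = 0.0
    theta: Optional[np.ndarray] = None
    root_value: Optional[np.ndarray] = None
    shift_age: Optional[float] = None
    mode2: Optional[str] = None
    Sigma2: Optional[np.ndarray] = None
    r2: float = 0.0
    alpha2: float = 0.0
    theta2: Optional[np.ndarray] = None

    def __post_init__(self):
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, float))
        try:
            np.linalg.cholesky(self.Sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("Sigma must be positive definite") from exc
        if self.mode == "OU" and self.alpha <= 0:
            raise ValueError("OU requires alpha > 0")
        if self.Sigma2 is not None:
            self.Sigma2 = np.atleast_2d(np.asarray(self.Sigma2, float))
            np.linalg.cholesky(self.Sigma2)

    @property
    def p(self) -> int:
        return self.Sigma.shape[0]


def _phase_params(model: TraitModel, age: float):
    if model.shift_age is not None and age < model.shift_age:
        return (
            model.mode2 or model.mode,
            model.Sigma2 if model.Sigma2 is not None else model.Sigma,
            model.r2,
            model.alpha2,
            model.theta2 if model.theta2 is not None else model.theta,
        )
    return model.mode, model.Sigma, model.r, model.alpha, model.theta


def _simulate_segment(x, mode, Sigma, r, alpha, theta, a0, a1, phase_start_age, rng):
    """Propagate a trait vector over one branch segment from age a0 to a1."""
    L = np.linalg.cholesky(Sigma)
    dt = a0 - a1
    if dt <= 0:
        return x
    if mode == "BM":
        eff = dt
        return x + L @ rng.standard_normal(len(x)) * math.sqrt(eff)
    if mode in ("EB", "ACDC"):
        # rate sigma^2 * exp(r * time since the phase started); for a
        # single-phase model the phase starts at the root
        s0, s1 = phase_start_age - a0, phase_start_age - a1
        if abs(r) < 1e-12:
            eff = dt
        else:
            eff = (math.exp(r * s1) - math.exp(r * s0)) / r
        return x + L @ rng.standard_normal(len(x)) * math.sqrt(eff)
    if mode == "OU":
        th = np.zeros(len(x)) if theta is None else np.asarray(theta, float)
        decay = math.exp(-alpha * dt)
        var = (1.0 - math.exp(-2 * alpha * dt)) / (2 * alpha)
        mean = th + (x - th) * decay
        return mean + L @ rng.standard_normal(len(x)) * math.sqrt(var)
    raise ValueError(f"unknown mode {mode!r}")


def sim_traits(
    tree: TimeTree, model: TraitModel, seed=None, trait_names: Optional[Sequence[str]] = None
) -> Tuple[pd.DataFrame, TrueHistory]:
    """Simulate correlated continuous traits tip-ward along the tree."""
    rng = _rng(seed)
    p = model.p
    crown = tree.crown_age
    x0 = np.zeros(p) if model.root_value is None else np.asarray(model.root_value, float)
    hist = TrueHistory(params={"model": model})
    vals: Dict[int, np.ndarray] = {tree.root.index: x0.copy()}
    for nd in tree.nodes("preorder"):
        if nd.parent_node is None:
            continue
        a0, a1 = nd.parent_node.age_my, nd.age_my
        x = vals[nd.parent_node.index].copy()
        cuts = [a0]
        if model.shift_age is not None and a1 < model.shift_age < a0:
            cuts.append(model.shift_age)
        cuts.append(a1)
        for s0, s1 in zip(cuts[:-1], cuts[1:]):
            mode, Sig, r, alpha, theta = _phase_params(model, (s0 + s1) / 2)
            in_phase2 = model.shift_age is not None and (s0 + s1) / 2 < model.shift_age
            phase_start = model.shift_age if in_phase2 else crown
            x = _simulate_segment(x, mode, Sig, r, alpha, theta, s0, s1, phase_start, rng)
        vals[nd.index] = x
    hist.node_values = {i: v.copy() for i, v in vals.items()}
    names = list(trait_names) if trait_names is not None else [f"trait{i+1}" for i in range(p)]
    data = {lf.taxon.label: vals[lf.index] for lf in tree.leaves()}
    return pd.DataFrame(data, index=names).T.sort_index(), hist


def sim_regime_traits(
    tree: TimeTree,
    painting: Mapping[int, object],
    optima: Mapping[object, Sequence[float]],
    alpha: float,
    sigma2,
    root_regime: Optional[object] = None,
    seed=None,
) -> Tuple[pd.DataFrame, TrueHistory]:
    """Multi-optimum OU simulation whose optimum follows a branch painting.

    ``painting`` maps every branch (postorder index of its child node) to a
    regime key; ``optima`` maps regime keys to optimum vectors.
    """
    rng = _rng(seed)
    if alpha <= 0:
        raise ValueError("alpha > 0 required")
    first = next(iter(optima.values()))
    p = len(np.atleast_1d(first))
    Sigma = np.eye(p) * float(sigma2) if np.isscalar(sigma2) else np.asarray(sigma2, float)
    for nd, _, _ in tree.edges():
        if nd.index not in painting:
            raise ValueError(f"branch {nd.index} not covered by painting")
    if root_regime is None:
        root_regime = painting[max(c.index for c in tree.root.child_nodes())]
    x0 = np.asarray(optima[root_regime], float).copy()
    vals = {tree.root.index: x0}
    for nd in tree.nodes("preorder"):
        if nd.parent_node is None:
            continue
        th = np.asarray(optima[painting[nd.index]], float)
        x = _simulate_segment(
            vals[nd.parent_node.index].copy(),
            "OU",
            Sigma,
            0.0,
            alpha,
            th,
            nd.parent_node.age_my,
            nd.age_my,
            tree.crown_age,
            rng,
        )
        vals[nd.index] = x
    hist = TrueHistory(
        node_values={i: v.copy() for i, v in vals.items()},
        painting=dict(painting),
        params={"alpha": alpha, "optima": dict(optima), "sigma2": sigma2},
    )
    names = [f"trait{i+1}" for i in range(p)]
    data = {lf.taxon.label: vals[lf.index] for lf in tree.leaves()}
    return pd.DataFrame(data, index=names).T.sort_index(), hist


# ======================================================================
# reference bundle
# ======================================================================
@dataclass
class ReferenceBundle:
    """A study-dimensioned synthetic dataset."""

    tree: TimeTree
    habitats: pd.Series  # tip -> habitat, NaN = unknown
    traits: pd.DataFrame  # tip x 11 traits, NaN rows = unmeasured
    clades: Dict[str, List[str]]
    coordinates: pd.DataFrame  # tip x (lon, lat)
    manifest: Dict[str, object]
    truth: Dict[str, object] = field(default_factory=dict)


# generator defaults: crown age and shift age as the study states them;
# speciation rates adapted from the fitted shift-in-speciation-rate model
# (slow old regime, fast young regime) and scaled so that a two-rate
# pure-birth process conditioned on 377 tips in 47 My is consistent.
REFERENCE_PARAMS = dict(
    n_tips=377,
    crown_age=47.0,
    shift_age=15.7,
    slowdown_age=5.0,  # niche filling: the burst decelerates near the present
    lambda_old=0.06,
    lambda_young=0.26,
    lambda_tail=0.05,
    habitat_rate=0.012,
    n_habitat_known=331,
    n_traits_measured=256,
    n_traits=11,
    trait_sigma2=0.02,
    trait_accel=6.0,  # post-shift rate multiplier emulating the late burst
    trait_corr=0.3,
)


def make_reference_dataset(seed: int = 0) -> ReferenceBundle:
    """Build the full synthetic study bundle (deterministic given seed)."""
    rng = _rng(seed)
    P = REFERENCE_PARAMS
    clade_sizes = dict(CLADE_SIZES)
    n_background = P["n_tips"] - sum(clade_sizes.values())  # 175

    # --- backbone: background tips + one placeholder stem per clade -----
    nb = n_background + len(clade_sizes)
    backbone = sim_conditioned_tree(
        nb,
        P["crown_age"],
        rates=[P["lambda_old"], P["lambda_young"] * 0.55, P["lambda_tail"]],
        change_ages=[P["shift_age"], P["slowdown_age"]],
        seed=rng,
        tip_prefix="bg",
    )
    # choose placeholder tips whose parent is old enough to host a radiation
    leaves = backbone.leaves()
    parent_age = {lf.taxon.label: lf.parent_node.age_my for lf in leaves}
    eligible = sorted(
        [l for l, a in parent_age.items() if a > 8.0],
        key=lambda l: -parent_age[l],
    )
    if len(eligible) < len(clade_sizes):
        eligible = sorted(parent_age, key=lambda l: -parent_age[l])
    placeholders = {}
    chosen = list(rng.choice(eligible[: max(len(clade_sizes) * 3, 18)],
                             size=len(clade_sizes), replace=False))
    for name, ph in zip(clade_sizes, chosen):
        placeholders[name] = ph

    # --- graft clade subtrees -----------------------------------------
    newick = backbone.to_newick()
    for name, size in clade_sizes.items():
        ph = placeholders[name]
        stem_top = parent_age[ph]
        crown = min(stem_top * 0.85, float(rng.uniform(11.0, 15.5)))
        sub = sim_conditioned_tree(
            size, crown,
            rates=[P["lambda_young"], P["lambda_tail"]],
            change_ages=[P["slowdown_age"]],
            seed=rng, tip_prefix=f"{name}_",
        )
        subnwk = sub.to_newick().strip().rstrip(";")
        # replace placeholder tip "ph:len" by the subtree with adjusted stem
        old = f"{ph}:"
        i = newick.index(old)
        j = i + len(old)
        k = j
        while newick[k] not in ",)":
            k += 1
        tip_len = float(newick[j:k])
        stem = tip_len - crown
        newick = newick[:i] + f"{subnwk}:{stem:.10f}" + newick[k:]
    tree = TimeTree.from_newick(newick)
    assert tree.n_tips == P["n_tips"]
    clades = {
        name: sorted(l for l in tree.tip_labels if l.startswith(f"{name}_"))
        for name in clade_sizes
    }

    # --- habitats ------------------------------------------------------
    q = P["habitat_rate"]
    Q = np.full((6, 6), q)
    np.fill_diagonal(Q, -5 * q)
    habitats, hab_truth = sim_discrete(
        tree, Q, root_dist=None, states=HABITATS, seed=rng
    )
    n_missing_hab = P["n_tips"] - P["n_habitat_known"]
    hide = rng.choice(tree.tip_labels, size=n_missing_hab, replace=False)
    habitats = habitats.astype(object)
    habitats.loc[sorted(hide)] = np.nan

    # --- traits --------------------------------------------------------
    p = P["n_traits"]
    corr = np.full((p, p), P["trait_corr"])
    np.fill_diagonal(corr, 1.0)
    Sigma = corr * P["trait_sigma2"]
    model = TraitModel(
        Sigma=Sigma,
        mode="BM",
        shift_age=P["shift_age"],
        mode2="BM",
        Sigma2=Sigma * P["trait_accel"],
    )
    names = ["body_length_mm"] + [f"resid_trait{i}" for i in range(1, p)]
    traits, trait_truth = sim_traits(tree, model, seed=rng, trait_names=names)
    # body length in mm: exponentiate a BM on log-size around 10 mm
    traits["body_length_mm"] = 10.0 * np.exp(traits["body_length_mm"])
    n_missing_tr = P["n_tips"] - P["n_traits_measured"]
    hide_t = rng.choice(tree.tip_labels, size=n_missing_tr, replace=False)
    traits.loc[sorted(hide_t)] = np.nan

    # --- geography: spherical BM from a Western-European origin --------
    from .geo import to_cartesian, from_cartesian

    origin = to_cartesian(0.0, 47.0)
    geo_model = TraitModel(Sigma=np.eye(3) * 2.0e-4, mode="BM", root_value=origin)
    xyz, _ = sim_traits(tree, geo_model, seed=rng, trait_names=["x", "y", "z"])
    lonlat = np.array([from_cartesian(v) for v in xyz.to_numpy()])
    coordinates = pd.DataFrame(lonlat, index=xyz.index, columns=["lon", "lat"])

    manifest = {"seed": int(seed) if not isinstance(seed, np.random.Generator) else None,
                "params": {k: (float(v) if isinstance(v, (int, float)) else v)
                           for k, v in P.items()},
                "clade_sizes": clade_sizes}
    truth = {"habitat_history": hab_truth, "trait_history": trait_truth,
             "Q": Q, "trait_model": model}
    return ReferenceBundle(tree, habitats, traits, clades, coordinates, manifest, truth)


# ----------------------------------------------------------------------
# bundle I/O (Newick + tab-separated tables + YAML manifest)
# ----------------------------------------------------------------------
def write_bundle(bundle: ReferenceBundle, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    bundle.tree.write(os.path.join(outdir, "tree.nwk"))
    hab = bundle.habitats.rename("habitat").to_frame()
    hab.index.name = "tip"
    hab.fillna("?").to_csv(os.path.join(outdir, "habitats.tsv"), sep="\t")
    tr = bundle.traits.copy()
    tr.index.name = "tip"
    tr.to_csv(os.path.join(outdir, "traits.tsv"), sep="\t")
    co = bundle.coordinates.copy()
    co.index.name = "tip"
    co.to_csv(os.path.join(outdir, "coordinates.tsv"), sep="\t")
    with open(os.path.join(outdir, "clades.tsv"), "w") as fh:
        fh.write("clade\ttip\n")
        for name, tips in bundle.clades.items():
            for t in tips:
                fh.write(f"{name}\t{t}\n")
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(bundle.manifest, fh)


def read_bundle(indir: str) -> ReferenceBundle:
    tree = TimeTree.from_file(os.path.join(indir, "tree.nwk"))
    hab = pd.read_csv(os.path.join(indir, "habitats.tsv"), sep="\t", index_col=0)[
        "habitat"
    ].replace("?", np.nan)
    traits = pd.read_csv(os.path.join(indir, "traits.tsv"), sep="\t", index_col=0)
    coords = pd.read_csv(os.path.join(indir, "coordinates.tsv"), sep="\t", index_col=0)
    cl = pd.read_csv(os.path.join(indir, "clades.tsv"), sep="\t")
    clades = {k: sorted(v["tip"]) for k, v in cl.groupby("clade")}
    with open(os.path.join(indir, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    return ReferenceBundle(tree, hab, traits, clades, coords, manifest)
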