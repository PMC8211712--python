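import warnings

import numpy as np
import pandas as pd
import pytest

from karstrad import TimeTree
from karstrad.simulate import make_reference_dataset, sim_conditioned_tree

warnings.filterwarnings("ignore", message="probability mass at the truncation")
warnings.filterwarnings("ignore", message="polytomies resolved")
warnings.filterwarnings("ignore", message="fewer than 100")


@pytest.fixture
def three_tip():
    return TimeTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four():
    return TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def medium_tree():
    """50-tip pure-birth tree for generic property checks."""
    return sim_conditioned_tree(50, 30.0, lambda1=0.15, seed=42)


@pytest.fixture(scope="session")
def bundle():
    """The study-dimensioned synthetic reference bundle."""
    return make_reference_dataset(seed=1)


# ----------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ----------------------------------------------------------------------
def brute_disparity(X: np.ndarray) -> float:
    """Double-loop mean squared pairwise Euclidean distance."""
    X = np.atleast_2d(X)
    n = len(X)
    if n < 2:
        return 0.0
    tot, cnt = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += float(np.sum((X[i] - X[j]) ** 2))
            cnt += 1
    return tot / cnt


def dense_expm_dd_loglik(bt, lam0, mu, K, L=400):
    """Dense matrix-exponential propagation of the hidden-lineage master
    equation (independent of the sparse expm_multiply production path)."""
    import math

    from scipy.linalg import expm

    bt = np.sort(np.asarray(bt, float))[::-1]
    T = bt[0]

    def lamN(N):
        if K is None:
            return lam0
        return max(0.0, lam0 - (lam0 - mu) * N / K)

    def gen(k):
        A = np.zeros((L, L))
        for n in range(L):
            lm = lamN(n + k)
            if n + 1 < L:
                A[n + 1, n] += (n + 2 * k) * lm
            if n - 1 >= 0:
                A[n - 1, n] += n * mu
            A[n, n] -= (n + k) * (lm + mu)
        return A

    events = [("node", a) for a in bt[1:]] + [("end", 0.0)]
    Q = np.zeros(L)
    Q[0] = 1.0
    ll, k, a_prev = 0.0, 2, T
    for kind, a in events:
        dt = a_prev - a
        if dt > 0:
            Q = expm(gen(k) * dt) @ Q
            s = Q.sum()
            ll += math.log(s)
            Q = Q / s
        if kind == "node":
            w = np.array([lamN(n + k) for n in range(L)])
            Q = Q * w
            s = Q.sum()
            ll += math.log(s)
            Q = Q / s
            k += 1
        a_prev = a
    ll += math.log(Q[0])
    # conditioning on survival of both crown lineages (exact 2-D enumeration)
    if mu > 0:
        M = 60
        A = np.zeros(((M + 1) ** 2, (M + 1) ** 2))
        idx = lambda i, j: i * (M + 1) + j
        for i in range(M + 1):
            for j in range(M + 1):
                s = idx(i, j)
                lm = lamN(i + j)
                if 0 < i < M:
                    A[idx(i + 1, j), s] += i * lm
                    A[s, s] -= i * lm
                if 0 < j < M:
                    A[idx(i, j + 1), s] += j * lm
                    A[s, s] -= j * lm
                if i > 0:
                    A[idx(i - 1, j), s] += i * mu
                    A[s, s] -= i * mu
                if j > 0:
                    A[idx(i, j - 1), s] += j * mu
                    A[s, s] -= j * mu
        P = np.zeros((M + 1) ** 2)
        P[idx(1, 1)] = 1.0
        P = expm(A * T) @ P
        ll -= math.log(P.reshape(M + 1, M + 1)[1:, 1:].sum())
    return ll


def mk_enumeration_loglik(tree, tip_states, Q, states):
    """Brute-force Mk likelihood: sum over all internal-state assignments."""
    import itertools

    from scipy.linalg import expm

    pos = {s: i for i, s in enumerate(states)}
    nodes = tree.nodes("postorder")
    internals = [nd for nd in nodes if not nd.is_leaf()]
    k = len(states)
    tot = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {nd.index: s for nd, s in zip(internals, assign)}
        pr = 1.0 / k  # flat root prior
        ok = True
        for nd in nodes:
            if nd.parent_node is None:
                continue
            P = expm(Q * nd.edge_length)
            if nd.is_leaf():
                obs = tip_states.get(nd.taxon.label)
                if obs is None or (isinstance(obs, float) and np.isnan(obs)):
                    pr *= P[amap[nd.parent_node.index]].sum()
                    continue
                pr *= P[amap[nd.parent_node.index], pos[obs]]
            else:
                pr *= P[amap[nd.parent_node.index], amap[nd.index]]
        tot += pr
    return float(np.log(tot))
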