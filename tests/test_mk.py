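import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from conftest import mk_enumeration_loglik
from karstrad.mk import (
    MkModel,
    ancestral_state_frequencies,
    ctt_curve,
    ctt_null_test,
    fit_mk,
    sample_stochastic_maps,
)
from karstrad.mk import _build_Q, _BranchSampler
from karstrad.simulate import sim_conditioned_tree, sim_discrete
from karstrad.tree import TimeTree


def test_two_state_transition_probability_closed_form():
    Q = _build_Q(np.array([0.5]), 2, "ER")
    P = expm(Q * 1.0)
    assert P[0, 0] == pytest.approx(0.5 * (1 + math.exp(-2 * 0.5 * 1.0)), abs=1e-9)


@pytest.mark.parametrize("structure", ["ER", "SYM", "ARD"])
def test_pruning_matches_enumeration(structure, balanced_four):
    rng = np.random.default_rng(5)
    k = 3
    from karstrad.mk import _n_rates

    theta = rng.uniform(0.1, 0.6, _n_rates(k, structure))
    Q = _build_Q(theta, k, structure)
    tips = pd.Series({"A": "x", "B": "z", "C": "y", "D": np.nan})
    m = MkModel(balanced_four, tips, structure, states=list("xyz"))
    assert m.loglik(Q) == pytest.approx(
        mk_enumeration_loglik(balanced_four, tips, Q, list("xyz")), abs=1e-10
    )


def test_single_observed_state_rejected(three_tip):
    with pytest.raises(ValueError, match="2 distinct observed"):
        fit_mk(three_tip, pd.Series({"A": "x", "B": "x", "C": "x"}), states=["x", "y"])


def test_rate_recovery_symmetric():
    """Six-state symmetric rates recovered from simulated tip states."""
    q_true = 0.012
    t = sim_conditioned_tree(150, 30.0, lambda1=0.2, seed=8)
    Q = np.full((6, 6), q_true)
    np.fill_diagonal(Q, -5 * q_true)
    states = list("abcdef")
    rates = []
    for s in range(8):
        tips, _ = sim_discrete(t, Q, states=states, seed=100 + s)
        rates.append(fit_mk(t, tips, "ER", states=states).rates[0])
    assert abs(np.mean(rates) - q_true) < 0.25 * q_true


class TestStochasticMaps:
    def test_zero_rate_maps_have_no_changes(self, balanced_four):
        Q = _build_Q(np.array([1e-8]), 2, "ER")
        tips = pd.Series({"A": "x", "B": "x", "C": "x", "D": "x"})
        m = MkModel(balanced_four, tips, "ER", states=["x", "y"])
        from karstrad.mk import MkResults

        fit = MkResults(m, Q, np.array([1e-8]), m.loglik(Q))
        maps = fit.sample_maps(50, seed=1)
        assert all(mp.n_changes() == 0 for mp in maps)

    def test_forced_different_endpoints_odd_change_count(self):
        Q = _build_Q(np.array([0.5]), 2, "ER")
        sampler = _BranchSampler(Q)
        rng = np.random.default_rng(7)
        for _ in range(200):
            path = sampler.sample_path(0, 1, 1.0, rng)
            assert len(path) % 2 == 1 and len(path) >= 1

    def test_node_frequencies_match_exact_marginals(self, balanced_four):
        tips = pd.Series({"A": "x", "B": "y", "C": "x", "D": "y"})
        fit = fit_mk(balanced_four, tips, "ER")
        maps = fit.sample_maps(8000, seed=11)
        freq = ancestral_state_frequencies(balanced_four, maps)
        marg = fit.ancestral_marginals()
        assert np.abs(freq.to_numpy() - marg.to_numpy()).max() < 0.02

    def test_tip_segments_end_in_observed_state(self, balanced_four):
        tips = pd.Series({"A": "x", "B": "y", "C": "x", "D": "y"})
        fit = fit_mk(balanced_four, tips, "ER")
        for mp in fit.sample_maps(20, seed=13):
            for lf in balanced_four.leaves():
                assert mp.node_states[lf.index] == tips[lf.taxon.label]


class TestCTT:
    def _fit_and_maps(self, tree, seed=2):
        Q = _build_Q(np.array([0.1]), 2, "ER")
        tips, _ = sim_discrete(tree, Q, states=["a", "b"], seed=seed)
        fit = fit_mk(tree, tips, "ER")
        return fit, fit.sample_maps(40, seed=seed + 1)

    def test_conservation_identity(self):
        tree = sim_conditioned_tree(30, 20.0, lambda1=0.2, seed=17)
        fit, maps = self._fit_and_maps(tree)
        for nb in (10, 20):
            res = ctt_curve(tree, maps, n_bins=nb)
            total = float(np.sum(res.observed * res.edge_length))
            assert total == pytest.approx(np.mean([m.n_changes() for m in maps]), abs=1e-9)

    def test_zero_change_maps_give_flat_zero(self, balanced_four):
        from karstrad.mk import StochasticMap

        maps = [StochasticMap(["a"], {i: "a" for i in range(7)}, {})]
        res = ctt_curve(balanced_four, maps, n_bins=5)
        assert np.all(res.observed == 0)

    def test_single_change_arithmetic(self, balanced_four):
        from karstrad.mk import StochasticMap

        # one change at age 0.5; bins [2,1) and [1,0): lower bin holds it
        nd = balanced_four.leaves()[0]
        maps = [StochasticMap(["a", "b"], {}, {nd.index: [(0.5, "a", "b")]})]
        res = ctt_curve(balanced_four, maps, n_bins=2)
        length_low = res.edge_length[1]
        assert res.observed[0] == 0
        assert res.observed[1] == pytest.approx(1.0 / length_low)

    def test_bins_validation(self, balanced_four):
        from karstrad.mk import StochasticMap

        maps = [StochasticMap(["a"], {}, {})]
        with pytest.raises(ValueError):
            ctt_curve(balanced_four, maps, n_bins=1)

    def test_concentrated_changes_rejected_by_envelope(self):
        """Maps with all changes artificially stacked in one young bin are
        flagged non-random against the fitted-rate null."""
        tree = sim_conditioned_tree(40, 20.0, lambda1=0.2, seed=19)
        Q = _build_Q(np.array([0.05]), 2, "ER")
        tips, _ = sim_discrete(tree, Q, states=["a", "b"], seed=20)
        fit = fit_mk(tree, tips, "ER")
        from karstrad.mk import StochasticMap

        some_tip = tree.leaves()[0]
        fake = [
            StochasticMap(["a", "b"], {}, {some_tip.index: [(0.1, "a", "b")] * 8})
            for _ in range(10)
        ]
        obs = ctt_curve(tree, fake, n_bins=10)
        res = ctt_null_test(tree, fit, obs, n_sims=199, seed=21)
        assert res.envelope.p_upper < 0.05
        assert res.verdict == "Non-random"


def test_ancestral_frequencies_rows_sum_to_one(balanced_four):
    tips = pd.Series({"A": "x", "B": "y", "C": "y", "D": "x"})
    fit = fit_mk(balanced_four, tips, "ER")
    freq = ancestral_state_frequencies(balanced_four, fit.sample_maps(100, seed=3))
    assert np.allclose(freq.sum(axis=1), 1.0)
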