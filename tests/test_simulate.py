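import numpy as np
import pandas as pd
import pytest

from karstrad.diversification import gamma_statistic
from karstrad.simulate import (
    CLADE_SIZES,
    SimulationSpec,
    TraitModel,
    make_reference_dataset,
    read_bundle,
    sim_conditioned_tree,
    sim_discrete,
    sim_regime_traits,
    sim_traits,
    sim_tree,
    write_bundle,
)
from karstrad.tree import TimeTree


def test_yule_target_n_and_determinism():
    spec = SimulationSpec(lambda0=1.0, n_tips=50)
    a = sim_tree(spec, seed=5)
    b = sim_tree(spec, seed=5)
    c = sim_tree(spec, seed=6)
    assert a.n_tips == 50
    assert a.to_newick() == b.to_newick()
    assert c.to_newick() != a.to_newick()


def test_dd_richness_fluctuates_near_K():
    """Standing diversity of a long diversity-dependent run sits near K."""
    K = 40.0
    finals = []
    for s in range(30):
        t = sim_tree(
            SimulationSpec(lambda0=0.5, mu=0.0, K=K, crown_age=40.0), seed=1000 + s
        )
        finals.append(t.n_tips)
    assert abs(np.mean(finals) - K) < 0.1 * K


def test_pure_birth_gamma_null_expectation():
    gs = [
        gamma_statistic(sim_tree(SimulationSpec(lambda0=1.0, n_tips=60), seed=s).branching_times())
        for s in range(200)
    ]
    assert abs(np.mean(gs)) < 0.2  # E[gamma] = 0 under pure birth


def test_discrete_frozen_process(three_tip):
    Q = np.full((3, 3), 1e-12)
    np.fill_diagonal(Q, -2e-12)
    tips, hist = sim_discrete(three_tip, Q, states=list("xyz"), seed=0)
    assert hist.n_events() == 0
    assert tips.nunique() == 1


def test_discrete_event_count_expectation():
    """Mean number of events on a branch of length t is q*t (2-state sym)."""
    t = TimeTree.from_newick("(A:1,B:1);")
    Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
    rng = np.random.default_rng(11)
    counts = []
    for _ in range(4000):
        _, hist = sim_discrete(t, Q, seed=rng)
        counts.append(sum(len(v) for v in hist.branch_events.values()))
    # two branches of length 1 -> expectation 2 * 0.5
    assert np.mean(counts) == pytest.approx(1.0, abs=0.05)


def test_invalid_Q_rejected(three_tip):
    with pytest.raises(ValueError):
        sim_discrete(three_tip, np.array([[1.0, -1.0], [0.5, -0.5]]), seed=0)


def test_bm_tip_variance():
    t = TimeTree.from_newick("(A:1,B:1);")
    rng = np.random.default_rng(2)
    vals = []
    for _ in range(4000):
        X, _ = sim_traits(t, TraitModel(Sigma=np.eye(1)), seed=rng)
        vals.append(X.to_numpy().ravel())
    assert np.var(np.array(vals)) == pytest.approx(1.0, rel=0.06)


def test_eb_r_zero_equals_bm():
    t = sim_conditioned_tree(20, 10.0, lambda1=0.3, seed=8)
    rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
    a, _ = sim_traits(t, TraitModel(Sigma=np.eye(1), mode="BM"), seed=rng1)
    b, _ = sim_traits(t, TraitModel(Sigma=np.eye(1), mode="EB", r=0.0), seed=rng2)
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_ou_large_alpha_clusters_at_optimum():
    t = sim_conditioned_tree(30, 10.0, lambda1=0.4, seed=10)
    X, _ = sim_traits(
        t,
        TraitModel(Sigma=np.eye(1), mode="OU", alpha=20.0, theta=np.array([3.0]),
                   root_value=np.array([0.0])),
        seed=4,
    )
    v = X.to_numpy().ravel()
    assert abs(np.mean(v) - 3.0) < 0.2
    assert np.std(v) < 0.5  # stationary sd = sqrt(1/(2*20)) ~ 0.16


def test_regime_traits_same_optimum_converge():
    t = sim_conditioned_tree(24, 15.0, lambda1=0.3, seed=12)
    kids = t.root.child_nodes()
    paint = {}
    for nd, _, _ in t.edges():
        paint[nd.index] = 1
    X, _ = sim_regime_traits(
        t, paint, {0: [0.0], 1: [5.0]}, alpha=3.0, sigma2=0.1, root_regime=0, seed=13
    )
    assert abs(X.to_numpy().mean() - 5.0) < 0.3


def test_regime_traits_uncovered_branch_errors():
    t = sim_conditioned_tree(6, 5.0, lambda1=0.5, seed=14)
    with pytest.raises(ValueError, match="not covered"):
        sim_regime_traits(t, {}, {0: [0.0]}, alpha=1.0, sigma2=0.1, root_regime=0, seed=0)


class TestReferenceBundle:
    def test_dimensions(self, bundle):
        assert bundle.tree.n_tips == 377
        assert bundle.tree.crown_age == pytest.approx(47.0, rel=1e-9)
        assert {k: len(v) for k, v in bundle.clades.items()} == CLADE_SIZES
        assert bundle.habitats.notna().sum() == 331
        assert bundle.traits.dropna().shape[0] == 256

    def test_determinism_and_seed_sensitivity(self, bundle):
        again = make_reference_dataset(seed=1)
        other = make_reference_dataset(seed=2)
        assert again.tree.to_newick() == bundle.tree.to_newick()
        pd.testing.assert_frame_equal(again.traits, bundle.traits)
        assert other.tree.to_newick() != bundle.tree.to_newick()

    def test_fixture_gamma_is_negative(self, bundle):
        assert gamma_statistic(bundle.tree.branching_times()) < -2

    def test_bundle_io_round_trip(self, bundle, tmp_path):
        write_bundle(bundle, str(tmp_path))
        rb = read_bundle(str(tmp_path))
        assert rb.tree.n_tips == 377
        assert rb.habitats.notna().sum() == 331
        assert set(rb.clades) == set(bundle.clades)
        assert np.allclose(
            rb.coordinates.to_numpy(), bundle.coordinates.to_numpy(), atol=1e-6
        )
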