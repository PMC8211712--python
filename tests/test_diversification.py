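import math

import numpy as np
import pytest

from conftest import dense_expm_dd_loglik
from karstrad.diversification import (
    DiversificationModel,
    akaike_weights,
    compare_models,
    crbd_loglik,
    dd_loglik,
    gamma_statistic,
    gamma_test,
    birth_death_model_family,
)
from karstrad.simulate import SimulationSpec, sim_tree


class TestGamma:
    def test_hand_derived_three_tip_value(self):
        # g2 = g3 = 1: T = 5, numerator -0.5, denominator 5*sqrt(1/12)
        assert gamma_statistic([2, 1]) == pytest.approx(-0.34641, abs=1e-5)

    def test_scale_invariance(self):
        bt = np.array([12.0, 8.0, 3.3, 1.1, 0.4])
        assert gamma_statistic(bt) == pytest.approx(gamma_statistic(bt * 10))
        assert gamma_statistic(bt) == pytest.approx(gamma_statistic(bt * 0.01))

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            gamma_statistic([2.0])

    def test_null_distribution_mean_and_sd(self):
        g = gamma_test(np.sort(np.random.default_rng(0).uniform(0.1, 9, 199))[::-1],
                       n_null=1000, seed=1)
        assert abs(np.mean(g.null_gammas)) < 0.1
        assert np.std(g.null_gammas) == pytest.approx(1.0, abs=0.1)

    def test_positive_gamma_gives_large_p(self):
        # a late-burst (positive gamma) tree under the lower-tail test
        bt = np.concatenate([[10.0], np.linspace(0.5, 0.1, 40)])
        res = gamma_test(bt, n_null=500, seed=2)
        assert gamma_statistic(bt) > 3
        assert res.p_value > 0.95

    def test_p_never_zero(self):
        bt = np.concatenate([[10.0], np.linspace(9.9, 9.1, 60)])
        res = gamma_test(bt, n_null=200, seed=3)
        assert res.p_value >= 1.0 / 201


class TestCRBD:
    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            crbd_loglik([2, 1], 0.1, 0.2)

    def test_yule_ml_matches_grid_search(self):
        t = sim_tree(SimulationSpec(lambda0=0.4, n_tips=40), seed=7)
        bt = t.branching_times()
        fit = DiversificationModel(t, birth_death_model_family(pure_birth=True)[0]).fit()
        grid = np.linspace(0.01, 2.0, 4000)
        lls = [crbd_loglik(bt, lam, 0.0) for lam in grid]
        lam_grid = grid[int(np.argmax(lls))]
        assert fit.params["lambda1"] == pytest.approx(lam_grid, rel=1e-3)
        # closed-form Yule ML: (n-2) / (total crown edge length)
        lam_closed = (len(bt) - 1) / (np.sum(bt[1:]) + 2 * bt[0])
        assert fit.params["lambda1"] == pytest.approx(lam_closed, rel=1e-4)

    def test_rate_recovery_with_extinction(self):
        lams, mus = [], []
        spec_fit = birth_death_model_family(pure_birth=False)[0]
        for s in range(40):
            t = sim_tree(SimulationSpec(lambda0=0.3, mu=0.1, n_tips=60), seed=9000 + s)
            f = DiversificationModel(t, spec_fit).fit(n_starts=3)
            lams.append(f.params["lambda1"])
        assert abs(np.mean(lams) - 0.3) < 0.2 * 0.3


class TestDDLoglik:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            dd_loglik([2, 1], -0.1, 0.0, 40)
        with pytest.raises(ValueError):
            dd_loglik([2, 1], 0.5, 0.0, 1.0)

    def test_K_to_infinity_reduces_to_yule(self):
        bt = np.array([10, 7, 5, 2, 1.2, 0.3])
        assert dd_loglik(bt, 0.3, 0.0, 1e9) == pytest.approx(
            crbd_loglik(bt, 0.3, 1e-12), abs=1e-4
        )

    @pytest.mark.parametrize("lam0,mu,K", [(0.5, 0.1, 15.0), (0.4, 0.05, 30.0), (0.3, 0.15, 1e7)])
    def test_matches_dense_expm_oracle_small_trees(self, lam0, mu, K):
        t = sim_tree(SimulationSpec(lambda0=0.4, n_tips=7), seed=21)
        bt = t.branching_times()
        ours = dd_loglik(bt, lam0, mu, K, n_max=402)
        oracle = dense_expm_dd_loglik(bt, lam0, mu, None if K > 1e6 else K, L=400)
        if mu > 0 and K < 1e6:
            # conditioning truncation differs slightly between routes
            assert ours == pytest.approx(oracle, abs=5e-4)
        else:
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_crbd_closed_form_with_extinction(self):
        from karstrad.diversification import _piecewise_loglik

        bt = np.array([10, 7, 5, 2, 1.2, 0.3])
        for lam, mu in [(0.3, 0.1), (0.5, 0.3)]:
            assert _piecewise_loglik(bt, [(lam, mu, None)], None) == pytest.approx(
                crbd_loglik(bt, lam, mu), abs=1e-8
            )


class TestFitting:
    def test_spec_collapse_constant_equals_crbd(self):
        t = sim_tree(SimulationSpec(lambda0=0.5, n_tips=30), seed=31)
        f = DiversificationModel(t, birth_death_model_family(pure_birth=True)[0]).fit()
        lam = f.params["lambda1"]
        assert f.loglik == pytest.approx(crbd_loglik(t.branching_times(), lam, 1e-12), abs=1e-3)

    def test_nested_model_never_fits_worse(self):
        t = sim_tree(SimulationSpec(lambda0=0.4, n_tips=60), seed=33)
        specs = birth_death_model_family(pure_birth=True)
        f_const = DiversificationModel(t, specs[0]).fit()
        f_dd = DiversificationModel(t, specs[1]).fit()
        f_shift = DiversificationModel(t, specs[2]).fit()
        assert f_dd.loglik >= f_const.loglik - 1e-4
        assert f_shift.loglik >= f_dd.loglik - 1e-4


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_equal_aic_symmetry(self):
        assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_shift_invariance(self):
        a = np.array([100.0, 103.0, 110.0])
        assert akaike_weights(a) == pytest.approx(akaike_weights(a + 55.5))

    def test_weights_sum_to_one(self):
        w = akaike_weights([10, 12, 13, 30, 90])
        assert w.sum() == pytest.approx(1.0)

    def test_compare_models_requires_fits(self):
        with pytest.raises(ValueError):
            compare_models([])
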