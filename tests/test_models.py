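import numpy as np
import pytest

from climniche.models import (
    TraitEvolutionModel,
    aicc_weights,
    fit_all_models,
    fit_model,
    model_covariance,
    mvn_loglik,
)
from climniche.simulate import simulate_traits
from climniche.tree import parse_newick, transform_tree

from conftest import random_chronogram


class TestModelCovariance:
    def test_bm_is_sigma2_times_shared_ancestry(self, balanced4):
        C = balanced4.phylo_covariance().C
        V = model_covariance(balanced4, "BM", {"sigma2": 3.0})
        assert np.allclose(V, 3.0 * C)

    def test_ou_small_alpha_limit_is_bm(self, tree81, cov81):
        V = model_covariance(tree81, "OU", {"sigma2": 2.0, "alpha": 1e-8})
        assert np.allclose(V, 2.0 * cov81, rtol=1e-4)

    def test_ou_two_tip_star_closed_form(self):
        t = parse_newick("(A:1,B:1);")
        V = model_covariance(t, "OU", {"sigma2": 2.0, "alpha": 1.0})
        expect = (2.0 / 2.0) * (1 - np.exp(-2.0))
        assert V[0, 0] == pytest.approx(expect, abs=1e-12)
        assert V[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_eb_covariance_equals_transformed_tree_covariance(self):
        t = random_chronogram(3, n_tips=9)
        a = -0.3
        V = model_covariance(t, "EB", {"sigma2": 1.5, "a": a})
        Ct = transform_tree(t, "EB", {"a": a}).phylo_covariance().C
        assert np.allclose(V, 1.5 * Ct, atol=1e-10)

    def test_invalid_params_rejected(self, balanced4):
        with pytest.raises(ValueError):
            model_covariance(balanced4, "OU", {"sigma2": 1.0, "alpha": 0.0})
        with pytest.raises(ValueError):
            model_covariance(balanced4, "EB", {"sigma2": 1.0, "a": 0.5})
        bad = parse_newick("((A:1,B:1):1,C:1.5);", ultrametric="ignore")
        with pytest.raises(ValueError, match="ultrametric"):
            model_covariance(bad, "OU", {"sigma2": 1.0, "alpha": 1.0})


class TestMvnLoglik:
    def test_standard_normal_point(self):
        assert mvn_loglik(np.zeros(1), 0.0, np.eye(1)) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_diagonal_factorizes_into_univariate_terms(self, rng):
        x = rng.normal(size=6)
        var = rng.uniform(0.5, 2.0, 6)
        expect = sum(
            -0.5 * (np.log(2 * np.pi * v) + xi**2 / v) for xi, v in zip(x, var)
        )
        assert mvn_loglik(x, 0.0, np.diag(var)) == pytest.approx(expect)

    def test_matches_dense_inverse_formula(self, rng):
        A = rng.normal(size=(5, 5))
        V = A @ A.T + 5 * np.eye(5)
        x = rng.normal(size=5)
        mu = rng.normal(size=5)
        expect = -0.5 * (
            5 * np.log(2 * np.pi)
            + np.log(np.linalg.det(V))
            + (x - mu) @ np.linalg.inv(V) @ (x - mu)
        )
        assert mvn_loglik(x, mu, V) == pytest.approx(expect, abs=1e-10)

    def test_non_pd_rejected_with_eigenvalue(self):
        V = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(Exception, match="eigenvalue"):
            mvn_loglik(np.zeros(2), 0.0, V)


class TestFitting:
    def test_bm_parameter_recovery(self, tree81):
        X = simulate_traits(
            tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 31, n_datasets=200
        )
        s2 = [fit_model(tree81, x, model="BM").sigma2 for x in X]
        z0 = [fit_model(tree81, x, model="BM").z0 for x in X]
        assert np.mean(s2) == pytest.approx(1.0, rel=0.1)
        assert abs(np.mean(z0)) < 0.1 * np.sqrt(tree81.root_age)

    def test_eb_fixed_zero_reproduces_bm_loglik(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 32)
        bm = fit_model(tree81, x, model="BM")
        eb0 = TraitEvolutionModel(x, tree81, model="EB").fit(fixed={"a": 0.0})
        assert eb0.lnL == pytest.approx(bm.lnL, abs=1e-12)
        assert eb0.sigma2 == pytest.approx(bm.sigma2, abs=1e-12)

    def test_ou_tiny_alpha_approaches_bm_loglik(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 33)
        bm = fit_model(tree81, x, model="BM")
        ou = TraitEvolutionModel(x, tree81, model="OU").fit(fixed={"alpha": 1e-8})
        assert ou.lnL == pytest.approx(bm.lnL, abs=1e-4)

    def test_ou_recovers_strong_alpha_within_factor_two(self, tree81):
        alpha = 5.0 / tree81.root_age
        X = simulate_traits(
            tree81, "OU", {"sigma2": 1.0, "z0": 0.0, "alpha": alpha}, 34,
            n_datasets=50,
        )
        est = np.array([fit_model(tree81, x, model="OU").alpha for x in X])
        assert alpha / 2 <= np.median(est) <= alpha * 2

    def test_ou_equals_accelerating_rates_on_ultrametric_tree(self, tree81):
        alpha = 3.0 / tree81.root_age
        x = simulate_traits(
            tree81, "OU", {"sigma2": 1.0, "z0": 0.0, "alpha": alpha}, 35
        )
        ou = fit_model(tree81, x, model="OU")
        ac = fit_model(tree81, x, model="EB", allow_ac=True)
        assert ac.a > 0  # picks the accelerating branch
        assert ac.lnL == pytest.approx(ou.lnL, abs=5e-3)

    def test_optimum_beats_random_admissible_draws(self, tree81, rng):
        x = simulate_traits(
            tree81, "OU", {"sigma2": 0.5, "z0": 2.0, "alpha": 0.03}, 36
        )
        m = TraitEvolutionModel(x, tree81, model="OU")
        best = m.fit()
        for _ in range(20):
            params = {
                "sigma2": float(rng.uniform(0.05, 5.0)),
                "z0": float(rng.normal(2.0, 2.0)),
                "alpha": float(rng.uniform(1e-4, 0.5)),
            }
            assert m.loglik(params) <= best.lnL + 1e-8

    def test_measurement_error_damps_single_tip_sensitivity(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 37)
        bump = x.copy()
        bump[0] += 3.0
        no_se = abs(
            fit_model(tree81, bump, model="BM").lnL
            - fit_model(tree81, x, model="BM").lnL
        )
        se = np.full(81, 2.0)
        with_se = abs(
            fit_model(tree81, bump, se, model="BM").lnL
            - fit_model(tree81, x, se, model="BM").lnL
        )
        assert with_se < no_se

    def test_input_validation(self, tree81, balanced4):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 38)
        with pytest.raises(ValueError, match="at least 4"):
            fit_model(parse_newick("((A:1,B:1):1,C:2);"), [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            fit_model(balanced4, np.zeros(4))
        with pytest.raises(ValueError, match="se"):
            fit_model(tree81, x, se=-np.ones(81))


class TestAiccWeights:
    def test_equal_aicc_gives_equal_weights(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 39)
        fits = [fit_model(tree81, x, model="BM") for _ in range(3)]
        aicc_weights(fits)
        for f in fits:
            assert f.weight == pytest.approx(1 / 3)

    def test_delta_two_gives_weight_ratio_e(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 40)
        f1 = fit_model(tree81, x, model="BM")
        f2 = fit_model(tree81, x, model="BM")
        f2.aicc = f1.aicc + 2.0
        aicc_weights([f1, f2])
        assert f1.weight / f2.weight == pytest.approx(np.e)

    def test_weights_sum_to_one(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 41)
        comp = fit_all_models(tree81, x)
        assert sum(comp.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mixed_data_rejected(self, tree81):
        x1 = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 42)
        x2 = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 43)
        with pytest.raises(ValueError, match="identical data"):
            aicc_weights(
                [fit_model(tree81, x1, model="BM"),
                 fit_model(tree81, x2, model="BM")]
            )


class TestModelSelection:
    def test_bm_data_selects_bm_modally(self, tree81):
        X = simulate_traits(
            tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 44, n_datasets=60
        )
        best = [fit_all_models(tree81, x).best.model for x in X]
        assert sum(b == "BM" for b in best) > len(best) / 2

    def test_strong_ou_data_selects_ou_modally(self, tree81):
        alpha = 5.0 / tree81.root_age
        X = simulate_traits(
            tree81, "OU", {"sigma2": 1.0, "z0": 0.0, "alpha": alpha}, 45,
            n_datasets=60,
        )
        best = [fit_all_models(tree81, x).best.model for x in X]
        assert sum(b == "OU" for b in best) > len(best) / 2

    def test_tie_breaks_toward_simpler_model(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 46)
        comp = fit_all_models(tree81, x)
        bm, eb = comp.fits["BM"], comp.fits["EB"]
        eb.aicc = bm.aicc  # force an exact tie
        assert comp.best.model == "BM"
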