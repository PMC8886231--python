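import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climniche.models import TraitEvolutionResults, fit_model


def bm_results(sigma2=1.0, z0=0.0):
    """Hand-built BM fit object (rates only read model and params)."""
    return TraitEvolutionResults(
        model="BM", params={"sigma2": sigma2, "z0": z0}, lnL=0.0, k=2,
        nobs=2, aicc=0.0,
    )
from climniche.rates import (
    absolute_tip_rates,
    ancestral_states,
    compare_sigma2,
    hpd_interval,
)
from climniche.simulate import make_pseudo_posterior, simulate_traits
from climniche.tree import Chronogram, parse_newick

from conftest import mrca_depth_bruteforce, random_chronogram


def conditional_mvn_oracle(tree: Chronogram, x: np.ndarray) -> np.ndarray:
    """Ancestral BM states by dense joint-covariance conditioning."""
    n, m = tree.n_tips, tree.n_nodes
    S = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            S[i, j] = (
                tree.depths[i] if i == j else mrca_depth_bruteforce(tree, i, j)
            )
    V_tt = S[:n, :n]
    V_at = S[n:, :n]
    one = np.ones(n)
    Vi = np.linalg.inv(V_tt)
    z0 = (one @ Vi @ x) / (one @ Vi @ one)
    return z0 + V_at @ Vi @ (x - z0)


class TestAncestralStates:
    def test_two_tip_symmetry(self):
        t = parse_newick("(A:1,B:1);")
        assert ancestral_states(t, [0.0, 2.0])[0] == pytest.approx(1.0)

    def test_constant_traits_propagate(self, balanced4):
        anc = ancestral_states(balanced4, np.full(4, 7.0))
        assert anc == pytest.approx(np.full(3, 7.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_conditional_oracle(self, seed):
        t = random_chronogram(300 + seed, n_tips=5)
        x = simulate_traits(t, "BM", {"sigma2": 1.0, "z0": 0.0}, seed)
        assert ancestral_states(t, x) == pytest.approx(
            conditional_mvn_oracle(t, x), abs=1e-10
        )

    def test_sigma2_scale_does_not_move_bm_estimates(self, balanced4):
        x = np.array([0.0, 1.0, 4.0, 9.0])
        a1 = ancestral_states(balanced4, x, params={"sigma2": 1.0})
        a2 = ancestral_states(balanced4, x, params={"sigma2": 42.0})
        assert a1 == pytest.approx(a2)


class TestAbsoluteTipRates:
    def test_two_tip_closed_form(self):
        t = parse_newick("(A:1,B:1);")
        tab = absolute_tip_rates(t, [0.0, 2.0], bm_results())
        assert tab["rate"].tolist() == pytest.approx([1.0, 1.0])

    def test_identical_tips_give_zero_rates(self, tree81):
        tab = absolute_tip_rates(tree81, np.full(81, 5.0), bm_results())
        assert np.allclose(tab["rate"], 0.0)

    def test_doubling_branch_lengths_halves_rates(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 51)
        fit1 = fit_model(tree81, x, model="BM")
        r1 = absolute_tip_rates(tree81, x, fit1)["rate"].to_numpy()
        doubled = Chronogram(
            tree81.parent.copy(), 2.0 * tree81.branch_lengths,
            list(tree81.tip_labels),
        )
        fit2 = fit_model(doubled, x, model="BM")
        r2 = absolute_tip_rates(doubled, x, fit2)["rate"].to_numpy()
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-8)

    def test_translation_invariance_and_linear_scaling(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 52)
        fit = fit_model(tree81, x, model="BM")
        base = absolute_tip_rates(tree81, x, fit)["rate"].to_numpy()
        shifted = absolute_tip_rates(
            tree81, x + 100.0, fit_model(tree81, x + 100.0, model="BM")
        )["rate"].to_numpy()
        scaled = absolute_tip_rates(
            tree81, 3.0 * x, fit_model(tree81, 3.0 * x, model="BM")
        )["rate"].to_numpy()
        assert shifted == pytest.approx(base, rel=1e-8)
        assert scaled == pytest.approx(3.0 * base, rel=1e-8)

    def test_bm_transform_is_identity_for_rates(self, tree81):
        # explicit check that a BM "transformed" covariance leaves the
        # reconstruction, and hence the rates, unchanged
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 53)
        fit = fit_model(tree81, x, model="BM")
        anc1 = ancestral_states(tree81, x, model="BM", params=fit.params)
        anc2 = ancestral_states(tree81, x, model="BM", params={"sigma2": 1.0})
        assert anc1 == pytest.approx(anc2)

    def test_rates_nonnegative_and_zero_branch_flagged(self):
        t = parse_newick("((A:0,B:0):1,C:1);", ultrametric="ignore")
        with pytest.warns(UserWarning, match="zero-length"):
            tab = absolute_tip_rates(t, [0.0, 2.0, 1.0], bm_results())
        assert tab["rate"].isna().sum() == 2
        assert (tab["rate"].dropna() >= 0).all()


class TestHPD:
    def test_integers_1_to_100(self):
        h = hpd_interval(np.arange(1, 101), 0.95)
        assert (h.lo, h.hi) == (1.0, 95.0)

    def test_all_equal_degenerates_to_point(self):
        h = hpd_interval([3.0, 3.0, 3.0])
        assert (h.lo, h.hi) == (3.0, 3.0)

    def test_normal_sample_recovers_plus_minus_196(self, rng):
        v = rng.standard_normal(100_000)
        h = hpd_interval(v, 0.95)
        assert h.lo == pytest.approx(-1.96, abs=0.05)
        assert h.hi == pytest.approx(1.96, abs=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = np.sort(rng.integers(0, 50, size=rng.integers(5, 40)).astype(float))
        mass = rng.choice([0.5, 0.8, 0.95])
        m = int(np.ceil(mass * v.size))
        widths = [(v[j + m - 1] - v[j], j) for j in range(v.size - m + 1)]
        best_w, best_j = min(widths)
        h = hpd_interval(v, mass)
        assert h.hi - h.lo == pytest.approx(best_w)
        assert h.lo == v[best_j]  # leftmost tie

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_unimodal_sample_hpd_contains_median(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=51)
        h = hpd_interval(v, 0.9)
        assert float(np.median(v)) in h

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([1.0])


class TestCompareSigma2:
    def test_identical_fit_lists(self):
        fits = {"mcc": 1.0, **{f"post_{i}": 1.0 + 0.1 * i for i in range(20)}}
        res = compare_sigma2(fits, dict(fits))
        assert res["frac_a_lt_b"] == 0.0
        assert res["hpd_a"] == res["hpd_b"]
        assert res["hpd_overlap"] == pytest.approx(1.0)

    def test_mismatched_ensembles_rejected(self):
        with pytest.raises(ValueError, match="ensemble"):
            compare_sigma2({"mcc": 1.0, "p1": 1.0}, {"mcc": 1.0, "p2": 1.0})

    def test_sigma2_contrast_recovery_one_vs_four(self, tree81):
        ens = make_pseudo_posterior(tree81, 60, 0.08, seed=7)
        fits_a, fits_b = {}, {}
        rng = np.random.default_rng(77)
        for tree_id, tree in ens.items():
            xa = simulate_traits(tree, "BM", {"sigma2": 1.0, "z0": 0.0}, rng)
            xb = simulate_traits(tree, "BM", {"sigma2": 4.0, "z0": 0.0}, rng)
            fits_a[tree_id] = fit_model(tree, xa, model="BM").sigma2
            fits_b[tree_id] = fit_model(tree, xb, model="BM").sigma2
        res = compare_sigma2(fits_a, fits_b, label_a="slow", label_b="fast")
        assert res["frac_a_lt_b"] > 0.9
        assert res["hpd_a"][1] < res["hpd_b"][0]  # non-overlapping HPDs
        assert res["hpd_overlap"] == 0.0
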