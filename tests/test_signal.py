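import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climniche.signal import blomberg_k, k_randomization_test, phylogenetic_mean
from climniche.simulate import simulate_traits
from climniche.tree import parse_newick

from conftest import random_chronogram


def k_oracle(C: np.ndarray, x: np.ndarray) -> float:
    """Textbook K from explicit dense-matrix formulas (se = 0)."""
    n = x.size
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    a = (one @ Ci @ x) / (one @ Ci @ one)
    r = x - a
    mse0 = r @ r / (n - 1)
    mse = r @ Ci @ r / (n - 1)
    r_bm = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
    return (mse0 / mse) / r_bm


class TestPhylogeneticMean:
    def test_constant_tips(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert phylogenetic_mean([3, 3, 3], t.phylo_covariance().C) == pytest.approx(3)

    def test_star_tree_reduces_to_arithmetic_mean(self):
        C = 2.0 * np.eye(4)
        x = np.array([0.0, 1.0, 2.0, 9.0])
        assert phylogenetic_mean(x, C) == pytest.approx(x.mean())

    def test_three_tip_explicit_solve(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        cov = t.phylo_covariance()
        x = np.array([0.0, 0.0, 3.0])[
            [cov.taxa_order.index(l) for l in ("A", "B", "C")]
        ]
        C = cov.C
        expect = float(
            (np.ones(3) @ np.linalg.solve(C, x))
            / (np.ones(3) @ np.linalg.solve(C, np.ones(3)))
        )
        assert phylogenetic_mean(x, C) == pytest.approx(expect, abs=1e-12)


class TestBlombergK:
    def test_star_tree_k_is_one_exactly(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        res = blomberg_k(t, [0.0, 1.0, 2.0, 5.0])
        assert res.K == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_dense_oracle_without_se(self, seed):
        t = random_chronogram(1000 + seed, n_tips=5 + seed % 11)
        x = simulate_traits(t, "BM", {"sigma2": 1.0, "z0": 0.0}, seed)
        assert blomberg_k(t, x).K == pytest.approx(
            k_oracle(t.phylo_covariance().C, x), abs=1e-10
        )

    def test_zero_se_matches_explicit_zero_vector(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 3)
        assert blomberg_k(tree81, x, np.zeros(81)).K == pytest.approx(
            blomberg_k(tree81, x).K
        )

    def test_bm_calibration_mean_near_one(self, tree81, cov81):
        X = simulate_traits(
            tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 11, n_datasets=500
        )
        ks = [blomberg_k(tree81, x, C=cov81).K for x in X]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_iid_traits_have_low_signal(self, tree81, cov81):
        X = simulate_traits(
            tree81, "white_noise", {"sigma2": 1.0, "z0": 0.0}, 12, n_datasets=200
        )
        ks = [blomberg_k(tree81, x, C=cov81).K for x in X]
        assert np.mean(ks) < 0.5

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        shift=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_affine_invariance(self, scale, shift):
        t = random_chronogram(5, n_tips=10)
        x = simulate_traits(t, "BM", {"sigma2": 1.0, "z0": 0.0}, 6)
        se = np.abs(simulate_traits(t, "white_noise", {"sigma2": 0.04}, 7))
        k1 = blomberg_k(t, x, se).K
        k2 = blomberg_k(t, scale * x + shift, scale * se).K
        assert k2 == pytest.approx(k1, rel=1e-6)

    def test_error_conditions(self, tree81):
        with pytest.raises(ValueError, match="variance"):
            blomberg_k(tree81, np.ones(81))
        with pytest.raises(ValueError, match="at least 3"):
            blomberg_k(parse_newick("(A:1,B:1);"), [0.0, 1.0])

    def test_measurement_error_shrinks_k_for_noisy_tips(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 8)
        noisy = x + np.random.default_rng(9).normal(0, 5.0, x.size)
        k_raw = blomberg_k(tree81, noisy).K
        k_corrected = blomberg_k(tree81, noisy, np.full(x.size, 5.0)).K
        assert k_corrected > k_raw


class TestRandomizationTest:
    def test_p_matches_exhaustive_enumeration_on_four_tips(self):
        from itertools import permutations

        t = parse_newick("((A:1,B:1):9,(C:1,D:1):9);")
        x = np.array([0.0, 0.1, 10.0, 10.1])
        k_obs = blomberg_k(t, x).K
        ks = [blomberg_k(t, np.array(p)).K for p in permutations(x)]
        # only pair-preserving layouts reach K_obs: exactly 8 of 4! = 1/3
        exact = np.mean([k >= k_obs - 1e-12 for k in ks])
        assert exact == pytest.approx(1 / 3)
        res = k_randomization_test(t, x, n_rand=2000, seed=0)
        assert res.p == pytest.approx(exact, abs=0.04)  # ~3 binomial SE

    def test_clustered_sister_pairs_significant(self):
        t = parse_newick(
            "(((A:1,B:1):4,(C:1,D:1):4):5,((E:1,F:1):4,(G:1,H:1):4):5);"
        )
        x = [0.0, 0.1, 10.0, 10.1, 20.0, 20.1, 30.0, 30.1]
        hits = sum(
            k_randomization_test(t, x, n_rand=500, seed=s).p <= 0.05
            for s in range(10)
        )
        assert hits >= 9

    def test_star_tree_symmetry_gives_p_one(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        res = k_randomization_test(t, [0, 1, 2, 3, 4], n_rand=200, seed=0)
        assert res.p == pytest.approx(1.0)

    def test_seed_required_and_reproducible(self, tree81):
        x = simulate_traits(tree81, "BM", {"sigma2": 1.0, "z0": 0.0}, 13)
        with pytest.raises(ValueError, match="seed"):
            k_randomization_test(tree81, x, n_rand=10)
        r1 = k_randomization_test(tree81, x, n_rand=50, seed=4)
        r2 = k_randomization_test(tree81, x, n_rand=50, seed=4)
        assert (r1.K, r1.p) == (r2.K, r2.p)

    def test_smoothed_p_never_zero(self):
        t = parse_newick("((A:1,B:1):9,(C:1,D:1):9);")
        res = k_randomization_test(
            t, [0.0, 0.1, 10.0, 10.1], n_rand=100, seed=1, smoothed=True
        )
        assert res.p > 0
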