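"""Blomberg's K with sampling error and a tip-randomization test.

K compares the observed ratio of trait variance among tips to the variance
after accounting for shared ancestry against the ratio expected under
Brownian motion on the same tree: K = 1 is the BM expectation, K near 0
means trait values are independent of the phylogeny, K > 1 means close
relatives are even more similar than BM predicts.

Known sampling error of the tip means (se) is folded in by first estimating
the Brownian rate sigma2 by ML under the covariance ``sigma2*C +
diag(se^2)`` and then working with the inflated structure ``C + E/sigma2``;
with se = 0 this reduces exactly to the classical statistic. Significance
against K = 0 comes from jointly permuting (x, se) across the tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .models import _LOG2PI, _profile_terms, gls_mean
from .tree import Chronogram

__all__ = ["SignalResult", "phylogenetic_mean", "blomberg_k", "k_randomization_test"]


@dataclass
class SignalResult:
    """K statistic for one variable on one tree."""

    K: float
    p: float | None
    n_rand: int
    sigma2_hat: float
    variable: str | None = None
    tree_id: str | None = None

    def summary(self) -> str:
        out = [f"Blomberg's K = {self.K:.4f}  (sigma2_hat = {self.sigma2_hat:.4g})"]
        if self.p is not None:
            out.append(f"randomization p = {self.p:.4g}  ({self.n_rand} permutations)")
        return "\n".join(out)


def phylogenetic_mean(x, C) -> float:
    """GLS estimate of the root state: ``(1'C^-1 1)^-1 1'C^-1 x``."""
    return gls_mean(np.asarray(x, float), np.asarray(C, float))


def _ml_sigma2(x: np.ndarray, C: np.ndarray, E: np.ndarray) -> float:
    """ML Brownian rate under ``sigma2*C + E`` (z0 profiled by GLS)."""
    n = x.size
    if not np.any(np.diag(E) > 0):
        _, q, _ = _profile_terms(x, C)
        return q / n
    T = float(np.max(np.diag(C)))
    scale = float(np.var(x)) / max(T, 1e-300)

    def neg(log_s2: float) -> float:
        s2 = math.exp(log_s2)
        try:
            _, q, logdet = _profile_terms(x, s2 * C + E)
        except linalg.LinAlgError:
            return np.inf
        return 0.5 * (n * _LOG2PI + logdet + q)

    lo, hi = math.log(1e-8 * scale), math.log(1e8 * scale)
    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    return math.exp(res.x)


def _k_statistic(x: np.ndarray, Ct: np.ndarray) -> float:
    """K from the (possibly error-inflated) covariance structure Ct."""
    n = x.size
    cho = linalg.cho_factor(Ct, lower=True, check_finite=False)
    one = np.ones(n)
    w1 = linalg.cho_solve(cho, one, check_finite=False)
    a_hat = float(w1 @ x / (w1 @ one))
    r = x - a_hat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ linalg.cho_solve(cho, r, check_finite=False)) / (n - 1)
    r_bm = (float(np.trace(Ct)) - n / float(w1 @ one)) / (n - 1)
    return (mse0 / mse) / r_bm


def blomberg_k(
    tree: Chronogram,
    x,
    se=None,
    *,
    C: np.ndarray | None = None,
) -> SignalResult:
    """K for tip values ``x`` (aligned to ``tree.tip_labels``).

    ``se`` holds per-tip sampling errors of the means (0/None for none);
    ``C`` lets callers reuse a precomputed shared-ancestry matrix.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n != tree.n_tips:
        raise ValueError("x length does not match number of tips")
    if n < 3:
        raise ValueError("K needs at least 3 tips")
    if float(np.var(x)) == 0.0:
        raise ValueError("zero trait variance: K undefined")
    se_arr = np.zeros(n) if se is None else np.asarray(se, dtype=float)
    if np.any(se_arr < 0):
        raise ValueError("se must be non-negative")
    if C is None:
        C = tree.phylo_covariance().C
    E = np.diag(se_arr**2)
    sigma2 = _ml_sigma2(x, C, E)
    Ct = C + E / sigma2 if np.any(se_arr > 0) else C
    K = _k_statistic(x, Ct)
    return SignalResult(K=float(K), p=None, n_rand=0, sigma2_hat=float(sigma2))


def k_randomization_test(
    tree: Chronogram,
    x,
    se=None,
    n_rand: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    reuse_sigma2: bool = False,
    smoothed: bool = False,
) -> SignalResult:
    """K plus a permutation p-value against phylogenetic independence.

    (x, se) pairs are shuffled jointly across tips ``n_rand`` times
    (default 1000) and ``p`` is the proportion of permutations whose K is at
    least the observed one. ``reuse_sigma2`` keeps the observed-data rate
    estimate for the permuted datasets instead of re-estimating;
    ``smoothed`` reports ``(count+1)/(n_rand+1)``.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if seed is None:
        raise ValueError("a seed (or Generator) is required for the randomization")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    se_arr = np.zeros(x.size) if se is None else np.asarray(se, dtype=float)
    C = tree.phylo_covariance().C
    obs = blomberg_k(tree, x, se_arr, C=C)
    has_se = bool(np.any(se_arr > 0))
    count = 0
    for _ in range(n_rand):
        perm = rng.permutation(x.size)
        xp, sp = x[perm], se_arr[perm]
        if has_se and reuse_sigma2:
            Ct = C + np.diag(sp**2) / obs.sigma2_hat
            k_perm = _k_statistic(xp, Ct)
        else:
            k_perm = blomberg_k(tree, xp, sp, C=C).K
        if k_perm >= obs.K:
            count += 1
    p = (count + 1) / (n_rand + 1) if smoothed else count / n_rand
    return SignalResult(
        K=obs.K, p=float(p), n_rand=n_rand, sigma2_hat=obs.sigma2_hat
    )
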