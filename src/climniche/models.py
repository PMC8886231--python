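"""Maximum-likelihood fitting of trait-evolution models on chronograms.

Three single-optimum Gaussian models of continuous-trait evolution are
supported, each defined by the tip covariance it induces on an ultrametric
tree with root age ``T`` and shared-ancestry matrix ``C`` (``C_ij`` = root
to MRCA path length, Myr):

``BM``
    Constant-rate random walk: ``V = sigma2 * C``.
``OU``
    Ornstein–Uhlenbeck with pull ``alpha`` toward an optimum, root state
    free and variance zero at the root (non-stationary form)::

        V_ij = sigma2/(2*alpha) * exp(-2*alpha*(T - C_ij)) * (1 - exp(-2*alpha*C_ij))

    On an ultrametric tree this is likelihood-equivalent to a model whose
    rate increases exponentially through time (AC), so OU support cannot be
    distinguished from accelerating rates.
``EB``
    Early burst: rate decays as ``sigma2 * exp(a*t)`` with ``a <= 0``;
    ``V_ij = sigma2 * (exp(a*C_ij) - 1)/a``.

Known per-tip sampling error enters as a fixed diagonal ``diag(se^2)``
added to ``V``. The root state ``z0`` is profiled out by GLS and ``sigma2``
analytically (or by a nested 1-D search when sampling error is present);
the remaining shape parameter (``alpha`` or ``a``) is optimized by a
bounded grid-plus-Brent search. Model support is compared with
small-sample-corrected Akaike weights (AICc_w).

The public surface follows the Model/Results convention: build a
:class:`TraitEvolutionModel` from data, call :meth:`~TraitEvolutionModel.fit`,
read estimates off the returned :class:`TraitEvolutionResults`.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .tree import Chronogram

__all__ = [
    "model_covariance",
    "mvn_loglik",
    "gls_mean",
    "TraitEvolutionModel",
    "TraitEvolutionResults",
    "ModelComparison",
    "fit_model",
    "fit_all_models",
    "aicc_weights",
]

MODELS = ("BM", "OU", "EB")

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Covariance kernels


def _check_shape_params(model: str, params: dict, *, allow_ac: bool) -> None:
    if model == "OU":
        alpha = params.get("alpha")
        if alpha is None or alpha <= 0:
            raise ValueError("OU requires alpha > 0")
    elif model == "EB":
        a = params.get("a", 0.0)
        if a > 0 and not allow_ac:
            raise ValueError("EB exponent a must be <= 0 (set allow_ac for AC)")


def _unit_covariance(C: np.ndarray, T: float, model: str, params: dict) -> np.ndarray:
    """Model covariance at sigma2 = 1."""
    if model == "BM":
        return C
    if model == "OU":
        alpha = float(params["alpha"])
        if params.get("stationary", False):
            return np.exp(-2.0 * alpha * (T - C)) / (2.0 * alpha)
        return np.exp(-2.0 * alpha * (T - C)) * (-np.expm1(-2.0 * alpha * C)) / (
            2.0 * alpha
        )
    if model == "EB":
        a = float(params.get("a", 0.0))
        if a == 0.0:
            return C
        return np.expm1(a * C) / a
    raise ValueError(f"unknown model {model!r}")


def model_covariance(
    tree: Chronogram,
    model: str,
    params: dict,
    *,
    allow_ac: bool = False,
) -> np.ndarray:
    """Expected tip covariance under a trait-evolution model.

    ``params`` holds ``sigma2`` (required) plus ``alpha`` (OU) or ``a``
    (EB). OU/EB require an ultrametric tree. Returns an array aligned to
    ``tree.tip_labels``.
    """
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model in ("OU", "EB") and not tree.is_ultrametric(rel_tol=1e-4):
        raise ValueError(f"{model} covariance requires an ultrametric tree")
    _check_shape_params(model, params, allow_ac=allow_ac)
    sigma2 = float(params["sigma2"])
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    C = tree.phylo_covariance().C
    return sigma2 * _unit_covariance(C, tree.root_age, model, params)


# ---------------------------------------------------------------------------
# Gaussian machinery


def mvn_loglik(x: np.ndarray, mu, V: np.ndarray) -> float:
    """Log density of ``x ~ MVN(mu, V)`` via Cholesky factorization."""
    x = np.asarray(x, dtype=float)
    V = np.asarray(V, dtype=float)
    n = x.size
    if V.shape != (n, n):
        raise ValueError("dimension mismatch between x and V")
    r = x - np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        lam = float(np.linalg.eigvalsh(V)[0])
        raise linalg.LinAlgError(
            f"covariance not positive definite (smallest eigenvalue {lam:.3g})"
        ) from exc
    alpha = linalg.cho_solve(cho, r, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return float(-0.5 * (n * _LOG2PI + logdet + r @ alpha))


def gls_mean(x: np.ndarray, V: np.ndarray) -> float:
    """GLS (phylogenetic) mean: ``(1'V^-1 1)^-1 1'V^-1 x``.

    Falls back to a tiny ridge when V is numerically singular.
    """
    x = np.asarray(x, dtype=float)
    V = np.asarray(V, dtype=float)
    if V.shape[0] != x.size:
        raise ValueError("dimension mismatch between x and V")
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        ridge = 1e-10 * np.trace(V) / V.shape[0]
        cho = linalg.cho_factor(
            V + ridge * np.eye(V.shape[0]), lower=True, check_finite=False
        )
    one = np.ones_like(x)
    w = linalg.cho_solve(cho, one, check_finite=False)
    return float((w @ x) / (w @ one))


def _profile_terms(x: np.ndarray, V0: np.ndarray):
    """Given unit-sigma2 covariance V0, return (z0_hat, quadform, logdet).

    quadform = (x - z0)' V0^-1 (x - z0) with z0 the GLS mean."""
    cho = linalg.cho_factor(V0, lower=True, check_finite=False)
    one = np.ones_like(x)
    w1 = linalg.cho_solve(cho, one, check_finite=False)
    z0 = float((w1 @ x) / (w1 @ one))
    r = x - z0
    q = float(r @ linalg.cho_solve(cho, r, check_finite=False))
    logdet = float(2.0 * np.sum(np.log(np.diag(cho[0]))))
    return z0, q, logdet


# ---------------------------------------------------------------------------
# Results


@dataclass
class TraitEvolutionResults:
    """Estimates from one model fit.

    ``params`` holds ``sigma2`` (trait-units²/Myr), ``z0`` (root state,
    trait units), and ``alpha`` (1/Myr, OU) or ``a`` (1/Myr, EB).
    ``weight`` is populated by :func:`aicc_weights` across a fit set.
    """

    model: str
    params: dict
    lnL: float
    k: int
    nobs: int
    aicc: float
    weight: float | None = None
    fingerprint: str = ""
    convergence: dict = field(default_factory=dict)

    @property
    def sigma2(self) -> float:
        return self.params["sigma2"]

    @property
    def z0(self) -> float:
        return self.params["z0"]

    @property
    def alpha(self) -> float | None:
        return self.params.get("alpha")

    @property
    def a(self) -> float | None:
        return self.params.get("a")

    def summary(self) -> str:
        lines = [
            f"Trait-evolution model: {self.model}",
            f"  n tips          {self.nobs}",
            f"  lnL             {self.lnL:.6f}",
            f"  k               {self.k}",
            f"  AICc            {self.aicc:.6f}",
            f"  sigma2          {self.sigma2:.6g}",
            f"  z0 (root state) {self.z0:.6g}",
        ]
        if self.alpha is not None:
            lines.append(f"  alpha           {self.alpha:.6g}  (t1/2 = "
                         f"{math.log(2.0) / self.alpha:.4g} Myr)")
        if self.a is not None:
            lines.append(f"  a (EB exponent) {self.a:.6g}")
        if self.weight is not None:
            lines.append(f"  AICc weight     {self.weight:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model object


class TraitEvolutionModel:
    """ML fit of a single trait-evolution model to tip data.

    Parameters
    ----------
    x : array of tip values aligned to ``tree.tip_labels``
    tree : Chronogram
    se : per-tip sampling error of the mean (same units as x); treated as a
        fixed known diagonal added to the model covariance. None means 0.
    model : "BM", "OU", or "EB"
    allow_ac : permit a > 0 in the EB model (accelerating rates)
    stationary_ou : use the stationary OU covariance instead of the
        default root-conditioned (zero root variance) form
    """

    def __init__(
        self,
        x,
        tree: Chronogram,
        se=None,
        model: str = "BM",
        *,
        allow_ac: bool = False,
        stationary_ou: bool = False,
    ) -> None:
        self.model = model.upper()
        if self.model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        self.tree = tree
        self.x = np.asarray(x, dtype=float)
        n = self.x.size
        if n != tree.n_tips:
            raise ValueError("x length does not match number of tips")
        if n < 4:
            raise ValueError("model fitting needs at least 4 tips")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite trait values")
        self.se = (
            np.zeros(n) if se is None else np.asarray(se, dtype=float)
        )
        if self.se.size != n or np.any(self.se < 0) or not np.all(
            np.isfinite(self.se)
        ):
            raise ValueError("se must be finite, non-negative, aligned to tips")
        if self.model in ("OU", "EB") and not tree.is_ultrametric(rel_tol=1e-4):
            raise ValueError(f"{self.model} requires an ultrametric tree")
        if float(np.var(self.x)) == 0.0:
            raise ValueError("zero trait variance: model parameters unidentifiable")
        self.allow_ac = allow_ac
        self.stationary_ou = stationary_ou
        self._C = tree.phylo_covariance().C
        self._T = tree.root_age
        self._E = np.diag(self.se**2)
        self._has_se = bool(np.any(self.se > 0))
        self.fingerprint = hashlib.sha1(
            self.x.tobytes() + self.se.tobytes() + np.int64(n).tobytes()
        ).hexdigest()[:16]

    # -- internals ----------------------------------------------------

    def _unit_cov(self, shape: float | None) -> np.ndarray:
        if self.model == "BM":
            return self._C
        if self.model == "OU":
            return _unit_covariance(
                self._C, self._T, "OU",
                {"alpha": shape, "stationary": self.stationary_ou},
            )
        return _unit_covariance(self._C, self._T, "EB", {"a": shape})

    def _sigma2_bounds(self) -> tuple[float, float]:
        scale = float(np.var(self.x)) / self._T
        return 1e-10 * scale, 1e6 * scale

    def _profile_given_shape(self, shape: float | None):
        """Maximize over (z0, sigma2) at a fixed shape parameter.

        Returns (lnL, sigma2, z0); -inf on numerical failure."""
        n = self.x.size
        try:
            V0 = self._unit_cov(shape)
            if not self._has_se:
                z0, q, logdet = _profile_terms(self.x, V0)
                if q <= 0:
                    return -np.inf, np.nan, np.nan
                sigma2 = q / n
                lnL = -0.5 * (n * _LOG2PI + n * math.log(sigma2) + logdet + n)
                return lnL, sigma2, z0

            lo, hi = self._sigma2_bounds()

            def neg(log_s2: float) -> float:
                s2 = math.exp(log_s2)
                try:
                    z0, q, logdet = _profile_terms(self.x, s2 * V0 + self._E)
                except linalg.LinAlgError:
                    return np.inf
                return 0.5 * (n * _LOG2PI + logdet + q)

            res = optimize.minimize_scalar(
                neg,
                bounds=(math.log(lo), math.log(hi)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            sigma2 = math.exp(res.x)
            z0, q, logdet = _profile_terms(self.x, sigma2 * V0 + self._E)
            return -res.fun, sigma2, z0
        except (linalg.LinAlgError, FloatingPointError, ValueError):
            return -np.inf, np.nan, np.nan

    def _shape_bounds(self) -> tuple[float, float]:
        T = self._T
        if self.model == "OU":
            return 1e-8, 50.0 / T
        lo = math.log(1e-5) / T
        hi = -lo if self.allow_ac else 0.0
        return lo, hi

    # -- fitting ------------------------------------------------------

    def fit(self, *, fixed: dict | None = None, n_grid: int = 24) -> TraitEvolutionResults:
        """Maximize the likelihood; returns a :class:`TraitEvolutionResults`.

        ``fixed`` pins a shape parameter (e.g. ``{"a": 0.0}`` or
        ``{"alpha": 0.5}``) and fits only ``sigma2``/``z0`` — useful for
        nested-model comparisons.
        """
        fixed = dict(fixed or {})
        n = self.x.size
        trace: dict = {}

        if self.model == "BM":
            shape_hat = None
            lnL, sigma2, z0 = self._profile_given_shape(None)
        else:
            key = "alpha" if self.model == "OU" else "a"
            if key in fixed:
                shape_hat = float(fixed[key])
                if self.model == "OU" and shape_hat <= 0:
                    raise ValueError("OU requires alpha > 0")
                if self.model == "EB" and shape_hat > 0 and not self.allow_ac:
                    raise ValueError("EB exponent a must be <= 0")
                lnL, sigma2, z0 = self._profile_given_shape(shape_hat)
            else:
                lo, hi = self._shape_bounds()
                if self.model == "OU":
                    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
                else:
                    grid = np.linspace(lo, hi, n_grid)
                vals = np.array([self._profile_given_shape(s)[0] for s in grid])
                if not np.any(np.isfinite(vals)):
                    raise RuntimeError(
                        f"{self.model} optimizer failed at every grid point"
                    )
                best = int(np.nanargmax(vals))
                blo = grid[max(best - 1, 0)]
                bhi = grid[min(best + 1, n_grid - 1)]
                if self.model == "OU":
                    obj = lambda t: -self._profile_given_shape(math.exp(t))[0]
                    res = optimize.minimize_scalar(
                        obj, bounds=(math.log(blo), math.log(bhi)),
                        method="bounded", options={"xatol": 1e-9},
                    )
                    shape_hat = math.exp(res.x)
                else:
                    obj = lambda t: -self._profile_given_shape(t)[0]
                    res = optimize.minimize_scalar(
                        obj, bounds=(blo, bhi),
                        method="bounded", options={"xatol": 1e-11 * max(1, abs(hi - lo))},
                    )
                    shape_hat = float(res.x)
                lnL, sigma2, z0 = self._profile_given_shape(shape_hat)
                # endpoints can beat the interior polish on flat surfaces
                for cand in (grid[best], lo, hi):
                    l2, s2, zz = self._profile_given_shape(cand)
                    if l2 > lnL:
                        lnL, sigma2, z0, shape_hat = l2, s2, zz, float(cand)
                trace["grid_max"] = float(np.nanmax(vals))
        if not np.isfinite(lnL):
            raise RuntimeError(f"{self.model} fit did not converge: {trace}")

        params = {"sigma2": float(sigma2), "z0": float(z0)}
        k = 2
        if self.model == "OU":
            params["alpha"] = float(shape_hat)
            k = 3
        elif self.model == "EB":
            params["a"] = float(shape_hat)
            k = 3
        if n - k - 1 <= 0:
            raise ValueError(f"AICc undefined: n={n} too small for k={k}")
        aicc = -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
        return TraitEvolutionResults(
            model=self.model,
            params=params,
            lnL=float(lnL),
            k=k,
            nobs=n,
            aicc=float(aicc),
            fingerprint=self.fingerprint,
            convergence=trace,
        )

    def loglik(self, params: dict) -> float:
        """Log-likelihood at explicit parameter values (no optimization)."""
        V = model_covariance(
            self.tree,
            self.model,
            {**params, "stationary": self.stationary_ou},
            allow_ac=self.allow_ac,
        ) + self._E
        return mvn_loglik(self.x, params["z0"], V)


# ---------------------------------------------------------------------------
# Convenience wrappers and model comparison


def fit_model(tree: Chronogram, x, se=None, model: str = "BM", **kwargs) -> TraitEvolutionResults:
    """One-shot fit: ``TraitEvolutionModel(x, tree, se, model).fit()``."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("fixed", "n_grid") if k in kwargs}
    return TraitEvolutionModel(x, tree, se, model, **kwargs).fit(**fit_kwargs)


def aicc_weights(fits: list[TraitEvolutionResults]) -> list[TraitEvolutionResults]:
    """Populate Akaike weights (in place) across fits of the same data.

    ``w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)`` with
    ``Delta_i = AICc_i - min(AICc)``.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    prints = {f.fingerprint for f in fits}
    if len(prints) != 1:
        raise ValueError("fits were not computed on identical data")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    return fits


_COMPLEXITY = {"BM": 0, "EB": 1, "OU": 2}


@dataclass
class ModelComparison:
    """AICc comparison across candidate models of one trait on one tree."""

    fits: dict

    @property
    def best(self) -> TraitEvolutionResults:
        """Lowest AICc; ties broken toward the simpler model, then name."""
        return min(
            self.fits.values(),
            key=lambda f: (round(f.aicc, 10), f.k, _COMPLEXITY[f.model], f.model),
        )

    @property
    def weights(self) -> dict:
        return {m: f.weight for m, f in self.fits.items()}

    def summary(self) -> str:
        rows = [
            f"{'model':<6}{'lnL':>14}{'AICc':>14}{'weight':>10}"
            f"{'sigma2':>14}{'shape':>12}"
        ]
        for m, f in self.fits.items():
            shape = f.alpha if f.alpha is not None else f.a
            rows.append(
                f"{m:<6}{f.lnL:>14.4f}{f.aicc:>14.4f}{f.weight:>10.4f}"
                f"{f.sigma2:>14.6g}{('' if shape is None else f'{shape:.4g}'):>12}"
            )
        rows.append(f"best: {self.best.model}")
        return "\n".join(rows)


def fit_all_models(
    tree: Chronogram,
    x,
    se=None,
    models=MODELS,
    **kwargs,
) -> ModelComparison:
    """Fit each candidate model and attach AICc weights."""
    fits = {
        m: TraitEvolutionModel(x, tree, se, m, **kwargs).fit() for m in models
    }
    aicc_weights(list(fits.values()))
    return ModelComparison(fits)
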