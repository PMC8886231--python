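"""Ancestral states, absolute per-tip rates of niche change, HPD intervals,
and paired diffusion-rate comparisons across a tree ensemble.

Absolute rates follow the tip/ancestor contrast recipe: reconstruct
ancestral states by GLS under the best-fit model's covariance, then for each
tip take ``|tip value - reconstructed parent state|`` divided by the tip's
branch duration on the original chronogram, giving trait-units per Myr
(°C/Myr for thermal variables).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .models import TraitEvolutionResults, _unit_covariance, gls_mean
from .tree import Chronogram

__all__ = [
    "ancestral_states",
    "absolute_tip_rates",
    "HPDInterval",
    "hpd_interval",
    "compare_sigma2",
]


def _node_tip_unit_cov(
    tree: Chronogram, model: str, params: dict, nodes: np.ndarray
) -> np.ndarray:
    """Model covariance (sigma2 = 1) between internal nodes and the tips."""
    S = tree.node_tip_shared_depths()[nodes]  # shared root-path lengths
    if model == "BM":
        return S
    t_nodes = tree.depths[nodes][:, None]
    t_tips = tree.depths[: tree.n_tips][None, :]
    if model == "EB":
        a = float(params.get("a", 0.0))
        if a == 0.0:
            return S
        return np.expm1(a * S) / a
    if model == "OU":
        alpha = float(params["alpha"])
        damp = np.exp(-alpha * (t_nodes - S)) * np.exp(-alpha * (t_tips - S))
        return damp * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)
    raise ValueError(f"unknown model {model!r}")


def ancestral_states(
    tree: Chronogram,
    x,
    *,
    model: str = "BM",
    params: dict | None = None,
    se=None,
) -> np.ndarray:
    """GLS reconstruction of internal-node states under a fitted model.

    Returns estimates for nodes ``n_tips .. n_nodes-1`` (tree index order).
    The conditional mean is ``z0 + Cov(node, tips) V^-1 (x - z0)`` with
    ``V`` the model covariance of the tips (plus ``diag(se^2)`` when
    sampling error is supplied) and ``z0`` the GLS root estimate.
    """
    model = model.upper()
    params = dict(params or {})
    sigma2 = float(params.get("sigma2", 1.0))
    x = np.asarray(x, dtype=float)
    if x.size != tree.n_tips:
        raise ValueError("x length does not match number of tips")
    C = tree.phylo_covariance().C
    V = sigma2 * _unit_covariance(C, tree.root_age, model, params)
    if se is not None:
        se = np.asarray(se, dtype=float)
        V = V + np.diag(se**2)
    nodes = np.arange(tree.n_tips, tree.n_nodes)
    cov_nt = sigma2 * _node_tip_unit_cov(tree, model, params, nodes)
    z0 = gls_mean(x, V)
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        # duplicate tips (zero-length cherries) make V singular; a tiny
        # ridge keeps the GLS defined without moving the estimates
        ridge = 1e-10 * float(np.trace(V)) / V.shape[0]
        try:
            cho = linalg.cho_factor(
                V + ridge * np.eye(V.shape[0]), lower=True, check_finite=False
            )
        except linalg.LinAlgError:
            lam = float(np.linalg.eigvalsh(V)[0])
            raise linalg.LinAlgError(
                "tip covariance not positive definite "
                f"(smallest eigenvalue {lam:.3g})"
            ) from exc
    w = linalg.cho_solve(cho, x - z0, check_finite=False)
    return z0 + cov_nt @ w


def absolute_tip_rates(
    tree: Chronogram,
    x,
    best_fit: TraitEvolutionResults,
    *,
    se=None,
    denominator: str = "original",
    basis: str = "mean",
) -> pd.DataFrame:
    """Per-tip absolute rate of trait change, in trait units per Myr.

    Ancestral states are reconstructed on the best-fit model's covariance;
    the time denominator is each tip's branch duration on the original
    chronogram (``denominator="transformed"`` instead uses the EB-rescaled
    durations — this destroys the Myr unit and exists for comparison only).
    Tips on zero-length terminal branches get NaN with a warning.
    """
    if denominator not in ("original", "transformed"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    x = np.asarray(x, dtype=float)
    anc = ancestral_states(
        tree, x, model=best_fit.model, params=best_fit.params, se=se
    )
    n = tree.n_tips
    parent_states = anc[tree.parent[:n] - n]
    dt = tree.branch_lengths[:n].copy()
    if denominator == "transformed" and best_fit.model == "EB":
        a = best_fit.params.get("a", 0.0)
        if a != 0.0:
            d1 = tree.depths[tree.parent[:n]]
            d2 = tree.depths[:n]
            dt = (np.exp(a * d2) - np.exp(a * d1)) / a
    rate = np.abs(x - parent_states)
    zero = dt <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} tip(s) on zero-length branches: rate undefined",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(zero, np.nan, rate / np.where(zero, np.nan, dt))
    return pd.DataFrame(
        {
            "tip_label": list(tree.tip_labels),
            "rate": rate,
            "basis": basis,
            "ancestor_state": parent_states,
            "tip_state": x,
            "dt_myr": np.where(zero, np.nan, dt),
        }
    )


@dataclass(frozen=True)
class HPDInterval:
    """Shortest contiguous interval holding ``mass`` of a sample."""

    lo: float
    hi: float
    mass: float = 0.95

    def overlaps(self, other: "HPDInterval") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi

    def __contains__(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def hpd_interval(values, mass: float = 0.95) -> HPDInterval:
    """Highest-density interval by the shortest-window rule.

    Sorts the sample and scans every window of ``ceil(mass * N)`` points,
    returning the narrowest (leftmost on ties).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError("HPD needs at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("HPD input contains non-finite values")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    m = min(v.size, int(math.ceil(mass * v.size)))
    widths = v[m - 1 :] - v[: v.size - m + 1]
    j = int(np.argmin(widths))  # argmin takes the leftmost tie
    return HPDInterval(lo=float(v[j]), hi=float(v[j + m - 1]), mass=mass)


def compare_sigma2(
    fits_a: dict,
    fits_b: dict,
    *,
    label_a: str = "A",
    label_b: str = "B",
    mass: float = 0.95,
) -> dict:
    """Paired comparison of diffusion rates across a tree ensemble.

    ``fits_a``/``fits_b`` map tree ids (``"mcc"`` plus posterior ids) to the
    best-fit sigma2 for each of two variables on that tree. Reports the MCC
    point estimates, HPD intervals over the posterior trees, the fraction
    of trees with ``sigma2_A < sigma2_B``, and an HPD overlap fraction
    (overlap length over union length; 0 = fully segregated).
    """
    if set(fits_a) != set(fits_b):
        raise ValueError("sigma2 comparisons need fits over the same tree ensemble")
    ids = sorted(fits_a)
    a = np.array([float(fits_a[i]) for i in ids])
    b = np.array([float(fits_b[i]) for i in ids])
    post = [i for i in ids if i != "mcc"]
    out = {
        "label_a": label_a,
        "label_b": label_b,
        "n_trees": len(ids),
        "frac_a_lt_b": float(np.mean(a < b)),
        "mcc_a": float(fits_a["mcc"]) if "mcc" in fits_a else float("nan"),
        "mcc_b": float(fits_b["mcc"]) if "mcc" in fits_b else float("nan"),
    }
    if len(post) >= 2:
        ha = hpd_interval([float(fits_a[i]) for i in post], mass)
        hb = hpd_interval([float(fits_b[i]) for i in post], mass)
        out["hpd_a"] = (ha.lo, ha.hi)
        out["hpd_b"] = (hb.lo, hb.hi)
        inter = max(0.0, min(ha.hi, hb.hi) - max(ha.lo, hb.lo))
        union = max(ha.hi, hb.hi) - min(ha.lo, hb.lo)
        out["hpd_overlap"] = float(inter / union) if union > 0 else 1.0
    return out
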