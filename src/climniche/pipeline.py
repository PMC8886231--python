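"""Per-variable, per-tree orchestration of the full analysis.

Runs the four stages — phylogenetic signal, disparity-through-time,
trait-evolution model selection, and rates — for every requested climate
variable on the MCC tree and each posterior tree, and writes tidy CSV
reports (the tabular equivalents of the study's figure panels). Failures
are quarantined per (variable, tree) so one sick optimizer corner does not
kill a 19 × 1001 sweep.

All randomness descends from the single config seed through
``numpy.random.SeedSequence([seed, stage_code, variable_index,
tree_index])``, so any subset of the run reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .disparity import dtt_test
from .models import MODELS, fit_all_models
from .rates import absolute_tip_rates, compare_sigma2, hpd_interval
from .signal import k_randomization_test
from .traits import (
    load_variable_groups,
    read_accessions,
    summarize_all,
    trait_vector,
)
from .tree import TreeEnsemble, load_ensemble

__all__ = [
    "RunConfig",
    "run_signal_stage",
    "run_dtt_stage",
    "run_model_stage",
    "run_rates_stage",
    "run_all",
]

log = logging.getLogger(__name__)

_STAGE_CODES = {"signal": 1, "dtt": 2, "models": 3, "rates": 4}

DEFAULT_SIGMA2_PAIRS = (("BIO5", "BIO6"), ("BIO16", "BIO17"))
DEFAULT_RATE_VARIABLES = ("BIO1", "BIO5", "BIO6")
#: Projected near-term warming used only as a presentation constant in the
#: rate report (°C by 2100, relative to late-20th-century baselines).
PROJECTED_WARMING_C = (1.0, 4.0)


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run."""

    mcc: str
    accessions: str
    posterior: str | None = None
    groups: str | None = None
    variables: tuple = ()          # empty = all BIO variables in the table
    n_rand: int = 1000
    n_sim: int = 1000
    n_posterior_used: int | None = None
    hpd_mass: float = 0.95
    seed: int = 0
    se_formula: str = "sd_over_sqrt_n"
    sigma2_pairs: tuple = DEFAULT_SIGMA2_PAIRS
    rate_variables: tuple = DEFAULT_RATE_VARIABLES
    output_dir: str = "climniche_out"
    workers: int = 1

    def __post_init__(self) -> None:
        if self.n_rand < 1 or self.n_sim < 1:
            raise ValueError("n_rand and n_sim must be >= 1")
        for path in (self.mcc, self.accessions, self.posterior, self.groups):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go and
        how many workers ran does not change the numbers)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        d.pop("workers", None)
        return hashlib.sha1(repr(sorted(d.items())).encode()).hexdigest()[:12]


@dataclass
class _Prepared:
    ensemble: TreeEnsemble
    summary: pd.DataFrame
    variables: list
    groups: dict
    config: RunConfig
    errors: list = field(default_factory=list)

    def stage_rng(self, stage: str, var_idx: int, tree_idx: int) -> np.random.Generator:
        ss = np.random.SeedSequence(
            [int(self.config.seed), _STAGE_CODES[stage], var_idx, tree_idx]
        )
        return np.random.default_rng(ss)


def _prepare(config: RunConfig) -> _Prepared:
    ensemble = load_ensemble(
        config.mcc, config.posterior, max_posterior=config.n_posterior_used
    )
    records = read_accessions(config.accessions)
    summary = summarize_all(records, se_formula=config.se_formula)
    available = list(dict.fromkeys(summary["variable"]))
    variables = list(config.variables) or available
    missing = [v for v in variables if v not in available]
    if missing:
        raise ValueError(f"variables not in the accession table: {missing}")
    groups = load_variable_groups(config.groups) if config.groups else {}
    Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    return _Prepared(ensemble, summary, variables, groups, config)


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# climniche {__version__}\n")
        fh.write(f"# seed={config.seed} config={config.digest()}\n")
        df.to_csv(fh, index=False)


def _per_tree_loop(prep: _Prepared, stage: str, worker):
    """Run ``worker(variable, var_idx, tree_id, tree, rng)`` over the grid,
    quarantining failures; returns rows in deterministic (variable, tree)
    order regardless of scheduling."""
    trees = list(prep.ensemble.items())
    tasks = [
        (var, vi, tree_id, tree, prep.stage_rng(stage, vi, ti))
        for vi, var in enumerate(prep.variables)
        for ti, (tree_id, tree) in enumerate(trees)
    ]

    def guarded(var, vi, tree_id, tree, rng):
        try:
            return ("ok", worker(var, vi, tree_id, tree, rng))
        except Exception as exc:
            return ("err", {"stage": stage, "variable": var, "tree_id": tree_id,
                            "error": f"{type(exc).__name__}: {exc}"})

    if prep.config.workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=prep.config.workers)(
            delayed(guarded)(*t) for t in tasks
        )
    else:
        results = [guarded(*t) for t in tasks]
    rows = []
    for (var, _vi, tree_id, _tree, _rng), (status, payload) in zip(tasks, results):
        if status == "ok":
            rows.append(payload)
        else:
            log.warning("%s failed for %s on %s: %s", stage, var, tree_id,
                        payload["error"])
            prep.errors.append(payload)
    if not rows:
        raise RuntimeError(f"stage {stage!r} failed for every (variable, tree)")
    return rows


def _flush_errors(prep: _Prepared) -> None:
    if prep.errors:
        path = Path(prep.config.output_dir) / "errors.csv"
        header = not path.exists()
        pd.DataFrame(prep.errors).to_csv(path, mode="a", header=header, index=False)
        prep.errors.clear()


def run_signal_stage(config: RunConfig, prep: _Prepared | None = None) -> pd.DataFrame:
    """K and its randomization p per (variable, tree); writes signal.csv."""
    prep = prep or _prepare(config)

    def worker(var, vi, tree_id, tree, rng):
        x, se = trait_vector(prep.summary, var, tree.tip_labels)
        res = k_randomization_test(tree, x, se, n_rand=config.n_rand, seed=rng)
        return {
            "variable": var, "tree_id": tree_id, "K": res.K, "p": res.p,
            "n_rand": res.n_rand, "sigma2_hat": res.sigma2_hat,
            "group": prep.groups.get(var, ""),
        }

    df = pd.DataFrame(_per_tree_loop(prep, "signal", worker))
    _write_csv(df, Path(config.output_dir) / "signal.csv", config)
    _flush_errors(prep)
    return df


def run_dtt_stage(config: RunConfig, prep: _Prepared | None = None) -> pd.DataFrame:
    """MDI and its one-sided p per (variable, tree); writes dtt.csv plus the
    MCC-tree curves (dtt_curves.csv)."""
    prep = prep or _prepare(config)

    def worker(var, vi, tree_id, tree, rng):
        x, _se = trait_vector(prep.summary, var, tree.tip_labels)
        res = dtt_test(tree, x, n_sim=config.n_sim, seed=rng)
        curve = None
        if tree_id == "mcc":
            curve = pd.DataFrame({
                "variable": var, "rel_time": res.rel_times,
                "observed": res.observed, "sim_median": res.sim_median,
                "sim_lo95": res.sim_lo95, "sim_hi95": res.sim_hi95,
            })
        return {
            "variable": var, "tree_id": tree_id, "MDI": res.MDI,
            "p": res.p, "p_upper": res.p_upper, "n_sim": res.n_sim,
            "group": prep.groups.get(var, ""),
        }, curve

    pairs = _per_tree_loop(prep, "dtt", worker)
    curves = [c for _r, c in pairs if c is not None]
    df = pd.DataFrame([r for r, _c in pairs])
    _write_csv(df, Path(config.output_dir) / "dtt.csv", config)
    if curves:
        _write_csv(pd.concat(curves, ignore_index=True),
                   Path(config.output_dir) / "dtt_curves.csv", config)
    _flush_errors(prep)
    return df


def run_model_stage(config: RunConfig, prep: _Prepared | None = None) -> pd.DataFrame:
    """BM/OU/EB fits with AICc weights per (variable, tree); writes
    models.csv. The per-(variable, tree) best model feeds the rate stage."""
    prep = prep or _prepare(config)

    def worker(var, vi, tree_id, tree, rng):
        x, se = trait_vector(prep.summary, var, tree.tip_labels)
        comp = fit_all_models(tree, x, se)
        rows = []
        for m in MODELS:
            f = comp.fits[m]
            rows.append({
                "variable": var, "tree_id": tree_id, "model": m,
                "sigma2": f.sigma2, "z0": f.z0,
                "alpha": f.alpha if f.alpha is not None else np.nan,
                "a": f.a if f.a is not None else np.nan,
                "lnL": f.lnL, "k": f.k, "AICc": f.aicc, "weight": f.weight,
                "best": m == comp.best.model,
                "group": prep.groups.get(var, ""),
            })
        return rows

    rows = [r for rs in _per_tree_loop(prep, "models", worker) for r in rs]
    df = pd.DataFrame(rows)
    _write_csv(df, Path(config.output_dir) / "models.csv", config)
    _flush_errors(prep)
    return df


def run_rates_stage(
    config: RunConfig,
    model_report: pd.DataFrame,
    prep: _Prepared | None = None,
) -> dict:
    """Absolute tip rates and paired sigma2 comparisons; writes rates.csv,
    rates_summary.csv, and sigma2_comparison.csv."""
    prep = prep or _prepare(config)
    best = model_report[model_report["best"]].set_index(["variable", "tree_id"])
    trees = dict(prep.ensemble.items())

    # --- absolute per-tip rates on the MCC tree + HPD over the posterior
    rate_rows = []
    for var in config.rate_variables:
        if var not in prep.variables:
            continue
        for basis in ("mean", "min", "max"):
            per_tree = {}
            for tree_id, tree in trees.items():
                if (var, tree_id) not in best.index:
                    continue
                row = best.loc[(var, tree_id)]
                x, se = trait_vector(prep.summary, var, tree.tip_labels, basis=basis)
                from .models import TraitEvolutionModel

                # refit the winning model on this basis' values
                fit = TraitEvolutionModel(x, tree, se, row["model"]).fit()
                tab = absolute_tip_rates(tree, x, fit, se=se, basis=basis)
                per_tree[tree_id] = tab.set_index("tip_label")["rate"]
            if "mcc" not in per_tree:
                continue
            mcc_rates = per_tree["mcc"]
            post = {k: v for k, v in per_tree.items() if k != "mcc"}
            for tip in mcc_rates.index:
                row = {
                    "variable": var, "basis": basis, "tip_label": tip,
                    "rate_mcc": mcc_rates[tip],
                }
                vals = [v[tip] for v in post.values() if np.isfinite(v[tip])]
                if len(vals) >= 2:
                    h = hpd_interval(vals, config.hpd_mass)
                    row["rate_hpd_lo"], row["rate_hpd_hi"] = h.lo, h.hi
                rate_rows.append(row)
    rates_df = pd.DataFrame(rate_rows)
    if not rates_df.empty:
        _write_csv(rates_df, Path(config.output_dir) / "rates.csv", config)

    # --- summary incl. the projected-warming comparison constant
    summary_rows = []
    for (var, basis), grp in rates_df.groupby(["variable", "basis"]):
        finite = grp["rate_mcc"].dropna()
        row = {
            "variable": var, "basis": basis,
            "mean_rate_mcc": finite.mean(),
            "min_rate_mcc": finite.min(), "max_rate_mcc": finite.max(),
        }
        # historic °C/Myr vs projected °C over ~80 years, expressed as the
        # ratio of projected to historic pace (presentation only)
        projected_rate = PROJECTED_WARMING_C[0] / (80 / 1e6)
        if finite.mean() > 0:
            row["projected_over_historic_min"] = projected_rate / finite.mean()
        summary_rows.append(row)
    if summary_rows:
        _write_csv(pd.DataFrame(summary_rows),
                   Path(config.output_dir) / "rates_summary.csv", config)

    # --- paired sigma2 comparisons from best-fit models
    comp_rows = []
    for var_a, var_b in config.sigma2_pairs:
        try:
            fits_a = best.loc[var_a]["sigma2"].to_dict()
            fits_b = best.loc[var_b]["sigma2"].to_dict()
        except KeyError:
            continue
        shared = sorted(set(fits_a) & set(fits_b))
        res = compare_sigma2(
            {k: fits_a[k] for k in shared}, {k: fits_b[k] for k in shared},
            label_a=var_a, label_b=var_b, mass=config.hpd_mass,
        )
        row = {
            "variable_a": var_a, "variable_b": var_b,
            "sigma2_mcc_a": res["mcc_a"], "sigma2_mcc_b": res["mcc_b"],
            "frac_a_lt_b": res["frac_a_lt_b"], "n_trees": res["n_trees"],
        }
        if "hpd_a" in res:
            row.update({
                "hpd_a_lo": res["hpd_a"][0], "hpd_a_hi": res["hpd_a"][1],
                "hpd_b_lo": res["hpd_b"][0], "hpd_b_hi": res["hpd_b"][1],
                "hpd_overlap": res["hpd_overlap"],
            })
        comp_rows.append(row)
    comp_df = pd.DataFrame(comp_rows)
    if not comp_df.empty:
        _write_csv(comp_df, Path(config.output_dir) / "sigma2_comparison.csv", config)
    _flush_errors(prep)
    return {"rates": rates_df, "sigma2_comparison": comp_df}


def run_all(config: RunConfig) -> dict:
    """Run every stage in order, sharing one prepared dataset."""
    prep = _prepare(config)
    out = {"signal": run_signal_stage(config, prep)}
    out["dtt"] = run_dtt_stage(config, prep)
    out["models"] = run_model_stage(config, prep)
    out.update(run_rates_stage(config, out["models"], prep))
    return out
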