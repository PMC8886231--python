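"""Synthetic chronograms, pseudo-posterior ensembles, and accession data.

Everything here emulates the shape of a genus-level climatic-niche study on
a photobiont-like clade: one ultrametric birth–death chronogram with ~81
OTUs, a jittered "pseudo-posterior" of trees with the same tip set, and an
accession-level table with a heavy-tailed number of accessions per OTU
(min 1, mean ≈ 29, capped at 454) over 19 partially correlated bioclimatic
variables. It lets the whole pipeline run and be tested without any
external download; all generators are deterministic given a seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .models import model_covariance
from .traits import BIO_VARIABLES, DEFAULT_VARIABLE_GROUPS
from .tree import Chronogram, TreeEnsemble

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "make_pseudo_posterior",
    "simulate_traits",
    "simulate_accessions",
    "accession_counts",
    "fixed_study_counts",
    "simulate_climate_table",
    "make_fixture_study",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the dataset shape the analyses assume: 81 OTUs, a
    100-Myr crown age, a heavy-tailed accession-count law with mean near 29
    and a hard cap of 454, and a lognormal branch jitter for the
    pseudo-posterior.
    """

    n_tips: int = 81
    birth_rate: float = 0.15   # events/Myr; conditioned on n_tips, so only
    death_rate: float = 0.05   # the shape of the tree depends on these
    root_age: float = 100.0    # Myr
    model: str = "BM"
    model_params: dict = field(
        default_factory=lambda: {"sigma2": 0.04, "z0": 10.0}
    )  # °C²/Myr scale: gives ~tip SD 2 °C over 100 Myr
    within_otu_sd: float = 2.0    # accession-level spread around the OTU mean
    count_mean: float = 29.1      # target mean accessions/OTU
    count_sigma: float = 1.3      # lognormal shape of the count law
    count_max: int = 454
    n_posterior: int = 100
    branch_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.birth_rate <= 0 or self.death_rate < 0 or self.root_age <= 0:
            raise ValueError("rates and root age must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def simulate_tree(config: SimulationConfig) -> Chronogram:
    """Birth–death chronogram conditioned on ``n_tips``, rescaled to
    ``root_age`` Myr; ultrametric by construction.

    The process is stopped at the n-th birth, which would leave the newest
    cherry with zero-length branches; an extra exponential waiting time is
    appended to every terminal branch (the time to the next event), which
    keeps the tree ultrametric and the terminal branches positive. Tips are
    relabeled ``OTU_001 ..`` deterministically.
    """
    rng = random.Random(int(config.seed))
    last_err = None
    for _ in range(20):
        try:
            dtree = treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_tips,
                rng=rng,
            )
            break
        except Exception as exc:  # total extinction: resample
            last_err = exc
    else:
        raise RuntimeError(f"birth-death simulation kept failing: {last_err}")
    extra = rng.expovariate(config.n_tips * config.birth_rate)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = max(3, len(str(config.n_tips)))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"OTU_{i + 1:0{width}d}"
    tree = Chronogram.from_dendropy(dtree, ultrametric="ignore")
    scale = config.root_age / tree.root_age
    return Chronogram(
        tree.parent, tree.branch_lengths * scale, tree.tip_labels,
        ultrametric="error",
    )


def _jitter_node_ages(
    tree: Chronogram, factors: np.ndarray
) -> Chronogram:
    """Multiply every internal node's age (height above the present) by its
    factor, clamping children below their parents; tips stay at age 0, so
    the result is exactly ultrametric and the root age is ``root_age *
    factors[root]`` whenever no clamp binds at the root (it never does)."""
    ages = tree.root_age - tree.depths
    new_ages = np.where(np.arange(tree.n_nodes) < tree.n_tips, 0.0,
                        ages * factors)
    order = [tree.root]
    stack = list(tree.children[tree.root])
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(tree.children[v])
    for v in order:
        p = tree.parent[v]
        if p >= 0 and v >= tree.n_tips:
            new_ages[v] = min(new_ages[v], new_ages[p] * (1.0 - 1e-9))
    new_bl = np.zeros_like(tree.branch_lengths)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0:
            new_bl[v] = new_ages[p] - new_ages[v]
    return Chronogram(tree.parent.copy(), new_bl, list(tree.tip_labels),
                      ultrametric="error")


def _random_nni(tree: Chronogram, rng: np.random.Generator) -> Chronogram:
    """One nearest-neighbour interchange on a random internal edge."""
    candidates = [
        v for v in range(tree.n_tips, tree.n_nodes)
        if tree.parent[v] >= 0 and len(tree.children[v]) >= 2
    ]
    if not candidates:
        return tree.copy()
    v = int(rng.choice(candidates))
    p = int(tree.parent[v])
    sibs = [c for c in tree.children[p] if c != v]
    if not sibs:
        return tree.copy()
    s = int(rng.choice(np.array(sibs)))
    c = int(rng.choice(np.array(tree.children[v])))
    parent = tree.parent.copy()
    parent[s], parent[c] = v, p
    bl = tree.branch_lengths.copy()
    # keep node depths feasible: swapped children keep their subtree shapes,
    # branch lengths are recomputed against their new parents' depths
    bl[s] = max(tree.depths[s] - tree.depths[v], 1e-9 * tree.root_age)
    bl[c] = max(tree.depths[c] - tree.depths[p], 1e-9 * tree.root_age)
    return Chronogram(parent, bl, list(tree.tip_labels), ultrametric="ignore")


def make_pseudo_posterior(
    tree: Chronogram,
    n: int,
    branch_jitter_sd: float,
    seed: int | np.random.Generator,
    *,
    topology: str = "fixed",
) -> TreeEnsemble:
    """A pseudo-posterior: ``n`` jittered copies of an input chronogram.

    Every internal node's age is multiplied by an independent lognormal
    factor with unit mean (``mu = -sd^2/2``), children clamped below their
    parents, emulating dating uncertainty while staying exactly ultrametric;
    the root age is therefore unbiased across the ensemble.
    ``topology="nni"`` additionally applies one random nearest-neighbour
    interchange per tree. ``jitter_sd = 0`` returns exact copies.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if topology not in ("fixed", "nni"):
        raise ValueError(f"unknown topology mode {topology!r}")
    rng = np.random.default_rng(seed)
    posterior = []
    for _ in range(n):
        if topology == "nni":
            base = _random_nni(tree, rng)
            base = _jitter_node_ages(base, np.ones(base.n_nodes))
        else:
            base = tree
        if branch_jitter_sd == 0.0:
            posterior.append(base.copy())
            continue
        factors = rng.lognormal(
            mean=-0.5 * branch_jitter_sd**2,
            sigma=branch_jitter_sd,
            size=base.n_nodes,
        )
        posterior.append(_jitter_node_ages(base, factors))
    return TreeEnsemble(mcc=tree.copy(), posterior=posterior)


def simulate_traits(
    tree: Chronogram,
    model: str,
    params: dict,
    seed: int | np.random.Generator,
    *,
    n_datasets: int = 1,
) -> np.ndarray:
    """Tip values drawn from the model's Gaussian distribution on the tree.

    ``model`` is BM/OU/EB (via their covariances) or ``white_noise``
    (i.i.d. ``N(z0, sigma2)``, ignoring the tree — the zero-signal regime).
    Returns an ``(n_datasets, n_tips)`` array (squeezed to 1-D when
    ``n_datasets == 1``), tips ordered like ``tree.tip_labels``.
    """
    rng = np.random.default_rng(seed)
    z0 = float(params.get("z0", 0.0))
    sigma2 = float(params.get("sigma2", 1.0))
    n = tree.n_tips
    if model.lower() in ("white_noise", "wn"):
        out = z0 + math.sqrt(sigma2) * rng.standard_normal((n_datasets, n))
    else:
        if sigma2 == 0.0:
            out = np.full((n_datasets, n), z0)
        else:
            V = model_covariance(tree, model, params)
            L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / n * np.eye(n))
            out = z0 + rng.standard_normal((n_datasets, n)) @ L.T
    return out[0] if n_datasets == 1 else out


def accession_counts(
    n_otus: int,
    rng: np.random.Generator,
    *,
    mean: float = 29.1,
    sigma: float = 1.3,
    max_count: int = 454,
) -> np.ndarray:
    """Heavy-tailed accession counts: rounded-up lognormal, clipped to
    ``[1, max_count]``, with the lognormal mean set to the target mean."""
    mu = math.log(mean) - 0.5 * sigma**2
    raw = np.ceil(rng.lognormal(mean=mu, sigma=sigma, size=n_otus))
    return np.clip(raw, 1, max_count).astype(int)


def fixed_study_counts(n_otus: int = 81, total: int = 2359,
                       max_count: int = 454) -> np.ndarray:
    """Deterministic heavy-tailed counts with an exact total.

    Produces one singleton OTU, one OTU at the cap, and lognormal-quantile
    counts in between, adjusted so the counts sum exactly to ``total`` —
    the worked-example shape (81 OTUs, 2,359 accessions: min 1, max 454,
    mean 29.1).
    """
    if n_otus < 3 or total < n_otus:
        raise ValueError("need n_otus >= 3 and total >= n_otus")
    from scipy.stats import norm

    body_n = n_otus - 2
    body_total = total - 1 - max_count
    q = norm.ppf((np.arange(body_n) + 0.5) / body_n)
    weights = np.exp(1.1 * q)
    body = np.maximum(1, np.round(body_total * weights / weights.sum())).astype(int)
    body = np.minimum(body, max_count)
    # fix rounding drift on the largest body entries
    drift = body_total - int(body.sum())
    i = body_n - 1
    while drift != 0 and i >= 0:
        step = 1 if drift > 0 else -1
        if 1 <= body[i] + step <= max_count:
            body[i] += step
            drift -= step
        i = i - 1 if i > 0 else body_n - 1
    counts = np.concatenate(([1], body, [max_count]))
    assert counts.sum() == total and counts.min() >= 1 and counts.max() <= max_count
    return counts


def simulate_accessions(
    tip_means: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    *,
    counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Accession-level records around per-OTU means.

    ``tip_means`` is (OTU × variable); each OTU receives ``n_i`` accessions
    (drawn from the configured count law unless ``counts`` is given) whose
    values are the OTU mean plus ``N(0, within_otu_sd^2)`` noise,
    independent across variables. Returns a frame consumable by
    :func:`climniche.traits.read_accessions` output conventions.
    """
    rng = np.random.default_rng(seed)
    otus = list(tip_means.index)
    if counts is None:
        counts = accession_counts(
            len(otus), rng, mean=config.count_mean,
            sigma=config.count_sigma, max_count=config.count_max,
        )
    counts = np.asarray(counts, dtype=int)
    if counts.size != len(otus) or counts.min() < 1:
        raise ValueError("counts must give every OTU at least one accession")
    rows = []
    for otu, n_i in zip(otus, counts):
        vals = (
            tip_means.loc[otu].to_numpy(float)[None, :]
            + config.within_otu_sd * rng.standard_normal((n_i, tip_means.shape[1]))
        )
        block = pd.DataFrame(vals, columns=list(tip_means.columns))
        block.insert(0, "otu_id", otu)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


#: Default per-group trait models for the 19-variable table: the annual/
#: extreme thermal-humidity blocks (groups 1–3) drift under BM, while the
#: seasonality, humidity-seasonality, isothermality blocks (groups 4–6)
#: and the ungrouped diurnal-range variable evolve under a strong OU pull.
DEFAULT_GROUP_MODELS: dict[str, tuple[str, dict]] = {
    "1": ("BM", {"sigma2": 0.04, "z0": 10.0}),
    "2": ("BM", {"sigma2": 0.06, "z0": 25.0}),
    "3": ("BM", {"sigma2": 0.08, "z0": -2.0}),
    "4": ("OU", {"sigma2": 0.5, "z0": 6.0, "alpha": 0.05}),
    "5": ("OU", {"sigma2": 0.4, "z0": 4.0, "alpha": 0.05}),
    "6": ("OU", {"sigma2": 0.3, "z0": 3.0, "alpha": 0.05}),
    "ungrouped": ("OU", {"sigma2": 0.3, "z0": 8.0, "alpha": 0.05}),
}


def simulate_climate_table(
    tree: Chronogram,
    seed: int | np.random.Generator,
    *,
    group_models: dict | None = None,
    groups: dict | None = None,
    factor_noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Correlated 19-variable tip-mean table from six latent group factors.

    Each group evolves one latent trait on the tree under its model; every
    variable in the group is that factor plus independent tip-level noise
    (``factor_noise_sd``), which reproduces the within-group correlation
    structure the analyses expect without claiming any particular
    inter-variable covariance.
    """
    rng = np.random.default_rng(seed)
    groups = groups or DEFAULT_VARIABLE_GROUPS
    group_models = group_models or DEFAULT_GROUP_MODELS
    factors = {}
    for g, (model, params) in group_models.items():
        factors[g] = simulate_traits(tree, model, params, rng)
    data = {}
    for v in BIO_VARIABLES:
        g = groups[v]
        data[v] = factors[g] + factor_noise_sd * rng.standard_normal(tree.n_tips)
    return pd.DataFrame(data, index=pd.Index(tree.tip_labels, name="otu_id"))


def make_fixture_study(outdir, config: SimulationConfig | None = None) -> dict:
    """Write a complete toy study directory (MCC + posterior Newick,
    accession CSV, variable-group YAML); returns the paths."""
    import pathlib

    import yaml

    config = config or SimulationConfig()
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence([int(config.seed), 20_001])
    s_tree, s_post, s_traits, s_acc = [s.generate_state(1)[0] % 2**31
                                       for s in root.spawn(4)]
    cfg_tree = replace(config, seed=int(s_tree))
    mcc = simulate_tree(cfg_tree)
    ensemble = make_pseudo_posterior(
        mcc, config.n_posterior, config.branch_jitter_sd, int(s_post)
    )
    tip_means = simulate_climate_table(mcc, int(s_traits))
    accessions = simulate_accessions(tip_means, config, int(s_acc))

    paths = {
        "mcc": outdir / "mcc.nwk",
        "posterior": outdir / "posterior.nwk",
        "accessions": outdir / "accessions.csv",
        "groups": outdir / "groups.yaml",
    }
    paths["mcc"].write_text(mcc.to_newick() + "\n")
    with open(paths["posterior"], "w") as fh:
        for t in ensemble.posterior:
            fh.write(t.to_newick() + "\n")
    accessions.to_csv(paths["accessions"], index=False)
    with open(paths["groups"], "w") as fh:
        yaml.safe_dump(DEFAULT_VARIABLE_GROUPS, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
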