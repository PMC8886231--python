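"""Accession-level climate records and per-OTU trait summaries.

Each accession (a georeferenced sequence record) carries values for the 19
bioclimatic variables BIO1–BIO19; analyses run on per-OTU means, with a
sampling error of the mean derived from a pooled within-OTU variance so that
OTUs represented by a single accession still receive a finite error.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BIO_VARIABLES",
    "DEFAULT_VARIABLE_GROUPS",
    "read_accessions",
    "summarize_by_otu",
    "pooled_se",
    "summarize_all",
    "trait_vector",
    "load_variable_groups",
    "write_summary",
]

log = logging.getLogger(__name__)

BIO_VARIABLES = tuple(f"BIO{i}" for i in range(1, 20))

#: Variable groupings used for reporting: six correlated blocks of thermal /
#: humidity variables (annual means; warm/humid-period means; cold/dry-period
#: means; seasonality and range; humidity seasonality; isothermality). BIO2
#: does not load cleanly on a single block and stays ungrouped.
DEFAULT_VARIABLE_GROUPS: dict[str, str] = {
    "BIO1": "1", "BIO12": "1",
    "BIO5": "2", "BIO8": "2", "BIO10": "2", "BIO13": "2", "BIO16": "2", "BIO18": "2",
    "BIO6": "3", "BIO9": "3", "BIO11": "3", "BIO14": "3", "BIO17": "3", "BIO19": "3",
    "BIO4": "4", "BIO7": "4",
    "BIO15": "5",
    "BIO3": "6",
    "BIO2": "ungrouped",
}


def read_accessions(path, *, sep: str | None = None) -> pd.DataFrame:
    """Read an accession table (CSV/TSV with a header row).

    Requires an ``otu_id`` column; BIO columns are matched case-insensitively
    against ``bio1 .. bio19`` and renamed to the canonical upper-case form.
    ``lat``/``lon`` columns are carried through when present. Missing values
    stay as NaN — they are excluded per variable downstream, never zeroed.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    rename = {}
    pat = re.compile(r"^bio_?(\d{1,2})$", re.IGNORECASE)
    for col in df.columns:
        if col.lower() == "otu_id":
            rename[col] = "otu_id"
        elif col.lower() in ("lat", "latitude"):
            rename[col] = "lat"
        elif col.lower() in ("lon", "long", "longitude"):
            rename[col] = "lon"
        else:
            m = pat.match(str(col).strip())
            if m and 1 <= int(m.group(1)) <= 19:
                rename[col] = f"BIO{int(m.group(1))}"
    df = df.rename(columns=rename)
    if "otu_id" not in df.columns:
        raise ValueError("accession table must have an 'otu_id' column")
    if not any(c in df.columns for c in BIO_VARIABLES):
        raise ValueError("accession table has no recognizable BIO1..BIO19 columns")
    df["otu_id"] = df["otu_id"].astype(str)
    if (df["otu_id"].str.len() == 0).any():
        raise ValueError("empty otu_id in accession table")
    return df


def _usable(records: pd.DataFrame, variable: str) -> pd.DataFrame:
    if variable not in records.columns:
        raise KeyError(f"variable {variable!r} not in accession table")
    sub = records[["otu_id", variable]].dropna(subset=[variable])
    n_dropped = len(records) - len(sub)
    if n_dropped:
        log.info("%s: dropped %d records with missing values", variable, n_dropped)
    if sub.empty:
        raise ValueError(f"no usable records for variable {variable!r}")
    return sub


def summarize_by_otu(records: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-OTU mean/min/max/n for one variable.

    Records missing the variable are dropped (for that variable only).
    Returns a frame indexed by ``otu_id`` with columns
    ``mean, min, max, n``.
    """
    sub = _usable(records, variable)
    g = sub.groupby("otu_id")[variable]
    out = pd.DataFrame(
        {"mean": g.mean(), "min": g.min(), "max": g.max(), "n": g.size()}
    )
    out.index.name = "otu_id"
    return out.sort_index()


def pooled_se(
    records: pd.DataFrame,
    variable: str,
    *,
    se_formula: str = "sd_over_sqrt_n",
) -> pd.Series:
    """Per-OTU sampling error of the mean from a pooled within-OTU variance.

    The pooled variance is ``s_p^2 = sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1)``
    over OTUs with ``n_i >= 2`` (``s_i^2`` the within-OTU sample variance).
    The default standard error is ``s_p / sqrt(n_i)`` — finite even for
    singleton OTUs, which is the point of pooling. ``se_formula =
    "var_over_sqrt_n"`` instead divides the pooled *variance* by ``sqrt(n_i)``
    (a literal reading sometimes seen in the literature; dimensionally a
    variance-like quantity, provided for reproducibility only).
    """
    if se_formula not in ("sd_over_sqrt_n", "var_over_sqrt_n"):
        raise ValueError(f"unknown se_formula {se_formula!r}")
    sub = _usable(records, variable)
    g = sub.groupby("otu_id")[variable]
    n = g.size()
    s2 = g.var(ddof=1)
    multi = n >= 2
    if not multi.any():
        raise ValueError(
            f"all OTUs are singletons for {variable!r}: pooled variance is "
            "undefined — supply per-OTU se explicitly or set se = 0"
        )
    dof = (n[multi] - 1).astype(float)
    sp2 = float((dof * s2[multi]).sum() / dof.sum())
    numer = np.sqrt(sp2) if se_formula == "sd_over_sqrt_n" else sp2
    se = numer / np.sqrt(n.astype(float))
    se.name = "se"
    return se.sort_index()


def summarize_all(
    records: pd.DataFrame,
    variables=None,
    *,
    se_formula: str = "sd_over_sqrt_n",
) -> pd.DataFrame:
    """Tidy per-(OTU, variable) summary: mean, min, max, n, se."""
    if variables is None:
        variables = [v for v in BIO_VARIABLES if v in records.columns]
    frames = []
    for v in variables:
        summ = summarize_by_otu(records, v)
        summ = summ.join(pooled_se(records, v, se_formula=se_formula))
        summ.insert(0, "variable", v)
        frames.append(summ.reset_index())
    return pd.concat(frames, ignore_index=True)


def trait_vector(
    summary: pd.DataFrame,
    variable: str,
    tip_labels,
    *,
    basis: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Align a summary table to a tree's tip order.

    Returns ``(x, se)`` arrays ordered like ``tip_labels``; ``basis`` picks
    the mean, min, or max per-OTU value. The sampling error applies to the
    mean; for min/max bases it is reused as-is (the same within-OTU spread
    informs all three).
    """
    if basis not in ("mean", "min", "max"):
        raise ValueError(f"unknown basis {basis!r}")
    sub = summary[summary["variable"] == variable].set_index("otu_id")
    missing = [t for t in tip_labels if t not in sub.index]
    if missing:
        raise KeyError(f"no trait summary for tips: {missing[:5]}")
    sub = sub.loc[list(tip_labels)]
    return sub[basis].to_numpy(float), sub["se"].to_numpy(float)


def load_variable_groups(path=None) -> dict[str, str]:
    """Variable→group mapping from YAML/JSON (defaults when path is None)."""
    if path is None:
        return dict(DEFAULT_VARIABLE_GROUPS)
    with open(path) as fh:
        text = fh.read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    groups = {str(k).upper(): str(v) for k, v in data.items()}
    missing = [v for v in BIO_VARIABLES if v not in groups]
    if missing:
        raise ValueError(f"variable-group config missing: {missing}")
    return groups


def write_summary(summary: pd.DataFrame, path) -> None:
    cols = ["otu_id", "variable", "mean", "min", "max", "n", "se"]
    summary[cols].to_csv(path, index=False)
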