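"""Chronograms, tree ensembles, and phylogenetic covariance.

A :class:`Chronogram` is a rooted, ultrametric, time-scaled phylogeny with
branch lengths in millions of years (Myr). It is the common input of every
analysis in this package: phylogenetic signal, disparity-through-time,
trait-evolution model fitting, and rate estimation. Internally the tree is
stored as flat parent/branch-length arrays (tips first), which makes the
covariance constructions used by the likelihood machinery cheap and
vectorized; Newick I/O is delegated to dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "PhyloCovariance",
    "TreeEnsemble",
    "UltrametricityError",
    "parse_newick",
    "read_newick",
    "read_tree_list",
    "load_ensemble",
    "transform_tree",
]

#: Default relative tolerance (fraction of tree depth) for ultrametricity.
#: Chronograms exported by Bayesian dating software carry rounding noise well
#: below this level; genuine violations sit far above it.
ULTRAMETRIC_REL_TOL = 1e-6


class UltrametricityError(ValueError):
    """Raised when root-to-tip depths differ by more than the tolerance."""


@dataclass(frozen=True)
class PhyloCovariance:
    """Expected trait covariance structure implied by shared ancestry.

    ``C[i, j]`` is the root-to-MRCA path length (Myr) of tips *i* and *j*;
    the diagonal holds root-to-tip depths. Under Brownian motion the trait
    covariance of the tips is ``sigma2 * C``.
    """

    taxa_order: tuple[str, ...]
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be a square matrix")
        if C.shape[0] != len(self.taxa_order):
            raise ValueError("taxa_order length does not match C")
        if not np.allclose(C, C.T, rtol=0, atol=1e-10):
            raise ValueError("C must be symmetric")
        object.__setattr__(self, "C", C)


class Chronogram:
    """Rooted ultrametric tree with branch durations in Myr.

    Nodes are indexed ``0 .. n_nodes-1`` with tips occupying
    ``0 .. n_tips-1``; ``parent[i]`` is the index of node *i*'s parent
    (``-1`` for the root) and ``branch_lengths[i]`` the duration of the
    branch subtending node *i* (0 for the root; any root edge in the input
    is ignored).
    """

    def __init__(
        self,
        parent: np.ndarray,
        branch_lengths: np.ndarray,
        tip_labels: list[str],
        *,
        ultrametric: str = "error",
        rel_tol: float = ULTRAMETRIC_REL_TOL,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_nodes = self.parent.size
        self.n_tips = len(self.tip_labels)
        self._validate(ultrametric=ultrametric, rel_tol=rel_tol)

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(
        cls,
        dtree: dendropy.Tree,
        *,
        ultrametric: str = "error",
        rel_tol: float = ULTRAMETRIC_REL_TOL,
    ) -> "Chronogram":
        leaves = [nd for nd in dtree.leaf_node_iter()]
        labels = []
        for nd in leaves:
            lab = nd.taxon.label if nd.taxon is not None else None
            if not lab:
                raise ValueError("tip without a label in Newick input")
            labels.append(lab)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
        index = {}
        for i, nd in enumerate(leaves):
            index[id(nd)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=np.int64)
        bl = np.zeros(n, dtype=float)
        root = dtree.seed_node
        for nd in dtree.preorder_node_iter():
            i = index[id(nd)]
            if nd is root:
                continue
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                name = labels[i] if i < len(leaves) else f"internal node #{i}"
                raise ValueError(f"missing branch length on edge above {name}")
            bl[i] = float(nd.edge.length)
        return cls(parent, bl, labels, ultrametric=ultrametric, rel_tol=rel_tol)

    # -- validation ---------------------------------------------------

    def _validate(self, *, ultrametric: str, rel_tol: float) -> None:
        if self.n_tips < 2:
            raise ValueError("a chronogram needs at least 2 tips")
        if len(set(self.tip_labels)) != self.n_tips:
            raise ValueError("tip labels must be unique")
        if np.count_nonzero(self.parent < 0) != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.branch_lengths < 0):
            bad = int(np.argmin(self.branch_lengths))
            raise ValueError(f"negative branch length at node {bad}")
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        # depths by preorder accumulation
        order = self._preorder()
        depths = np.zeros(self.n_nodes)
        for i in order:
            p = self.parent[i]
            if p >= 0:
                depths[i] = depths[p] + self.branch_lengths[i]
        self.depths = depths
        self.root_age = float(depths[: self.n_tips].max())
        self._check_ultrametric(mode=ultrametric, rel_tol=rel_tol)

    def _preorder(self) -> np.ndarray:
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)
        self.children = children
        order = []
        stack = [int(np.flatnonzero(self.parent < 0)[0])]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(children[v]))
        if len(order) != self.n_nodes:
            raise ValueError("tree contains a cycle or disconnected node")
        return np.array(order, dtype=np.int64)

    def _check_ultrametric(self, *, mode: str, rel_tol: float) -> None:
        tip_depths = self.depths[: self.n_tips]
        spread = float(tip_depths.max() - tip_depths.min())
        tol = rel_tol * max(self.root_age, np.finfo(float).tiny)
        if spread > tol:
            msg = (
                f"tree is not ultrametric: tip depths span "
                f"[{tip_depths.min():.6g}, {tip_depths.max():.6g}] "
                f"(spread {spread:.3g} > tolerance {tol:.3g})"
            )
            if mode == "error":
                raise UltrametricityError(msg)
            if mode == "warn":
                warnings.warn(msg, stacklevel=3)

    # -- basic queries ------------------------------------------------

    def is_ultrametric(self, rel_tol: float = ULTRAMETRIC_REL_TOL) -> bool:
        tip_depths = self.depths[: self.n_tips]
        return float(np.ptp(tip_depths)) <= rel_tol * max(self.root_age, 1e-300)

    def tip_index(self, labels=None) -> np.ndarray:
        """Indices of `labels` among the tips (defaults to all tips)."""
        lut = {lab: i for i, lab in enumerate(self.tip_labels)}
        if labels is None:
            return np.arange(self.n_tips)
        try:
            return np.array([lut[l] for l in labels], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} not among the tips") from exc

    def copy(self) -> "Chronogram":
        return Chronogram(
            self.parent.copy(),
            self.branch_lengths.copy(),
            list(self.tip_labels),
            ultrametric="ignore",
        )

    # -- covariance machinery -----------------------------------------

    def _ancestry_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_nodes): A[u, v] = u lies on the root→v path
        (u == v included; the root row is all True)."""
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for v in self._preorder():
            p = self.parent[v]
            if p >= 0:
                A[:, v] = A[:, p]
            A[v, v] = True
        return A

    def phylo_covariance(self) -> PhyloCovariance:
        """Tip covariance structure: shared root-to-MRCA path lengths."""
        A = self._ancestry_matrix()[:, : self.n_tips]  # nodes x tips
        # exclude the root edge (branch_lengths[root] == 0 anyway)
        W = A * self.branch_lengths[:, None]
        C = W.T @ A
        C = 0.5 * (C + C.T)
        return PhyloCovariance(tuple(self.tip_labels), C)

    def node_tip_shared_depths(self) -> np.ndarray:
        """(n_nodes, n_tips) matrix of shared root-path lengths between every
        node and every tip — the MRCA depths used for ancestral-state
        covariances."""
        A = self._ancestry_matrix()
        W = A * self.branch_lengths[:, None]
        return W.T @ A[:, : self.n_tips]

    # -- serialization ------------------------------------------------

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        dtree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_tips):
            nodes[i].taxon = taxa.get_taxon(self.tip_labels[i])
        for i, p in enumerate(self.parent):
            nodes[i].edge.length = float(self.branch_lengths[i])
            if p >= 0:
                nodes[p].add_child(nodes[i])
        dtree.seed_node = nodes[self.root]
        dtree.seed_node.edge.length = None
        return dtree

    def to_newick(self, digits: int = 10) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{digits}g}"

        def rec(v: int) -> str:
            if v < self.n_tips:
                lab = _quote_label(self.tip_labels[v])
                return f"{lab}:{fmt(self.branch_lengths[v])}"
            inner = ",".join(rec(c) for c in self.children[v])
            if v == self.root:
                return f"({inner})"
            return f"({inner}):{fmt(self.branch_lengths[v])}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Chronogram: {self.n_tips} tips, root age "
            f"{self.root_age:.4g} Myr>"
        )


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;,= \t'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Parsing


def parse_newick(
    text: str,
    *,
    ultrametric: str = "error",
    rel_tol: float = ULTRAMETRIC_REL_TOL,
) -> Chronogram:
    """Parse a single Newick string into a :class:`Chronogram`.

    Quoted labels, ``[...]`` comments, and internal-node labels/support
    values are accepted (and the latter ignored); a root edge length is
    dropped. ``ultrametric`` is one of ``"error"``, ``"warn"``,
    ``"ignore"``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Chronogram.from_dendropy(dtree, ultrametric=ultrametric, rel_tol=rel_tol)


def read_newick(path, **kwargs) -> Chronogram:
    """Read the first tree in a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read(), **kwargs)


def read_tree_list(path, **kwargs) -> list[Chronogram]:
    """Read a multi-tree Newick file (one tree per line or ;-separated)."""
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick tree list in {path}: {exc}") from exc
    return [Chronogram.from_dendropy(t, **kwargs) for t in trees]


# ---------------------------------------------------------------------------
# Ensembles


@dataclass
class TreeEnsemble:
    """An MCC summary tree plus an ordered posterior tree sample.

    All trees must share an identical tip-label set; the posterior may be
    empty (MCC-only analyses).
    """

    mcc: Chronogram
    posterior: list[Chronogram] = field(default_factory=list)

    def __post_init__(self) -> None:
        ref = set(self.mcc.tip_labels)
        for k, t in enumerate(self.posterior):
            if set(t.tip_labels) != ref:
                raise ValueError(
                    f"posterior tree {k} has a different tip set than the MCC tree"
                )

    def __len__(self) -> int:
        return 1 + len(self.posterior)

    def items(self):
        """Yield (tree_id, tree) pairs: ``"mcc"`` first, then ``"post_0001"``…"""
        yield "mcc", self.mcc
        width = max(4, len(str(len(self.posterior))))
        for k, t in enumerate(self.posterior):
            yield f"post_{k + 1:0{width}d}", t


def load_ensemble(
    mcc_path,
    posterior_path=None,
    *,
    max_posterior: int | None = None,
    **kwargs,
) -> TreeEnsemble:
    """Load an MCC tree and (optionally) a multi-tree posterior file."""
    mcc = read_newick(mcc_path, **kwargs)
    posterior: list[Chronogram] = []
    if posterior_path is not None:
        posterior = read_tree_list(posterior_path, **kwargs)
        if max_posterior is not None:
            posterior = posterior[:max_posterior]
    return TreeEnsemble(mcc, posterior)


# ---------------------------------------------------------------------------
# Model-based tree transformations


def transform_tree(tree: Chronogram, model: str, params: dict | None = None,
                   *, allow_ac: bool = False) -> Chronogram:
    """Rescale branch durations according to a trait-evolution model.

    BM is the identity. Under an early-burst model with exponent ``a`` a
    branch spanning absolute times ``t1 → t2`` (from the root) becomes
    ``(exp(a*t2) - exp(a*t1)) / a``; ``a = 0`` leaves the tree unchanged and
    ``a > 0`` (accelerating rates) is rejected unless ``allow_ac=True``.

    The non-stationary OU covariance is not exactly representable as a
    rescaled tree, so OU consumers work in covariance space instead — see
    :func:`climniche.models.model_covariance`. The input is never mutated.
    """
    params = dict(params or {})
    model = model.upper()
    if model == "BM":
        return tree.copy()
    if model == "OU":
        raise ValueError(
            "the OU transform is realized as a covariance, not a tree; "
            "use climniche.models.model_covariance(tree, 'OU', params)"
        )
    if model != "EB":
        raise ValueError(f"unknown model {model!r}")
    a = float(params.get("a", 0.0))
    if a > 0 and not allow_ac:
        raise ValueError("EB exponent a must be <= 0 (pass allow_ac=True for AC)")
    if a == 0.0:
        return tree.copy()
    new_bl = np.zeros_like(tree.branch_lengths)
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        t1, t2 = tree.depths[p], tree.depths[i]
        new_bl[i] = (np.exp(a * t2) - np.exp(a * t1)) / a
    return Chronogram(tree.parent.copy(), new_bl, list(tree.tip_labels),
                      ultrametric="ignore")
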