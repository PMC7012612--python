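"""Continuous phenotypes on trees: composite longevity traits and branch paths.

Two derived longevity phenotypes are built from species trait data by PCA on
log-scaled, standardized maximum lifespan and adult body size:

* 3L ("long-lived and large-bodied") — the first principal component, the
  shared size/lifespan axis;
* ELL ("exceptionally long-lived for its body size") — the second principal
  component, orthogonal to 3L, which contrasts lifespan against the value
  predicted from body size.

To compare a phenotype against branch-specific evolutionary rates, the tip
values are converted into *phenotype paths*: maximum-likelihood ancestral
states under Brownian motion are reconstructed at every internal node, and
each branch is assigned the child-minus-parent difference. This is the
phylogenetically independent change in the phenotype along each branch.

The ML reconstruction exploits the Gaussian structure of Brownian motion:
the reconstructed states minimize the sum of squared per-branch changes
divided by branch length, a sparse quadratic problem solved through the
tree's weighted Laplacian. The solve is precomputed once per tree as a
linear operator (branch deltas = matrix @ tip values), which makes repeated
reconstruction over thousands of permuted phenotypes a single matrix
multiplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .trees import PhyloTree, branch_label

__all__ = [
    "TraitTable",
    "PhenotypeTable",
    "PhenotypePaths",
    "compute_3l_ell",
    "ancestral_states",
    "phenotype_paths",
]

#: Relative epsilon substituted for zero-length branches in the reconstruction.
ZERO_BRANCH_EPS = 1e-9


@dataclass
class TraitTable:
    """Species-level trait data: maximum lifespan (years) and body size (mass)."""

    data: pd.DataFrame  # columns: species, max_lifespan, body_size

    REQUIRED = ("species", "max_lifespan", "body_size")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        if self.data["species"].duplicated().any():
            dupes = self.data.loc[self.data["species"].duplicated(), "species"]
            raise ValueError(f"duplicate species rows: {sorted(set(dupes))}")

    @property
    def species(self) -> List[str]:
        return list(self.data["species"])

    @classmethod
    def read_csv(cls, path: str | Path) -> "TraitTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def restrict(self, species: set) -> "TraitTable":
        sub = self.data[self.data["species"].isin(species)].reset_index(drop=True)
        return TraitTable(sub)


@dataclass
class PhenotypeTable:
    """Per-species composite longevity phenotype scores (3L and ELL)."""

    data: pd.DataFrame  # columns: species, p3l, ell

    @property
    def species(self) -> List[str]:
        return list(self.data["species"])

    def phenotype(self, which: str) -> Dict[str, float]:
        """Tip-value mapping for ``which`` in {"3l", "ell"}."""
        col = {"3l": "p3l", "ell": "ell", "p3l": "p3l"}.get(which.lower())
        if col is None:
            raise ValueError(f"unknown phenotype {which!r}")
        return dict(zip(self.data["species"], self.data[col]))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def compute_3l_ell(traits: TraitTable, log_transform: bool = True) -> PhenotypeTable:
    """PCA of (log) lifespan and body size into the 3L and ELL phenotypes.

    Both traits are log10-transformed (they span orders of magnitude across
    mammals), z-scored, and decomposed; PC1 becomes 3L and PC2 becomes ELL.
    Signs are fixed so that 3L correlates positively with log lifespan and
    ELL correlates positively with the residual of log lifespan regressed on
    log body size.
    """
    df = traits.data
    if len(df) < 3:
        raise ValueError("need at least 3 species for phenotype PCA")
    for col in ("max_lifespan", "body_size"):
        bad = df.loc[df[col] <= 0, "species"]
        if len(bad):
            raise ValueError(
                f"non-positive {col} for species: {sorted(bad)}; "
                "trait values must be strictly positive"
            )
    life = df["max_lifespan"].to_numpy(dtype=float)
    size = df["body_size"].to_numpy(dtype=float)
    if log_transform:
        life, size = np.log10(life), np.log10(size)
    X = np.column_stack([size, life])
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cov = np.cov(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    scores = Z @ eigvecs[:, order]
    p3l, ell = scores[:, 0], scores[:, 1]
    # orient: 3L up with log lifespan, ELL up with lifespan-given-size residual
    if np.corrcoef(p3l, life)[0, 1] < 0:
        p3l = -p3l
    resid = life - np.polyval(np.polyfit(size, life, 1), size)
    if ell.std() > 0 and resid.std() > 0 and np.corrcoef(ell, resid)[0, 1] < 0:
        ell = -ell
    return PhenotypeTable(
        pd.DataFrame({"species": df["species"], "p3l": p3l, "ell": ell})
    )


# -- ancestral reconstruction ------------------------------------------------


def _anc_operators(tree: PhyloTree):
    """Cached linear operators for Brownian ML reconstruction on ``tree``.

    Returns ``(tip_order, internal_ids, M, P)`` where ``M`` maps tip values
    to internal-node states and ``P`` maps tip values to per-branch deltas
    (child state minus parent state) in the tree's canonical branch order.
    """
    cached = tree._cache.get("anc_ops")
    if cached is not None:
        return cached

    tips = [n for n in tree.iter_nodes() if n.is_leaf]
    tips.sort(key=lambda n: n.name)
    internal = [n for n in tree.iter_nodes() if not n.is_leaf]
    tip_idx = {id(n): i for i, n in enumerate(tips)}
    int_idx = {id(n): i for i, n in enumerate(internal)}
    nt, ni = len(tips), len(internal)

    depth = tree.depth()
    eps = ZERO_BRANCH_EPS * (depth if depth > 0 else 1.0)

    L_ii = np.zeros((ni, ni))
    L_it = np.zeros((ni, nt))
    had_zero = False
    for node in tree.iter_nodes():
        if node is tree.root:
            continue
        length = node.length
        if length <= 0:
            had_zero = True
            length = eps
        w = 1.0 / length
        p = int_idx[id(node.parent)]
        L_ii[p, p] += w
        if node.is_leaf:
            L_it[p, tip_idx[id(node)]] -= w
        else:
            c = int_idx[id(node)]
            L_ii[c, c] += w
            L_ii[p, c] -= w
            L_ii[c, p] -= w
    if had_zero:
        warnings.warn(
            "zero-length branches replaced by epsilon for ancestral "
            "reconstruction",
            stacklevel=3,
        )
    M = np.linalg.solve(L_ii, -L_it)  # internal states = M @ tip values
    # each internal estimate is a convex combination of tips: enforce the
    # exact row-sum so constant traits reconstruct exactly even when near
    # zero-length branches make the solve ill-conditioned
    M += (1.0 - M.sum(axis=1))[:, None] / nt

    # branch deltas: child minus parent, in canonical branch order
    branch_nodes = tree.branch_nodes()
    P = np.zeros((len(branch_nodes), nt))
    for b, node in enumerate(branch_nodes):
        if node.is_leaf:
            P[b, tip_idx[id(node)]] += 1.0
        else:
            P[b] += M[int_idx[id(node)]]
        P[b] -= M[int_idx[id(node.parent)]]

    tip_order = [n.name for n in tips]
    internal_ids = [tree.tipset(n) for n in internal]
    tree._cache["anc_ops"] = (tip_order, internal_ids, M, P)
    return tree._cache["anc_ops"]


def _tip_vector(tree: PhyloTree, tipvals: Mapping[str, float]) -> np.ndarray:
    tip_order, _, _, _ = _anc_operators(tree)
    missing = [t for t in tip_order if t not in tipvals]
    if missing:
        raise ValueError(f"missing tip values for: {missing}")
    return np.array([float(tipvals[t]) for t in tip_order])


def ancestral_states(
    tree: PhyloTree, tipvals: Mapping[str, float]
) -> Dict[frozenset, float]:
    """Brownian-motion ML states at internal nodes.

    Nodes are keyed by their descendant tip-set (the root maps to the full
    tip set). Estimates equal the conditional expectations of the node
    states given the tips under Brownian motion, obtained by minimizing the
    sum over branches of (squared state change / branch length).
    """
    tip_order, internal_ids, M, _ = _anc_operators(tree)
    t = _tip_vector(tree, tipvals)
    states = M @ t
    return dict(zip(internal_ids, states))


@dataclass
class PhenotypePaths:
    """Per-branch phenotype change on a tree.

    ``delta[i]`` is the reconstructed child state minus parent state for the
    i-th branch in the tree's canonical branch order.
    """

    branch_ids: List[frozenset]
    delta: np.ndarray
    node_states: Dict[frozenset, float]
    root_state: float

    @property
    def labels(self) -> List[str]:
        return [branch_label(ts) for ts in self.branch_ids]

    def as_series(self) -> pd.Series:
        return pd.Series(self.delta, index=self.labels, name="delta")

    def write_tsv(self, path: str | Path) -> None:
        self.as_series().rename_axis("branch").to_csv(path, sep="\t")


def phenotype_paths(tree: PhyloTree, tipvals: Mapping[str, float]) -> PhenotypePaths:
    """Branch-wise phenotype change from ML ancestral reconstruction.

    For every branch (terminal branches included), the path value is the
    child node's state minus the parent node's state; summing path values
    along any root-to-tip path telescopes back to that tip's value minus the
    root state.
    """
    tip_order, internal_ids, M, P = _anc_operators(tree)
    t = _tip_vector(tree, tipvals)
    delta = P @ t
    states = dict(zip(internal_ids, M @ t))
    return PhenotypePaths(
        branch_ids=tree.branch_ids(),
        delta=delta,
        node_states=states,
        root_state=float(states[tree.tip_set]),
    )


def paths_operator(tree: PhyloTree) -> Tuple[List[str], np.ndarray]:
    """Expose the (tip order, delta matrix) pair for batched reconstruction.

    ``deltas = P @ values`` where ``values`` has one row per tip in
    ``tip_order``; columns may hold many phenotypes (e.g. permulation
    replicates) at once.
    """
    tip_order, _, _, P = _anc_operators(tree)
    return tip_order, P
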