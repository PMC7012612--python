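"""Rank-based pathway enrichment of gene association statistics.

For each annotated pathway, the signed -log p statistics of its member
genes are compared to those of all other pathway-annotated genes with a
Wilcoxon rank-sum statistic (tie-corrected normal approximation). The
background is deliberately restricted to genes appearing in at least one
pathway annotation, so genes absent from the annotation universe cannot
shift any enrichment. A negative z means the pathway's genes sit toward the
constrained (negative-statistic) end of the ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GeneSetCollection",
    "EnrichmentConfig",
    "read_gmt",
    "write_gmt",
    "enrich",
    "ranksum_z",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) and their gene universe."""

    sets: Dict[str, List[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set {name!r}")

    @property
    def universe(self) -> frozenset:
        return frozenset(g for genes in self.sets.values() for g in genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> List[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, tab-separated genes).

    Duplicate genes within a set are dropped with a warning; malformed lines
    raise an error naming the line number.
    """
    path = Path(path)
    sets: Dict[str, List[str]] = {}
    descriptions: Dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT lines need name, description and at "
                f"least one gene (got {len(fields)} fields)"
            )
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            warnings.warn(
                f"{path}:{lineno}: duplicate genes in set {name!r} removed",
                stacklevel=2,
            )
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = deduped
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class EnrichmentConfig:
    """Size bounds applied to each set after intersection with measured genes."""

    min_set_size: int = 10
    max_set_size: int = 500

    def __post_init__(self) -> None:
        if not 1 <= self.min_set_size <= self.max_set_size:
            raise ValueError("need 1 <= min_set_size <= max_set_size")


def ranksum_z(
    values: np.ndarray, member_idx: Sequence[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized Wilcoxon rank-sum z and two-sided p for many gene sets.

    ``values`` holds the background statistics; each entry of ``member_idx``
    indexes one set's members within it. Uses the tie-corrected normal
    approximation with continuity correction, signed so that members ranking
    low (negative statistics) give negative z.
    """
    values = np.asarray(values, dtype=float)
    N = values.size
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    n1 = np.array([len(ix) for ix in member_idx], dtype=float)
    r1 = np.array([ranks[ix].sum() for ix in member_idx])
    n2 = N - n1
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        sigma = np.sqrt(sigma2)
        diff = u - mu
        z = np.sign(diff) * np.maximum(np.abs(diff) - 0.5, 0.0) / sigma
    z = np.where(sigma > 0, z, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def prepare_membership(
    collection: GeneSetCollection,
    measured_genes: Iterable[str],
    config: Optional[EnrichmentConfig] = None,
) -> Tuple[List[str], Dict[str, np.ndarray]]:
    """Restrict to the annotated background and size-filtered sets.

    Returns the ordered background gene list (measured genes that appear in
    at least one set) and, for each surviving pathway, the indices of its
    members within that background.
    """
    if config is None:
        config = EnrichmentConfig()
    universe = collection.universe
    background = sorted(g for g in measured_genes if g in universe)
    if not background:
        raise ValueError("no measured genes overlap the pathway universe")
    pos = {g: i for i, g in enumerate(background)}
    member_idx: Dict[str, np.ndarray] = {}
    for name, genes in collection.sets.items():
        idx = np.array(sorted(pos[g] for g in genes if g in pos), dtype=int)
        if not config.min_set_size <= idx.size <= config.max_set_size:
            continue
        if idx.size == len(background):  # no complement to rank against
            continue
        member_idx[name] = idx
    return background, member_idx


def enrich(
    assoc: pd.DataFrame,
    collection: GeneSetCollection,
    config: Optional[EnrichmentConfig] = None,
) -> pd.DataFrame:
    """Pathway enrichment of the per-gene signed -log p statistics.

    ``assoc`` is the gene association table (indexed by gene, with a
    ``stat`` column). Returns a DataFrame indexed by pathway with columns
    ``n_genes, stat, p_param, p_perm, p_adj``; ``p_perm`` and ``p_adj`` are
    NaN until filled by the permulation step.
    """
    background, member_idx = prepare_membership(collection, assoc.index, config)
    values = assoc.loc[background, "stat"].to_numpy()
    names = sorted(member_idx)
    z, p = ranksum_z(values, [member_idx[n] for n in names])
    return pd.DataFrame(
        {
            "n_genes": [member_idx[n].size for n in names],
            "stat": z,
            "p_param": p,
            "p_perm": np.nan,
            "p_adj": np.nan,
        },
        index=pd.Index(names, name="pathway"),
    )
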