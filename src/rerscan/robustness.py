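"""Robustness analyses: species subsampling and alternate topologies.

A scan's conclusions should not hinge on which species happened to be
sequenced or on uncertain parts of the species topology. These harnesses
rerun the entire analysis (master tree, phenotype PCA refit on the subset,
RERs, associations, enrichments) after removing species — randomly at a
ladder of removal fractions, or as targeted named groups (e.g. marine
mammals) — or after swapping in an alternate master topology, and then
correlate the signed -log p results of the rerun against the full run on
the items tested by both.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import AssociationConfig
from .enrichment import EnrichmentConfig, GeneSetCollection
from .model import RERScan
from .phenotypes import TraitTable
from .rer import RERConfig
from .trees import GeneTreeSet, PhyloTree, TreeError, robinson_foulds

__all__ = [
    "RemovalPlan",
    "ResultComparison",
    "subsample_and_rerun",
    "targeted_removal",
    "compare_topologies",
]

#: Below this many species a rerun is considered non-analyzable and skipped.
MIN_ANALYZABLE_SPECIES = 10


@dataclass
class RemovalPlan:
    """Species-removal schedule for robustness reruns."""

    mode: str = "random"  # "random" | "targeted"
    levels: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    n_draws: int = 10
    seed: int = 0
    targeted_sets: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("random", "targeted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(not 0.0 <= f < 1.0 for f in self.levels):
            raise ValueError("removal fractions must lie in [0, 1)")

    def n_removed(self, level: float, n_species: int) -> int:
        """Species removed at a fraction: floor(level * n)."""
        return int(level * n_species)


@dataclass
class ResultComparison:
    """Agreement between a full run and a rerun on reduced/altered input."""

    name: str
    level: float
    draw: int
    n_species: int
    gene_pearson: float
    gene_spearman: float
    n_genes_common: int
    pathway_pearson: float = np.nan
    pathway_spearman: float = np.nan
    n_pathways_common: int = 0


def _signed_logp(df: pd.DataFrame, stat_col: str, p_col: str) -> pd.Series:
    return np.sign(df[stat_col]) * (-np.log(np.maximum(df[p_col], 1e-300)))


def _corr_pair(a: pd.Series, b: pd.Series) -> Tuple[float, float, int]:
    common = a.index.intersection(b.index)
    if len(common) < 3:
        return np.nan, np.nan, len(common)
    x = a.loc[common].to_numpy()
    y = b.loc[common].to_numpy()
    if np.array_equal(x, y):
        return 1.0, 1.0, len(common)
    return (
        float(sps.pearsonr(x, y)[0]),
        float(sps.spearmanr(x, y)[0]),
        len(common),
    )


def _run_scan(
    genes: GeneTreeSet,
    traits: TraitTable,
    collection: Optional[GeneSetCollection],
    phenotype: str,
    rer_config: Optional[RERConfig],
    assoc_config: Optional[AssociationConfig],
    enrich_config: Optional[EnrichmentConfig],
    master: Optional[PhyloTree] = None,
):
    model = RERScan(
        gene_trees=genes,
        traits=traits,
        gene_sets=collection,
        phenotype=phenotype,
        master=master,
        rer_config=rer_config,
        assoc_config=assoc_config,
        enrich_config=enrich_config,
    )
    return model.fit()


def _rerun_master(full_results) -> Optional[PhyloTree]:
    """Reuse the full run's master when it was supplied by the user; when it
    was estimated from the gene trees, reruns re-estimate it from scratch."""
    if full_results is not None and full_results.model.master_was_provided:
        return full_results.model.master
    return None


def _compare_runs(full, sub, name: str, level: float, draw: int) -> ResultComparison:
    g_full = _signed_logp(full.associations, "stat", "p")
    g_sub = _signed_logp(sub.associations, "stat", "p")
    gp, gs, ng = _corr_pair(g_full, g_sub)
    pp = ps = np.nan
    np_common = 0
    if full.enrichments is not None and sub.enrichments is not None:
        e_full = _signed_logp(full.enrichments, "stat", "p_param")
        e_sub = _signed_logp(sub.enrichments, "stat", "p_param")
        pp, ps, np_common = _corr_pair(e_full, e_sub)
    return ResultComparison(
        name=name,
        level=level,
        draw=draw,
        n_species=len(sub.model.species),
        gene_pearson=gp,
        gene_spearman=gs,
        n_genes_common=ng,
        pathway_pearson=pp,
        pathway_spearman=ps,
        n_pathways_common=np_common,
    )


def subsample_and_rerun(
    genes: GeneTreeSet,
    traits: TraitTable,
    plan: RemovalPlan,
    collection: Optional[GeneSetCollection] = None,
    phenotype: str = "3l",
    rer_config: Optional[RERConfig] = None,
    assoc_config: Optional[AssociationConfig] = None,
    enrich_config: Optional[EnrichmentConfig] = None,
    full_results=None,
) -> pd.DataFrame:
    """Rerun the scan at each removal level/draw and compare to the full run.

    At each level, ``floor(level * n_species)`` species are removed at
    random (``n_draws`` independent draws per level, seeded from the plan);
    the scan — including the phenotype PCA, refit within the subset — is
    rerun from scratch and its signed -log p results are correlated against
    the full-data results over the genes (and pathways) tested by both.
    Draws that would leave fewer than 10 species are skipped with a warning.
    """
    if full_results is None:
        full_results = _run_scan(
            genes, traits, collection, phenotype, rer_config, assoc_config,
            enrich_config,
        )
    species = sorted(full_results.model.species)
    rows: List[ResultComparison] = []
    for li, level in enumerate(plan.levels):
        n_remove = plan.n_removed(level, len(species))
        for draw in range(plan.n_draws):
            if len(species) - n_remove < MIN_ANALYZABLE_SPECIES:
                warnings.warn(
                    f"level {level}: removal leaves fewer than "
                    f"{MIN_ANALYZABLE_SPECIES} species; draw skipped",
                    stacklevel=2,
                )
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([plan.seed, li, draw])
            )
            removed = set(rng.choice(species, size=n_remove, replace=False))
            keep = set(species) - removed
            sub = _run_scan(
                genes, traits.restrict(keep), collection, phenotype,
                rer_config, assoc_config, enrich_config,
                master=_rerun_master(full_results),
            )
            rows.append(
                _compare_runs(full_results, sub, f"random_{level:g}", level, draw)
            )
    return pd.DataFrame([asdict(r) for r in rows])


def targeted_removal(
    genes: GeneTreeSet,
    traits: TraitTable,
    species_to_drop: Iterable[str],
    collection: Optional[GeneSetCollection] = None,
    phenotype: str = "3l",
    name: str = "targeted",
    rer_config: Optional[RERConfig] = None,
    assoc_config: Optional[AssociationConfig] = None,
    enrich_config: Optional[EnrichmentConfig] = None,
    full_results=None,
) -> ResultComparison:
    """Remove a named species group (e.g. marine mammals) and compare."""
    if full_results is None:
        full_results = _run_scan(
            genes, traits, collection, phenotype, rer_config, assoc_config,
            enrich_config,
        )
    species = full_results.model.species
    drop = set(species_to_drop)
    unknown = drop - set(species)
    if unknown:
        raise TreeError(f"unknown species: {sorted(unknown)}")
    keep = set(species) - drop
    if len(keep) < MIN_ANALYZABLE_SPECIES:
        raise ValueError("targeted removal leaves too few species")
    sub = _run_scan(
        genes, traits.restrict(keep), collection, phenotype, rer_config,
        assoc_config, enrich_config, master=_rerun_master(full_results),
    )
    frac = len(drop) / len(species)
    return _compare_runs(full_results, sub, name, frac, 0)


def compare_topologies(
    genes: GeneTreeSet,
    traits: TraitTable,
    alt_master: PhyloTree,
    collection: Optional[GeneSetCollection] = None,
    phenotype: str = "3l",
    rer_config: Optional[RERConfig] = None,
    assoc_config: Optional[AssociationConfig] = None,
    enrich_config: Optional[EnrichmentConfig] = None,
    full_results=None,
) -> Tuple[ResultComparison, int]:
    """Rerun the scan on an alternate master topology.

    Gene-tree branches are re-mapped onto the alternate topology by tip-set;
    branches with no counterpart become missing cells. Returns the result
    comparison together with the Robinson-Foulds distance between the
    original and alternate masters.
    """
    if full_results is None:
        full_results = _run_scan(
            genes, traits, collection, phenotype, rer_config, assoc_config,
            enrich_config,
        )
    original = full_results.model.master
    if alt_master.tip_set != frozenset(full_results.model.species):
        raise TreeError("alternate master must share the analysis species set")
    rf = robinson_foulds(original, alt_master)
    alt_rer_config = replace(
        rer_config if rer_config is not None else RERConfig(),
        allow_incongruent=(rf != 0),
    )
    sub = _run_scan(
        genes, traits, collection, phenotype, alt_rer_config, assoc_config,
        enrich_config, master=alt_master,
    )
    comparison = _compare_runs(full_results, sub, "alt_topology", 0.0, 0)
    return comparison, rf
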