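"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the real inputs of a rate-trait scan without any
external data: a fixed mammal species tree (the bundled 61-species analysis
tree by default), two correlated traits evolving by Brownian motion on it
(log body size and log maximum lifespan), and per-gene trees that are
noisy, rate-scaled copies of the master tree. A configurable subset of
genes is *planted*: their branch rates are additionally coupled to the
branch-wise phenotype change, which is exactly the signal the association
stage tests for. Ground truth (which genes, which direction) is recorded so
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .enrichment import GeneSetCollection
from .phenotypes import PhenotypePaths, TraitTable, compute_3l_ell, phenotype_paths
from .trees import (
    EXCLUDED_FOR_MISSING_TRAITS,
    GeneTreeSet,
    PhyloTree,
    load_fixture_tree,
    prune,
)

import pandas as pd

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "default_master",
    "generate_traits",
    "generate_gene_trees",
    "generate_gene_sets",
    "generate_dataset",
]

# Brownian rates for the two log10 traits, chosen so tip values span the
# ranges seen across mammals (body mass over several orders of magnitude,
# maximum lifespan over roughly two) on a tree of ~0.4 substitutions
# root-to-tip depth.
LOG10_BODY_SIZE_RATE = 6.0
LOG10_LIFESPAN_RATE = 1.0
LOG10_BODY_SIZE_ROOT = 3.0  # ~1 kg in grams
LOG10_LIFESPAN_ROOT = 1.2  # ~16 years


def default_master() -> PhyloTree:
    """The bundled mammal tree restricted to the 61 analysis species."""
    full = load_fixture_tree("mammal61")
    keep = full.tip_set - set(EXCLUDED_FOR_MISSING_TRAITS)
    return prune(full, keep)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults describe the reference condition used throughout the tests:
    the 61-species mammal tree, 500 genes of which 10% carry a planted
    rate-phenotype coupling of strength 0.5 (on the standardized-path,
    log-rate scale, with the constraint sign: rates drop where the
    phenotype rises), multiplicative lognormal branch noise with cv 0.3,
    and log body size / log lifespan evolving with Brownian correlation
    0.75.
    """

    master: Optional[PhyloTree] = None
    n_genes: int = 500
    frac_associated: float = 0.10
    effect_size: float = 0.5
    gene_noise_cv: float = 0.3
    trait_corr: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_associated <= 1.0:
            raise ValueError("frac_associated must lie in [0, 1]")
        if self.gene_noise_cv <= 0:
            raise ValueError("gene_noise_cv must be > 0")
        if not -1.0 <= self.trait_corr <= 1.0:
            raise ValueError("trait_corr must lie in [-1, 1]")
        if self.master is None:
            self.master = default_master()

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class GroundTruth:
    """Which genes carry a planted association, and with what sign."""

    associated_genes: Set[str]
    direction: Dict[str, int] = field(default_factory=dict)


def _gene_ids(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_traits(spec: SyntheticSpec) -> TraitTable:
    """Correlated bivariate Brownian traits on the master tree.

    Log10 body size and log10 maximum lifespan receive jointly normal
    per-branch increments with correlation ``trait_corr``; the exponentiated
    tip values are strictly positive by construction.
    """
    tree = spec.master
    rng = spec.rng(1)
    rho = spec.trait_corr
    sb, sl = LOG10_BODY_SIZE_RATE, LOG10_LIFESPAN_RATE
    states: Dict[int, np.ndarray] = {
        id(tree.root): np.array([LOG10_BODY_SIZE_ROOT, LOG10_LIFESPAN_ROOT])
    }
    chol = np.linalg.cholesky(
        np.array([[sb, rho * np.sqrt(sb * sl)], [rho * np.sqrt(sb * sl), sl]])
        + 1e-12 * np.eye(2)
    )
    rows = []
    for node in tree.iter_nodes():
        if node is tree.root:
            continue
        step = chol @ rng.standard_normal(2) * np.sqrt(node.length)
        state = states[id(node.parent)] + step
        states[id(node)] = state
        if node.is_leaf:
            rows.append((node.name, 10.0 ** state[1], 10.0 ** state[0]))
    rows.sort()
    return TraitTable(
        pd.DataFrame(rows, columns=["species", "max_lifespan", "body_size"])
    )


def generate_gene_trees(
    spec: SyntheticSpec, paths: PhenotypePaths
) -> Tuple[GeneTreeSet, GroundTruth]:
    """Gene trees as noisy rate-scaled copies of the master, with planted signal.

    Every gene tree shares the master topology; branch b of gene g has length

        master_length[b] * rate_g * lognormal_noise(cv) * coupling

    where ``rate_g`` is a gene-level lognormal rate and, for the planted
    genes only, ``coupling = exp(direction * effect_size * z_b)`` with z_b
    the standardized phenotype path on branch b. The planted direction is -1
    (rates fall as the phenotype rises — increased constraint), so planted
    genes should surface with negative correlations.
    """
    tree = spec.master
    rng = spec.rng(2)
    branch_nodes = tree.branch_nodes()
    base = np.array([n.length for n in branch_nodes])
    delta = np.asarray(paths.delta, dtype=float)
    if delta.shape[0] != len(branch_nodes):
        raise ValueError("phenotype paths do not match the master tree branches")
    sd = delta.std()
    z = (delta - delta.mean()) / (sd if sd > 0 else 1.0)

    ids = _gene_ids(spec.n_genes)
    n_assoc = int(round(spec.frac_associated * spec.n_genes))
    associated = set(rng.choice(ids, size=n_assoc, replace=False)) if n_assoc else set()
    direction = {g: -1 for g in associated}

    sigma_ln = np.sqrt(np.log1p(spec.gene_noise_cv**2))
    trees: Dict[str, PhyloTree] = {}
    for gid in ids:
        rate_g = float(np.exp(rng.normal(0.0, 0.5)))
        noise = np.exp(rng.normal(0.0, sigma_ln, base.size) - sigma_ln**2 / 2.0)
        lengths = base * rate_g * noise
        if gid in associated:
            lengths = lengths * np.exp(direction[gid] * spec.effect_size * z)
        gtree = tree.copy()
        for node, ln in zip(gtree.branch_nodes(), lengths):
            node.length = float(ln)
        trees[gid] = gtree
    genes = GeneTreeSet(gene_ids=ids, trees=trees, species_universe=tree.tip_set)
    return genes, GroundTruth(associated_genes=associated, direction=direction)


def generate_gene_sets(
    gene_ids: Sequence[str],
    truth: GroundTruth,
    n_sets: int = 50,
    set_size: int = 25,
    frac_enriched_sets: float = 0.1,
    seed: int = 0,
) -> Tuple[GeneSetCollection, Set[str]]:
    """Pathway annotations with a known enriched subset.

    Enriched sets are drawn from the planted (associated) genes — entirely
    from them when enough exist — while null sets are drawn uniformly from
    all genes. Returns the collection and the names of the enriched sets.
    """
    gene_ids = list(gene_ids)
    if set_size > len(gene_ids):
        raise ValueError("set_size exceeds the number of genes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n_enriched = int(round(frac_enriched_sets * n_sets))
    assoc = sorted(truth.associated_genes)
    sets: Dict[str, List[str]] = {}
    enriched: Set[str] = set()
    width = max(3, len(str(n_sets)))
    for i in range(1, n_sets + 1):
        name = f"pathway_{i:0{width}d}"
        if i <= n_enriched and assoc:
            size = min(set_size, len(assoc))
            members = list(rng.choice(assoc, size=size, replace=False))
            enriched.add(name)
        else:
            members = list(rng.choice(gene_ids, size=set_size, replace=False))
        sets[name] = sorted(members)
    return GeneSetCollection(sets=sets), enriched


@dataclass
class SyntheticDataset:
    """A fully generated study: inputs plus ground truth."""

    spec: SyntheticSpec
    master: PhyloTree
    traits: TraitTable
    paths: PhenotypePaths
    genes: GeneTreeSet
    truth: GroundTruth
    collection: GeneSetCollection
    enriched_sets: Set[str]


def generate_dataset(
    spec: Optional[SyntheticSpec] = None,
    phenotype: str = "3l",
    n_sets: int = 50,
    set_size: int = 25,
    frac_enriched_sets: float = 0.1,
) -> SyntheticDataset:
    """Generate a complete synthetic study keyed to one phenotype.

    Traits are generated on the master tree, the chosen composite phenotype
    (3L by default) is built from them, its branch paths drive the planted
    gene-tree signal, and pathway annotations with a known enriched subset
    are drawn over the genes.
    """
    spec = spec or SyntheticSpec()
    traits = generate_traits(spec)
    phenotypes = compute_3l_ell(traits)
    paths = phenotype_paths(spec.master, phenotypes.phenotype(phenotype))
    genes, truth = generate_gene_trees(spec, paths)
    collection, enriched = generate_gene_sets(
        genes.gene_ids,
        truth,
        n_sets=n_sets,
        set_size=set_size,
        frac_enriched_sets=frac_enriched_sets,
        seed=spec.seed,
    )
    return SyntheticDataset(
        spec=spec,
        master=spec.master,
        traits=traits,
        paths=paths,
        genes=genes,
        truth=truth,
        collection=collection,
        enriched_sets=enriched,
    )
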