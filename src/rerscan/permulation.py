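"""Phylogenetically restricted permutations ("permulations") and pi1.

A plain permutation of a phenotype across species destroys its phylogenetic
structure, so permutation nulls are anti-conservative whenever related
species share both trait values and evolutionary rates. Permulations fix
this: a Brownian-motion phenotype is simulated on the master tree, and the
*observed* phenotype values are reassigned to species by the rank of the
simulated values. Each null phenotype is therefore an exact permutation of
the observed values (same multiset) that nevertheless respects the
phylogeny. Rerunning the association and enrichment stages on many such
null phenotypes yields empirical null distributions for every gene and
pathway statistic.

The fraction of truly associated genes is summarized by pi1 = 1 - pi0,
where pi0 is estimated from the p-value mass above a threshold lambda,
against either the theoretical uniform null or the permulation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .association import AssociationConfig, _matrix_correlations, associate_all
from .enrichment import EnrichmentConfig, GeneSetCollection, prepare_membership, ranksum_z
from .phenotypes import paths_operator
from .rer import RERMatrix, winsorize
from .trees import PhyloTree

__all__ = [
    "PermulationConfig",
    "PermulationNull",
    "Pi1Estimate",
    "simulate_brownian",
    "permulate_phenotype",
    "null_statistics",
    "empirical_p",
    "estimate_pi1",
    "pi1_sweep",
]


@dataclass
class PermulationConfig:
    """Permulation settings.

    n_reps
        Number of permulation replicates (1000 by default, the scale used
        for the published empirical p-values).
    seed
        Base seed; each replicate draws from an independent generator
        derived from (seed, replicate index), so results are independent of
        execution order.
    sigma2
        Brownian rate for the simulations. Rank-matching makes the null
        invariant to it; kept configurable for completeness.
    pseudocount
        If True, empirical p-values are (1 + #more extreme)/(1 + n) instead
        of the plain proportion.
    direction
        How "more extreme" is counted: "signed" (one-sided in the sign of
        the observed statistic; the directional reading used for enrichment
        statistics), "two-sided" (by absolute value), or "greater".
    """

    n_reps: int = 1000
    seed: int = 0
    sigma2: float = 1.0
    pseudocount: bool = False
    direction: str = "signed"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.direction not in ("signed", "two-sided", "greater"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _tip_incidence(tree: PhyloTree):
    """Cached (tip order, branch lengths, tips x branches incidence matrix)."""
    cached = tree._cache.get("tip_incidence")
    if cached is None:
        tip_order = sorted(tree.tips)
        tip_pos = {t: i for i, t in enumerate(tip_order)}
        branch_nodes = tree.branch_nodes()
        lengths = np.array([n.length for n in branch_nodes])
        A = np.zeros((len(tip_order), len(branch_nodes)))
        for b, node in enumerate(branch_nodes):
            for t in tree.tipset(node):
                A[tip_pos[t], b] = 1.0
        tree._cache["tip_incidence"] = cached = (tip_order, lengths, A)
    return cached


def _rng_for(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def _simulate_tips(
    tree: PhyloTree, sigma2: float, rng: np.random.Generator
) -> Tuple[List[str], np.ndarray]:
    tip_order, lengths, A = _tip_incidence(tree)
    increments = np.sqrt(sigma2 * lengths) * rng.standard_normal(lengths.size)
    return tip_order, A @ increments


def simulate_brownian(
    tree: PhyloTree, sigma2: float = 1.0, seed: int = 0
) -> Dict[str, float]:
    """Simulate one Brownian-motion trait on the tree.

    The root state is 0 and each branch adds an independent Normal(0,
    sigma2 * branch length) increment; returns the tip values.
    """
    tip_order, values = _simulate_tips(tree, sigma2, _rng_for(seed, 0))
    return dict(zip(tip_order, values))


def _rank_match(sim: np.ndarray, observed_sorted: np.ndarray) -> np.ndarray:
    """Assign sorted observed values to positions by the rank of ``sim``."""
    out = np.empty_like(observed_sorted)
    order = np.argsort(sim, kind="stable")
    out[order] = observed_sorted
    return out


def permulate_phenotype(
    tree: PhyloTree,
    observed: Mapping[str, float],
    seed: int = 0,
    sigma2: float = 1.0,
) -> Dict[str, float]:
    """One permulated phenotype: simulate Brownian values, then give the
    species with the k-th smallest simulated value the k-th smallest
    observed value. The output is an exact permutation of the observed
    values. Ties in the simulated values (measure-zero for continuous
    simulations) break by species-label order; tied observed values are
    assigned in stable sorted order.
    """
    tip_order, sim = _simulate_tips(tree, sigma2, _rng_for(seed, 0))
    missing = [t for t in tip_order if t not in observed]
    if missing:
        raise ValueError(f"observed phenotype missing species: {missing}")
    obs_sorted = np.sort(np.array([float(observed[t]) for t in tip_order]))
    values = _rank_match(sim, obs_sorted)
    return dict(zip(tip_order, values))


@dataclass
class PermulationNull:
    """Null statistic collections from permulated phenotypes."""

    seed: int
    n_reps: int
    gene_ids: List[str]
    gene_obs_stat: np.ndarray  # (G,)
    gene_null_stat: np.ndarray  # (G, R)
    gene_obs_p: np.ndarray  # (G,) parametric p under the real phenotype
    gene_null_p: np.ndarray  # (G, R) parametric p under permulated phenotypes
    pathway_names: List[str]
    pathway_obs_stat: np.ndarray  # (S,)
    pathway_null_stat: np.ndarray  # (S, R)
    n_failed: int = 0

    def gene_empirical_p(
        self, direction: str = "signed", pseudocount: bool = False
    ) -> pd.Series:
        vals = [
            empirical_p(o, row, direction=direction, pseudocount=pseudocount)
            for o, row in zip(self.gene_obs_stat, self.gene_null_stat)
        ]
        return pd.Series(vals, index=pd.Index(self.gene_ids, name="gene"))

    def pathway_empirical_p(
        self, direction: str = "signed", pseudocount: bool = False
    ) -> pd.Series:
        vals = [
            empirical_p(o, row, direction=direction, pseudocount=pseudocount)
            for o, row in zip(self.pathway_obs_stat, self.pathway_null_stat)
        ]
        return pd.Series(vals, index=pd.Index(self.pathway_names, name="pathway"))


def null_statistics(
    rers: RERMatrix,
    master: PhyloTree,
    observed: Mapping[str, float],
    collection: Optional[GeneSetCollection] = None,
    config: Optional[PermulationConfig] = None,
    assoc_config: Optional[AssociationConfig] = None,
    enrich_config: Optional[EnrichmentConfig] = None,
) -> PermulationNull:
    """Recompute gene and pathway statistics under permulated phenotypes.

    For each replicate: permulate the phenotype on the master tree, rebuild
    the phenotype paths, correlate every gene's (winsorized) RERs with them,
    and recompute pathway rank-sum statistics on the annotated background.
    Replicates are driven by generators derived from (seed, replicate), so
    the result is independent of execution order. Replicates producing any
    undefined gene statistic are excluded from pathway nulls and counted in
    ``n_failed``.
    """
    config = config or PermulationConfig()
    assoc_config = assoc_config or AssociationConfig()
    enrich_config = enrich_config or EnrichmentConfig()

    tip_order, P = paths_operator(master)
    missing = [t for t in tip_order if t not in observed]
    if missing:
        raise ValueError(f"observed phenotype missing species: {missing}")
    t_obs = np.array([float(observed[t]) for t in tip_order])

    # align RER columns with the master's canonical branch order
    labels = master.branch_labels()
    data = rers.data.reindex(columns=labels)
    y_obs = pd.Series(P @ t_obs, index=labels)

    obs_assoc = associate_all(RERMatrix(data=data), y_obs, assoc_config)
    genes = list(obs_assoc.index)
    if not genes:
        raise ValueError("no genes eligible for association")

    X = data.loc[genes].to_numpy()
    mask = np.isfinite(X)
    Xw = np.zeros_like(X)
    for i in range(X.shape[0]):
        row = np.where(mask[i], X[i], np.nan)
        row = winsorize(row, assoc_config.winsorize_k)
        Xw[i] = np.where(mask[i], row, 0.0)

    if collection is not None and len(collection):
        background, member_idx = prepare_membership(collection, genes, enrich_config)
        pathway_names = sorted(member_idx)
        idx_list = [member_idx[n] for n in pathway_names]
        bg_rows = np.array([genes.index(g) for g in background])
        obs_z, _ = ranksum_z(
            obs_assoc.loc[background, "stat"].to_numpy(), idx_list
        )
    else:
        pathway_names, idx_list, bg_rows = [], [], np.array([], dtype=int)
        obs_z = np.array([])

    R = config.n_reps
    G, S = len(genes), len(pathway_names)
    gene_null_stat = np.full((G, R), np.nan)
    gene_null_p = np.full((G, R), np.nan)
    pathway_null = np.full((S, R), np.nan)
    obs_sorted = np.sort(t_obs)
    n_failed = 0
    log_div = assoc_config._log_div

    for rep in range(R):
        rng = _rng_for(config.seed, rep)
        _, lengths, A = _tip_incidence(master)
        sim = A @ (np.sqrt(config.sigma2 * lengths) * rng.standard_normal(lengths.size))
        perm = _rank_match(sim, obs_sorted)
        # hard invariant: each permulated phenotype is a permutation of the
        # observed values
        assert np.array_equal(np.sort(perm), obs_sorted)
        y = P @ perm
        _, p_rep, _, stat_rep = _matrix_correlations(Xw, mask, y, log_div)
        gene_null_stat[:, rep] = stat_rep
        gene_null_p[:, rep] = p_rep
        if S:
            bg_stats = stat_rep[bg_rows]
            if np.all(np.isfinite(bg_stats)):
                z, _ = ranksum_z(bg_stats, idx_list)
                pathway_null[:, rep] = z
            else:
                n_failed += 1

    return PermulationNull(
        seed=config.seed,
        n_reps=R,
        gene_ids=genes,
        gene_obs_stat=obs_assoc["stat"].to_numpy(),
        gene_null_stat=gene_null_stat,
        gene_obs_p=obs_assoc["p"].to_numpy(),
        gene_null_p=gene_null_p,
        pathway_names=pathway_names,
        pathway_obs_stat=obs_z,
        pathway_null_stat=pathway_null,
        n_failed=n_failed,
    )


def empirical_p(
    observed: float,
    nulls: np.ndarray,
    direction: str = "signed",
    pseudocount: bool = False,
) -> float:
    """Empirical p-value of ``observed`` against a null sample.

    direction "signed" counts nulls more extreme than the observed value in
    the direction of its sign (null > observed for positive observations,
    null < observed for negative); "two-sided" counts |null| > |observed|;
    "greater" counts null > observed. The default estimate is the plain
    proportion; with ``pseudocount`` it is (1 + count)/(1 + n).
    """
    nulls = np.asarray(nulls, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size == 0:
        raise ValueError("empty null sample")
    if direction == "signed":
        count = np.sum(nulls > observed) if observed >= 0 else np.sum(nulls < observed)
    elif direction == "two-sided":
        count = np.sum(np.abs(nulls) > abs(observed))
    elif direction == "greater":
        count = np.sum(nulls > observed)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if pseudocount:
        return float((1 + count) / (1 + nulls.size))
    return float(count / nulls.size)


@dataclass
class Pi1Estimate:
    """Estimated fraction of non-null hypotheses."""

    pi1: float
    pi0: float
    null_source: str  # "uniform" | "permulation"
    lam: float


def estimate_pi1(
    p_real: np.ndarray,
    null: Union[str, np.ndarray] = "uniform",
    lam: float = 0.5,
) -> Pi1Estimate:
    """Estimate pi1 = 1 - pi0 from a p-value distribution.

    With the uniform null, pi0 = #(p > lambda) / ((1 - lambda) n). With an
    empirical null sample of p-values (e.g. parametric p-values recomputed
    under permulated phenotypes), pi0 is the ratio of the tail proportions:
    [#(p_real > lambda)/n_real] / [#(p_null > lambda)/n_null]. pi0 is
    clipped to [0, 1].
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    p = np.asarray(p_real, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    tail_real = np.mean(p > lam)
    if isinstance(null, str):
        if null != "uniform":
            raise ValueError("null must be 'uniform' or an array of null p-values")
        pi0 = tail_real / (1.0 - lam)
        source = "uniform"
    else:
        pn = np.asarray(null, dtype=float).ravel()
        pn = pn[np.isfinite(pn)]
        if pn.size == 0:
            raise ValueError("empty null p-value sample")
        tail_null = np.mean(pn > lam)
        pi0 = 1.0 if tail_null == 0 and tail_real == 0 else (
            np.inf if tail_null == 0 else tail_real / tail_null
        )
        source = "permulation"
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Estimate(pi1=1.0 - pi0, pi0=pi0, null_source=source, lam=lam)


def pi1_sweep(
    p_real: np.ndarray,
    null: Union[str, np.ndarray] = "uniform",
    lambdas: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Sensitivity of the pi1 estimate to the lambda threshold."""
    if lambdas is None:
        lambdas = np.round(np.arange(0.05, 0.96, 0.05), 2)
    rows = [estimate_pi1(p_real, null, lam=float(l)) for l in lambdas]
    return pd.DataFrame(
        {"lambda": [r.lam for r in rows], "pi0": [r.pi0 for r in rows],
         "pi1": [r.pi1 for r in rows]}
    )
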