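"""Model/results objects orchestrating the full rate-trait scan.

:class:`RERScan` is built from the study inputs (gene trees, species trait
table, optional pathway annotations) and precomputes the deterministic
stages: master tree, composite phenotypes, branch-wise phenotype paths and
the RER matrix. :meth:`RERScan.fit` then runs the inferential stages —
gene-phenotype correlations, pathway enrichment, and (optionally)
permulation nulls with empirical p-values and pi1 — and returns a
:class:`RERScanResults` carrying the estimate tables, diagnostics and a
``summary()``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .association import AssociationConfig, associate_all, bh_adjust
from .enrichment import EnrichmentConfig, GeneSetCollection, enrich, read_gmt
from .permulation import (
    PermulationConfig,
    PermulationNull,
    estimate_pi1,
    null_statistics,
    pi1_sweep,
)
from .phenotypes import (
    PhenotypePaths,
    TraitTable,
    compute_3l_ell,
    phenotype_paths,
)
from .rer import RERConfig, RERMatrix, compute_rers
from .trees import GeneTreeSet, PhyloTree, master_tree, prune, read_gene_trees

__all__ = ["RERScan", "RERScanResults", "RunConfig", "run_full", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed so adding a stage never perturbs others."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class RERScan:
    """A relative-evolutionary-rate scan for one continuous phenotype.

    Parameters
    ----------
    gene_trees
        Per-gene trees, all congruent with a shared species topology.
    traits
        Species trait table (maximum lifespan, body size). Species without
        trait rows are dropped from the analysis. Alternatively pass
        ``phenotype_values`` directly.
    gene_sets
        Optional pathway annotations for enrichment.
    phenotype
        "3l" (PC1 of log size/lifespan), "ell" (PC2), or "custom" with
        ``phenotype_values``.
    master
        Species tree with average branch lengths; estimated from the gene
        trees when not given.
    """

    def __init__(
        self,
        gene_trees: GeneTreeSet,
        traits: Optional[TraitTable] = None,
        gene_sets: Optional[GeneSetCollection] = None,
        phenotype: str = "3l",
        phenotype_values: Optional[Mapping[str, float]] = None,
        master: Optional[PhyloTree] = None,
        rer_config: Optional[RERConfig] = None,
        assoc_config: Optional[AssociationConfig] = None,
        enrich_config: Optional[EnrichmentConfig] = None,
    ):
        self.rer_config = rer_config or RERConfig()
        self.assoc_config = assoc_config or AssociationConfig()
        self.enrich_config = enrich_config or EnrichmentConfig()
        self.gene_sets = gene_sets
        self.phenotype = phenotype

        self.master_was_provided = master is not None
        if master is None:
            master = master_tree(gene_trees)

        if phenotype_values is not None:
            species = frozenset(phenotype_values) & master.tip_set
            self.phenotype_table = None
            tipvals = {s: float(phenotype_values[s]) for s in species}
        else:
            if traits is None:
                raise ValueError("need either a trait table or phenotype_values")
            species = frozenset(traits.species) & master.tip_set
            restricted = traits.restrict(species)
            self.phenotype_table = compute_3l_ell(restricted)
            tipvals = self.phenotype_table.phenotype(phenotype)

        if species != master.tip_set:
            master = prune(master, species)
            gene_trees = gene_trees.restrict_species(species)
        self.species = species
        self.master = master
        self.gene_trees = gene_trees
        self.traits = traits
        self.phenotype_values: Dict[str, float] = dict(tipvals)
        self.paths: PhenotypePaths = phenotype_paths(master, tipvals)
        self.rers: RERMatrix = compute_rers(gene_trees, master, self.rer_config)

    @classmethod
    def from_files(
        cls,
        gene_trees: Union[str, Path],
        traits: Union[str, Path],
        gmt: Optional[Union[str, Path]] = None,
        **kwargs,
    ) -> "RERScan":
        return cls(
            gene_trees=read_gene_trees(gene_trees),
            traits=TraitTable.read_csv(traits),
            gene_sets=read_gmt(gmt) if gmt else None,
            **kwargs,
        )

    def fit(
        self,
        n_permulations: int = 0,
        seed: int = 0,
        pseudocount: bool = False,
        direction: str = "signed",
    ) -> "RERScanResults":
        """Run association, enrichment, and optional permulation stages."""
        t0 = time.time()
        associations = associate_all(self.rers, self.paths, self.assoc_config)
        enrichments = None
        if self.gene_sets is not None and len(self.gene_sets):
            enrichments = enrich(associations, self.gene_sets, self.enrich_config)

        pi1_uniform = (
            estimate_pi1(associations["p"].to_numpy()) if len(associations) else None
        )
        null = None
        pi1_perm = None
        if n_permulations > 0:
            config = PermulationConfig(
                n_reps=n_permulations,
                seed=stage_seed(seed, "permulation"),
                pseudocount=pseudocount,
                direction=direction,
            )
            null = null_statistics(
                self.rers,
                self.master,
                self.phenotype_values,
                self.gene_sets,
                config,
                self.assoc_config,
                self.enrich_config,
            )
            pi1_perm = estimate_pi1(
                null.gene_obs_p, null.gene_null_p[np.isfinite(null.gene_null_p)]
            )
            if enrichments is not None and len(enrichments):
                p_perm = null.pathway_empirical_p(
                    direction=direction, pseudocount=pseudocount
                )
                enrichments = enrichments.copy()
                enrichments["p_perm"] = p_perm.reindex(enrichments.index)
                ok = enrichments["p_perm"].notna()
                enrichments.loc[ok, "p_adj"] = bh_adjust(
                    enrichments.loc[ok, "p_perm"].to_numpy()
                )
        return RERScanResults(
            model=self,
            associations=associations,
            enrichments=enrichments,
            pi1_uniform=pi1_uniform,
            pi1_permulation=pi1_perm,
            permulation_null=null,
            n_permulations=n_permulations,
            seed=seed,
            fit_seconds=time.time() - t0,
        )


@dataclass
class RERScanResults:
    """Fitted scan results: per-gene and per-pathway tables plus diagnostics."""

    model: RERScan
    associations: pd.DataFrame
    enrichments: Optional[pd.DataFrame]
    pi1_uniform: Optional[object]
    pi1_permulation: Optional[object]
    permulation_null: Optional[PermulationNull]
    n_permulations: int
    seed: int
    fit_seconds: float = 0.0

    def gene_rank(self, gene: str) -> int:
        """1-based rank of a gene by increasing signed -log p statistic
        (most constrained first)."""
        order = self.associations["stat"].sort_values()
        return int(np.flatnonzero(order.index == gene)[0]) + 1

    def pi1_lambda_sweep(self) -> pd.DataFrame:
        null = (
            self.permulation_null.gene_null_p.ravel()
            if self.permulation_null is not None
            else "uniform"
        )
        return pi1_sweep(self.associations["p"].to_numpy(), null)

    def summary(self) -> str:
        model = self.model
        lines = [
            "Relative evolutionary rate scan",
            "=" * 46,
            f"Phenotype:            {model.phenotype}",
            f"Species:              {len(model.species)}",
            f"Genes tested:         {len(self.associations)} / {len(model.gene_trees)}",
            f"Branches:             {len(model.master.branch_ids())}",
            f"Permulations:         {self.n_permulations}",
        ]
        if self.pi1_uniform is not None:
            lines.append(
                f"pi1 (uniform null):   {self.pi1_uniform.pi1:.3f}"
            )
        if self.pi1_permulation is not None:
            lines.append(
                f"pi1 (permulation):    {self.pi1_permulation.pi1:.3f}"
            )
        if len(self.associations):
            lines.append("")
            lines.append("Most constrained genes (lowest signed -log p):")
            top = self.associations.sort_values("stat").head(5)
            for gene, row in top.iterrows():
                lines.append(
                    f"  {gene:<16} rho={row['rho']:+.3f}  p={row['p']:.3g}"
                    f"  n={int(row['n'])}"
                )
        if self.enrichments is not None and len(self.enrichments):
            lines.append("")
            lines.append("Top pathways by |enrichment z|:")
            top = self.enrichments.reindex(
                self.enrichments["stat"].abs().sort_values(ascending=False).index
            ).head(5)
            for pw, row in top.iterrows():
                extra = (
                    f"  p_perm={row['p_perm']:.3g}"
                    if np.isfinite(row.get("p_perm", np.nan))
                    else ""
                )
                lines.append(
                    f"  {pw:<20} z={row['stat']:+.2f}  p={row['p_param']:.3g}"
                    f"  n={int(row['n_genes'])}{extra}"
                )
        return "\n".join(lines)

    def plot_pvalues(self, ax=None):
        """Histogram of gene correlation p-values (excess near 0 = signal)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.associations["p"], bins=20, range=(0, 1), edgecolor="k")
        ax.axhline(len(self.associations) / 20, ls="--", color="gray")
        ax.set_xlabel("correlation p-value")
        ax.set_ylabel("genes")
        ax.set_title(f"{self.model.phenotype} phenotype")
        return ax

    def to_directory(self, outdir: Union[str, Path], config_hash: str = "") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash={config_hash}\n" if config_hash else ""

        def write(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            with path.open("w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", na_rep="NA")

        write(self.associations, "associations.tsv")
        if self.enrichments is not None:
            write(self.enrichments, "enrichment.tsv")
        with (outdir / "pi1.txt").open("w") as fh:
            fh.write(header)
            if self.pi1_uniform is not None:
                fh.write(f"pi1_uniform\t{self.pi1_uniform.pi1:.6f}\n")
            if self.pi1_permulation is not None:
                fh.write(f"pi1_permulation\t{self.pi1_permulation.pi1:.6f}\n")


@dataclass
class RunConfig:
    """File-based configuration of a full scan."""

    gene_trees: str
    traits: str
    gmt: Optional[str] = None
    phenotype: str = "3l"
    output_dir: str = "rerscan_out"
    seed: int = 0
    n_permulations: int = 0
    rer: RERConfig = field(default_factory=RERConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (
            ("rer", RERConfig),
            ("association", AssociationConfig),
            ("enrichment", EnrichmentConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "gene_trees": self.gene_trees,
            "traits": self.traits,
            "gmt": self.gmt,
            "phenotype": self.phenotype,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "n_permulations": self.n_permulations,
            "rer": vars(self.rer).copy(),
            "association": vars(self.association).copy(),
            "enrichment": vars(self.enrichment).copy(),
        }
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_full(config: RunConfig) -> RERScanResults:
    """Execute the end-to-end scan described by ``config``.

    Stages run in order (trees, phenotypes, RERs, association, enrichment,
    permulations); outputs and a locked copy of the configuration are
    written to ``config.output_dir``, all stamped with the config hash.
    Identical configs reproduce identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{stage}] {message}")

    t0 = time.time()
    model = RERScan.from_files(
        config.gene_trees,
        config.traits,
        gmt=config.gmt,
        phenotype=config.phenotype,
        rer_config=config.rer,
        assoc_config=config.association,
        enrich_config=config.enrichment,
    )
    log("trees", f"{len(model.gene_trees)} gene trees, {len(model.species)} species")
    log(
        "rer",
        f"{len(model.rers.genes)} genes x {len(model.rers.branches)} branches; "
        f"{int(model.rers.data.isna().to_numpy().sum())} missing cells",
    )
    results = model.fit(n_permulations=config.n_permulations, seed=config.seed)
    log(
        "association",
        f"{len(results.associations)} genes tested, "
        f"{len(model.gene_trees) - len(results.associations)} excluded",
    )
    if results.enrichments is not None:
        log("enrichment", f"{len(results.enrichments)} pathways tested")
    if results.permulation_null is not None:
        log(
            "permulation",
            f"{results.n_permulations} replicates, "
            f"{results.permulation_null.n_failed} failed",
        )
    log("run", f"wall time {time.time() - t0:.1f}s")

    chash = config.hash()
    results.to_directory(outdir, config_hash=chash)
    (outdir / "config.lock.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
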