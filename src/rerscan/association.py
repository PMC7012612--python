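"""Gene-phenotype association: correlating RERs with phenotype paths.

Each gene's relative evolutionary rates across branches are Pearson-
correlated with the branch-wise phenotype change. RERs are winsorized first
(the k-1 most extreme values per tail capped at the k-th) to limit the
influence of outlier branches. The per-gene summary statistic used for
ranking and enrichment is sign(rho) * (-log p): large negative values mark
genes increasingly constrained where the phenotype grows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phenotypes import PhenotypePaths
from .rer import RERMatrix, winsorize

__all__ = [
    "AssociationConfig",
    "GeneAssociation",
    "correlate_gene",
    "associate_all",
    "bh_adjust",
    "compare_gene_sets",
]

#: p-values are floored here so the signed -log p statistic stays finite.
P_FLOOR = 1e-300


@dataclass
class AssociationConfig:
    """Settings for RER-phenotype correlation.

    min_branches
        Minimum number of pairwise-complete branches for a gene to be
        tested; genes below it are dropped (default 10).
    winsorize_k
        Per-tail winsorization order applied to the RERs before correlating
        (default 3: the two most extreme values per tail are capped at the
        third most extreme).
    log_base
        Base of the -log p statistic; natural log by default. Rankings are
        invariant to this choice.
    min_pos
        Accepted for config compatibility with binary-trait tooling; it has
        no effect for continuous phenotypes.
    """

    min_branches: int = 10
    winsorize_k: int = 3
    log_base: Union[str, float] = "e"
    min_pos: int = 0

    def __post_init__(self) -> None:
        if self.min_branches < 3:
            raise ValueError("min_branches must be >= 3")

    @property
    def _log_div(self) -> float:
        return 1.0 if self.log_base == "e" else math.log(float(self.log_base))


class GeneAssociation(NamedTuple):
    """Per-gene correlation record."""

    gene: str
    rho: float
    p: float
    n: int
    stat: float


def _signed_log_stat(rho: np.ndarray, p: np.ndarray, log_div: float) -> np.ndarray:
    return np.sign(rho) * (-np.log(np.maximum(p, P_FLOOR)) / log_div)


def correlate_gene(
    gene: str,
    rers: Union[pd.Series, np.ndarray],
    paths: Union[PhenotypePaths, pd.Series, np.ndarray],
    config: Optional[AssociationConfig] = None,
) -> Optional[GeneAssociation]:
    """Correlate one gene's RER vector with the phenotype paths.

    Uses pairwise-complete entries; RERs are winsorized on that subset. The
    two-sided p-value comes from the t distribution with n-2 degrees of
    freedom. Returns None (with a warning) when fewer than ``min_branches``
    branches are available or either vector is constant.
    """
    if config is None:
        config = AssociationConfig()
    x = np.asarray(rers.to_numpy() if isinstance(rers, pd.Series) else rers, float)
    if isinstance(paths, PhenotypePaths):
        y = paths.delta
    elif isinstance(paths, pd.Series):
        y = paths.to_numpy(dtype=float)
    else:
        y = np.asarray(paths, dtype=float)
    if x.shape != y.shape:
        raise ValueError("RER and path vectors must share a branch index")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < config.min_branches:
        warnings.warn(
            f"gene {gene!r}: {n} branches < min_branches={config.min_branches}; "
            "not tested",
            stacklevel=2,
        )
        return None
    xv = winsorize(x[mask], config.winsorize_k)
    yv = y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn(f"gene {gene!r}: zero variance; not tested", stacklevel=2)
        return None
    rho, p = stats.pearsonr(xv, yv)
    p = max(float(p), P_FLOOR)
    stat = float(np.sign(rho) * (-math.log(p) / config._log_div))
    return GeneAssociation(gene=gene, rho=float(rho), p=p, n=n, stat=stat)


def _matrix_correlations(
    X: np.ndarray, mask: np.ndarray, y: np.ndarray, log_div: float
):
    """Row-wise Pearson correlation of a masked matrix against one vector.

    ``X`` must already be winsorized per row with masked cells zeroed.
    Returns (rho, p, n, stat) arrays; rows with zero variance get NaN rho.
    """
    n = mask.sum(axis=1).astype(float)
    sy = mask @ y
    syy = mask @ (y * y)
    sx = X.sum(axis=1)
    sxx = (X * X).sum(axis=1)
    sxy = X @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        rho = cov / np.sqrt(varx * vary)
        rho = np.clip(rho, -1.0, 1.0)
        df = n - 2
        t2 = rho * np.sqrt(df / np.maximum(1e-300, 1.0 - rho * rho))
        p = 2.0 * stats.t.sf(np.abs(t2), df)
    p = np.maximum(p, P_FLOOR)
    bad = ~np.isfinite(rho) | (varx <= 0) | (vary <= 0)
    rho[bad] = np.nan
    p[bad] = np.nan
    stat = _signed_log_stat(rho, p, log_div)
    stat[bad] = np.nan
    return rho, p, n.astype(int), stat


def associate_all(
    rers: RERMatrix,
    paths: Union[PhenotypePaths, pd.Series],
    config: Optional[AssociationConfig] = None,
) -> pd.DataFrame:
    """Correlate every gene's RERs with the phenotype paths.

    Returns a DataFrame indexed by gene id (sorted) with columns ``rho, p,
    p_adj, n, stat``; genes failing ``min_branches`` or with degenerate
    variance are omitted. ``p_adj`` is the Benjamini-Hochberg adjustment of
    the parametric p-values.
    """
    if config is None:
        config = AssociationConfig()
    if isinstance(paths, PhenotypePaths):
        y = pd.Series(paths.delta, index=paths.labels)
    else:
        y = paths
    y = y.reindex(rers.data.columns)
    yv = y.to_numpy(dtype=float)

    X = rers.values
    mask = np.isfinite(X) & np.isfinite(yv)[None, :]
    Xw = np.zeros_like(X)
    for i in range(X.shape[0]):
        row = np.where(mask[i], X[i], np.nan)
        if mask[i].sum() >= config.min_branches:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row = winsorize(row, config.winsorize_k)
        Xw[i] = np.where(mask[i], row, 0.0)

    rho, p, n, stat = _matrix_correlations(Xw, mask, yv, config._log_div)
    keep = (n >= config.min_branches) & np.isfinite(rho)
    df = pd.DataFrame(
        {"rho": rho[keep], "p": p[keep], "n": n[keep], "stat": stat[keep]},
        index=pd.Index(np.asarray(rers.genes)[keep], name="gene"),
    ).sort_index()
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df[["rho", "p", "p_adj", "n", "stat"]]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class GeneSetComparison(NamedTuple):
    statistic: float  # Mann-Whitney U for the set
    pvalue: float
    n_set: int
    n_background: int


def compare_gene_sets(
    assoc: pd.DataFrame,
    set_a: Iterable[str],
    background: Iterable[str],
    alternative: str = "two-sided",
) -> GeneSetComparison:
    """Wilcoxon rank-sum comparison of correlation coefficients.

    Compares the rho values of ``set_a`` against the rest of ``background``
    (tie-corrected normal approximation). Used e.g. to ask whether a curated
    gene class (tumor suppressors, oncogenes) is shifted toward stronger
    constraint than genes at large.
    """
    set_a = {g for g in set_a if g in assoc.index}
    background = {g for g in background if g in assoc.index}
    if not set_a <= background:
        raise ValueError("set_a must be a subset of background")
    rest = background - set_a
    if not set_a or not rest:
        raise ValueError("gene-set comparison needs non-empty set and complement")
    rho_a = assoc.loc[sorted(set_a), "rho"].to_numpy()
    rho_b = assoc.loc[sorted(rest), "rho"].to_numpy()
    res = stats.mannwhitneyu(rho_a, rho_b, alternative=alternative, method="asymptotic")
    return GeneSetComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_set=len(rho_a),
        n_background=len(rho_b),
    )
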