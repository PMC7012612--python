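"""Relative evolutionary rates (RERs).

A gene's branch lengths (amino-acid substitutions per branch) reflect both
the gene's own evolutionary constraint and the genome-wide rate of the
lineage: long branches of the species tree accumulate more substitutions in
every gene. RERs remove the genome-wide component by regressing each gene's
branch lengths on the master-tree branch lengths (the proteome-wide
expectation) and keeping the residuals. A negative residual on a branch
means the gene accumulated fewer substitutions than expected there
(increased constraint); a positive residual means more (relaxed constraint
or positive selection).

The regression is per gene, across branches, with an intercept. Branch
lengths are variance-stabilized with a square-root transform by default, and
residual heteroskedasticity along the fitted value is corrected by one pass
of inverse-variance reweighting estimated from decile-binned squared
residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .trees import GeneTreeSet, PhyloTree, TreeError, branch_label, prune_with_map

__all__ = ["RERConfig", "RERMatrix", "compute_rers", "winsorize"]


@dataclass
class RERConfig:
    """Settings for RER computation.

    scale
        Normalize each gene's valid branch lengths by their sum before the
        regression, removing gene-level average rate differences.
    weight
        Apply one pass of inverse-variance reweighting against residual
        heteroskedasticity; the returned residuals are then scaled by the
        square root of the weights.
    cutoff
        Minimum branch length in substitution units; branches below it (in
        the gene tree or the master tree) are treated as missing. 0.001 by
        default.
    transform
        "sqrt" (default) or "identity", applied to both gene and master
        branch lengths before the regression.
    winsorize_k
        Per-tail winsorization order used downstream when correlating RERs
        with phenotypes: the k-1 most extreme values in each tail are set to
        the k-th most extreme.
    """

    scale: bool = True
    weight: bool = True
    cutoff: float = 0.001
    transform: str = "sqrt"
    winsorize_k: int = 3
    #: if True, gene branches are matched to master branches by tip-set and
    #: master branches with no counterpart in a gene become missing cells,
    #: instead of raising on topology incongruence. Used when scanning
    #: against an alternate master topology.
    allow_incongruent: bool = False

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.winsorize_k < 1:
            raise ValueError("winsorize_k must be >= 1")
        if self.transform not in ("sqrt", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class RERMatrix:
    """Genes x branches matrix of relative evolutionary rates.

    ``data`` is a DataFrame indexed by gene id with one column per master
    branch (labelled by smallest member + clade size); missing cells are NaN.
    ``branch_ids`` aligns columns with master-branch tip-sets when known.
    """

    data: pd.DataFrame
    branch_ids: Optional[List[frozenset]] = None

    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    @property
    def branches(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_valid(self) -> pd.Series:
        """Number of non-missing branches per gene."""
        return self.data.notna().sum(axis=1)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RERMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene", na_values="NA")
        return cls(data=df)


def _transform(x: np.ndarray, name: str) -> np.ndarray:
    if name == "sqrt":
        return np.sqrt(x)
    return x


def _ols(x: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None):
    """Weighted least squares of y on [1, x].

    Returns (residuals, fitted, leverage); the leverage is the diagonal of
    the (weighted) hat matrix, used to undo the shrinkage the fit imposes
    on residuals at high-leverage branches.
    """
    X = np.column_stack([np.ones_like(x), x])
    sw = np.ones_like(x) if w is None else np.sqrt(w)
    A = X * sw[:, None]
    beta, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    gram_inv = np.linalg.pinv(A.T @ A)
    leverage = np.einsum("ij,jk,ik->i", A, gram_inv, A)
    fitted = X @ beta
    return y - fitted, fitted, np.clip(leverage, 0.0, 1.0 - 1e-9)


class _VarianceCurve:
    """Mean-variance relationship of residuals against fitted values.

    Squared residuals are averaged within equal-count bins of the fitted
    value and interpolated piecewise-linearly (log-variance scale, with
    linear extrapolation beyond the end bin centers, since residual spread
    keeps growing along the longest branches). Estimated by pooling the
    (fitted, residual) pairs of *all* genes — per-gene curves are far too
    noisy in the long-branch tail, where miscalibration matters most — and
    floored at the 5th percentile of bin variances so a nearly-perfect bin
    cannot produce exploding weights.
    """

    def __init__(self, fitted: np.ndarray, resid: np.ndarray, n_bins: int = 10):
        n = fitted.size
        n_bins = int(np.clip(min(n_bins, n // 3), 2, 200))
        self._flat = False
        self.floor = 1.0
        edges = np.unique(np.quantile(fitted, np.linspace(0, 1, n_bins + 1)))
        if edges.size < 3:
            self._flat = True
            return
        which = np.clip(
            np.searchsorted(edges, fitted, side="right") - 1, 0, edges.size - 2
        )
        centers, variances = [], []
        for b in range(edges.size - 1):
            mask = which == b
            if mask.any():
                centers.append(fitted[mask].mean())
                # median-based variance: robust to the minority of branches
                # carrying genuine rate shifts (0.4549 = median of chi^2_1)
                variances.append(np.median(resid[mask] ** 2) / 0.45494)
        self.centers = np.asarray(centers)
        variances = np.asarray(variances)
        if np.all(variances <= 0) or self.centers.size < 2:
            self._flat = True
            return
        self.floor = max(np.percentile(variances, 5), 1e-12 * variances.mean())
        self.logvar = np.log(np.maximum(variances, 1e-12 * variances.mean()))

    def variance(self, fitted: np.ndarray) -> np.ndarray:
        """Interpolated residual variance at the given fitted values."""
        if self._flat:
            return np.ones(fitted.size)
        c, lv = self.centers, self.logvar
        logv = np.interp(fitted, c, lv)
        lo = fitted < c[0]
        hi = fitted > c[-1]
        logv[lo] = lv[0] + (lv[1] - lv[0]) / (c[1] - c[0]) * (fitted[lo] - c[0])
        logv[hi] = lv[-1] + (lv[-1] - lv[-2]) / (c[-1] - c[-2]) * (
            fitted[hi] - c[-1]
        )
        return np.exp(logv)

    def weights(self, fitted: np.ndarray) -> np.ndarray:
        """Inverse-variance weights (floored) at the given fitted values."""
        if self._flat:
            return np.ones(fitted.size)
        return 1.0 / np.maximum(self.variance(fitted), self.floor)


def compute_rers(
    genes: GeneTreeSet, master: PhyloTree, config: Optional[RERConfig] = None
) -> RERMatrix:
    """Compute the genes x branches RER matrix against a master tree.

    Per gene: branches below ``cutoff`` (gene or master length) are dropped;
    remaining gene lengths are optionally sum-normalized, transformed, and
    regressed on the matched (pruned) master lengths; residuals — reweighted
    once against heteroskedasticity when ``weight`` is on — are the RERs.
    Genes with fewer than 3 valid branches yield an all-missing row.
    """
    if config is None:
        config = RERConfig()
    if not genes.species_universe <= master.tip_set:
        raise TreeError("master tree does not cover the gene-tree species")

    master_ids = master.branch_ids()
    col_index = {ts: i for i, ts in enumerate(master_ids)}
    labels = [branch_label(ts) for ts in master_ids]
    out = np.full((len(genes.gene_ids), len(master_ids)), np.nan)

    prune_cache: Dict[frozenset, tuple] = {}
    fits = {}  # gene row -> (x, y, columns, residuals, fitted)
    for gi, gid in enumerate(genes.gene_ids):
        gtree = genes.trees[gid]
        tipset = gtree.tip_set
        if tipset == master.tip_set:
            pruned, mapping = master, {ts: ts for ts in master_ids}
        else:
            cached = prune_cache.get(tipset)
            if cached is None:
                cached = prune_with_map(master, tipset)
                prune_cache[tipset] = cached
            pruned, mapping = cached

        gene_lengths = gtree.branch_lengths()
        pruned_ids = pruned.branch_ids()
        if set(gene_lengths) != set(pruned_ids) and not config.allow_incongruent:
            raise TreeError(
                f"gene {gid!r} topology is incongruent with the master topology"
            )
        master_lengths = pruned.branch_lengths()
        g = np.array([gene_lengths.get(ts, np.nan) for ts in pruned_ids])
        m = np.array([master_lengths[ts] for ts in pruned_ids])
        cols = np.array([col_index[mapping[ts]] for ts in pruned_ids])

        valid = np.isfinite(g) & (g >= config.cutoff) & (m >= config.cutoff)
        if valid.sum() < 3:
            warnings.warn(
                f"gene {gid!r}: only {int(valid.sum())} branches pass the "
                f"length cutoff; RERs not computed",
                stacklevel=2,
            )
            continue
        gv, mv = g[valid], m[valid]
        if config.scale:
            gv = gv / gv.sum()
        y = _transform(gv, config.transform)
        x = _transform(mv, config.transform)
        resid, fitted, leverage = _ols(x, y)
        fits[gi] = (x, y, cols[valid], resid, fitted, leverage)

    # perfect fits leave only float noise; standardizing that noise would
    # amplify it, so fall back to the raw (zero-ish) residuals
    degenerate = fits and (
        np.mean(np.concatenate([f[3] for f in fits.values()]) ** 2)
        < 1e-20 * np.mean(np.concatenate([f[1] for f in fits.values()]) ** 2)
    )
    if config.weight and fits and not degenerate:
        # pooled mean-variance curve from leverage-corrected first-pass
        # residuals (observed residual variance is sigma^2 * (1 - h))
        all_fitted = np.concatenate([f[4] for f in fits.values()])
        all_resid = np.concatenate(
            [f[3] / np.sqrt(1.0 - f[5]) for f in fits.values()]
        )
        n_bins = int(np.clip(all_fitted.size // 500, 10, 50))
        curve = _VarianceCurve(all_fitted, all_resid, n_bins=n_bins)
        for gi, (x, y, cols_v, resid, fitted, _) in fits.items():
            w = curve.weights(fitted)
            resid_w, _, lev_w = _ols(x, y, w)
            # standardize by the unfloored variance so floored (shortest)
            # branches still come out on the common unit scale
            var = np.maximum(curve.variance(fitted), 1e-12 * curve.floor)
            out[gi, cols_v] = resid_w / np.sqrt(var * (1.0 - lev_w))
    else:
        for gi, (x, y, cols_v, resid, fitted, _) in fits.items():
            out[gi, cols_v] = resid

    df = pd.DataFrame(out, index=list(genes.gene_ids), columns=labels)
    return RERMatrix(data=df, branch_ids=master_ids)


def winsorize(values: np.ndarray, k: int) -> np.ndarray:
    """Cap the k-1 most extreme values per tail at the k-th most extreme.

    Missing (NaN) entries are untouched. If fewer than ``2k - 1`` values are
    present the tails would overlap and the vector is returned unchanged with
    a warning. ``k = 1`` is the identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = np.asarray(values, dtype=float)
    out = values.copy()
    finite = np.isfinite(values)
    n = int(finite.sum())
    if k == 1 or n == 0:
        return out
    if n < 2 * k - 1:
        warnings.warn(
            f"winsorize: {n} non-missing values < 2k-1 = {2 * k - 1}; unchanged",
            stacklevel=2,
        )
        return out
    sorted_vals = np.sort(values[finite])
    low, high = sorted_vals[k - 1], sorted_vals[-k]
    out[finite & (values < low)] = low
    out[finite & (values > high)] = high
    return out
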