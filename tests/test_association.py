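"""Gene-phenotype correlation, BH adjustment, gene-set comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rerscan as rs
from rerscan.rer import RERMatrix


def pearson_t_oracle(x, y):
    """Direct covariance / t-statistic evaluation."""
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    rho = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, p


class TestCorrelateGene:
    def test_self_correlation_hits_p_floor(self):
        v = np.linspace(-2, 2, 10)
        rec = rs.correlate_gene(
            "g", v, v, rs.AssociationConfig(min_branches=5, winsorize_k=1)
        )
        assert rec.rho == pytest.approx(1.0)
        assert rec.p == 1e-300
        assert rec.stat > 0

    def test_matches_direct_formula_oracle_on_short_vectors(self):
        rng = np.random.default_rng(0)
        config = rs.AssociationConfig(min_branches=5, winsorize_k=1)
        for _ in range(20):
            x, y = rng.normal(size=5), rng.normal(size=5)
            rec = rs.correlate_gene("g", x, y, config)
            rho, p = pearson_t_oracle(x, y)
            assert rec.rho == pytest.approx(rho, abs=1e-12)
            assert rec.p == pytest.approx(p, abs=1e-12)
            assert rec.stat == pytest.approx(
                np.sign(rho) * -np.log(p), abs=1e-9
            )

    def test_too_few_branches_returns_none(self):
        with pytest.warns(UserWarning, match="min_branches"):
            rec = rs.correlate_gene(
                "g", np.arange(5.0), np.arange(5.0), rs.AssociationConfig()
            )
        assert rec is None

    def test_zero_variance_returns_none(self):
        config = rs.AssociationConfig(min_branches=5, winsorize_k=1)
        with pytest.warns(UserWarning, match="variance"):
            rec = rs.correlate_gene(
                "g", np.ones(10), np.arange(10.0), config
            )
        assert rec is None

    def test_pairwise_complete_entries_used(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        x[3] = np.nan
        y[7] = np.nan
        config = rs.AssociationConfig(min_branches=5, winsorize_k=1)
        rec = rs.correlate_gene("g", x, y, config)
        ok = np.isfinite(x) & np.isfinite(y)
        rho, p = pearson_t_oracle(x[ok], y[ok])
        assert rec.n == ok.sum()
        assert rec.rho == pytest.approx(rho, abs=1e-12)


class TestAssociateAll:
    def make_matrix(self, X, labels=None):
        labels = labels or [f"b{j}" for j in range(X.shape[1])]
        genes = [f"g{i:03d}" for i in range(X.shape[0])]
        return RERMatrix(data=pd.DataFrame(X, index=genes, columns=labels))

    def test_empty_when_no_gene_passes_min_branches(self):
        X = np.full((5, 4), np.nan)
        rers = self.make_matrix(X)
        y = pd.Series(np.arange(4.0), index=rers.data.columns)
        out = rs.associate_all(rers, y)
        assert len(out) == 0

    def test_planted_gene_attains_largest_stat(self, small_planted_fit,
                                               small_planted_dataset):
        assoc = small_planted_fit.associations
        top_gene = assoc["stat"].abs().idxmax()
        assert top_gene in small_planted_dataset.truth.associated_genes

    def test_consistent_branch_permutation_is_invariant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 30))
        rers = self.make_matrix(X)
        y = pd.Series(rng.normal(size=30), index=rers.data.columns)
        base = rs.associate_all(rers, y)
        perm = rng.permutation(30)
        rers2 = RERMatrix(data=rers.data.iloc[:, perm])
        again = rs.associate_all(rers2, y.iloc[perm])
        pd.testing.assert_frame_equal(base, again)

    def test_negating_paths_flips_rho_and_stat_only(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 25))
        rers = self.make_matrix(X)
        y = pd.Series(rng.normal(size=25), index=rers.data.columns)
        a = rs.associate_all(rers, y)
        b = rs.associate_all(rers, -y)
        np.testing.assert_allclose(a["rho"], -b["rho"], atol=1e-12)
        np.testing.assert_allclose(a["stat"], -b["stat"], atol=1e-9)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_matrix_route_agrees_with_scalar_route(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 40))
        X[rng.random(X.shape) < 0.1] = np.nan
        rers = self.make_matrix(X)
        y = pd.Series(rng.normal(size=40), index=rers.data.columns)
        table = rs.associate_all(rers, y)
        for gene in table.index:
            rec = rs.correlate_gene(
                gene, rers.data.loc[gene], y, rs.AssociationConfig()
            )
            assert table.loc[gene, "rho"] == pytest.approx(rec.rho, abs=1e-10)
            assert table.loc[gene, "p"] == pytest.approx(rec.p, rel=1e-8)

    def test_type_one_error_calibration_with_independent_inputs(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 60))
        rers = self.make_matrix(X)
        y = pd.Series(rng.normal(size=60), index=rers.data.columns)
        out = rs.associate_all(rers, y)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_stat_ranking_invariant_to_log_base(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 40))
        rers = self.make_matrix(X)
        y = pd.Series(rng.normal(size=40), index=rers.data.columns)
        nat = rs.associate_all(rers, y, rs.AssociationConfig(log_base="e"))
        ten = rs.associate_all(rers, y, rs.AssociationConfig(log_base=10))
        assert list(nat["stat"].rank()) == list(ten["stat"].rank())


class TestBHAdjust:
    def test_documented_example(self):
        np.testing.assert_allclose(
            rs.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert rs.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = rng.random(rng.integers(2, 50))
            got = rs.bh_adjust(p)
            # brute-force step-up definition
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            np.testing.assert_allclose(got, adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rs.bh_adjust(np.array([0.5, 1.5]))


class TestCompareGeneSets:
    def make_assoc(self, rho):
        genes = [f"g{i:03d}" for i in range(len(rho))]
        return pd.DataFrame({"rho": rho}, index=pd.Index(genes, name="gene"))

    def test_shifted_set_detected_and_matches_exact_enumeration(self):
        rng = np.random.default_rng(8)
        # moderate downward shift: significant but not in the far tail,
        # where the normal approximation is not expected to track the exact
        # enumeration closely
        rho = np.concatenate(
            [rng.uniform(-0.6, 0.2, 10), rng.uniform(-0.3, 0.6, 30)]
        )
        assoc = self.make_assoc(rho)
        genes = list(assoc.index)
        res = rs.compare_gene_sets(assoc, genes[:10], genes)
        assert res.pvalue < 0.05
        exact = stats.mannwhitneyu(
            rho[:10], rho[10:], alternative="two-sided", method="exact"
        )
        assert res.statistic == exact.statistic
        # the tie-corrected normal approximation tracks the exact p in the
        # bulk of the distribution (the relative error grows in the far tail)
        rng2 = np.random.default_rng(80)
        for _ in range(20):
            vals = rng2.normal(size=30)
            a2 = self.make_assoc(vals)
            g2 = list(a2.index)
            approx = rs.compare_gene_sets(a2, g2[:10], g2)
            ex = stats.mannwhitneyu(
                vals[:10], vals[10:], alternative="two-sided", method="exact"
            )
            if ex.pvalue >= 0.05:
                assert approx.pvalue == pytest.approx(ex.pvalue, rel=0.1)

    def test_uniform_draws_give_uniform_p(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(200):
            rho = rng.normal(size=40)
            assoc = self.make_assoc(rho)
            genes = list(assoc.index)
            chosen = list(rng.choice(genes, size=12, replace=False))
            pvals.append(rs.compare_gene_sets(assoc, chosen, genes).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_sets_rejected(self):
        assoc = self.make_assoc(np.arange(10.0))
        genes = list(assoc.index)
        with pytest.raises(ValueError):
            rs.compare_gene_sets(assoc, genes, genes)
        with pytest.raises(ValueError):
            rs.compare_gene_sets(assoc, genes[:2] + ["nope_not_subset_xx"], genes[:2])
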