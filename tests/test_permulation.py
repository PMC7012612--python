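"""Brownian simulation, permulated phenotypes, empirical p, and pi1."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rerscan as rs
from rerscan.permulation import PermulationConfig, _rank_match, _tip_incidence
from rerscan.rer import RERMatrix


class TestSimulateBrownian:
    def test_zero_branch_lengths_give_zero_tips(self):
        tree = rs.read_newick("((A:0,B:0):0,C:0);")
        vals = rs.simulate_brownian(tree, sigma2=1.0, seed=0)
        assert all(v == 0.0 for v in vals.values())

    def test_tip_variance_matches_root_to_tip_depth(self, master61):
        sigma2 = 2.0
        n = 10_000
        tip_order, lengths, A = _tip_incidence(master61)
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((lengths.size, n))
        tips = A @ (np.sqrt(sigma2 * lengths)[:, None] * Z)
        depths = A @ lengths
        emp = tips.var(axis=1)
        ratios = emp / (sigma2 * depths)
        # every tip within 5% of sigma^2 x depth (MC sd ~1.4%)
        assert np.all(np.abs(ratios - 1) < 0.05)

    def test_tip_covariance_matches_shared_path(self, master61):
        sigma2 = 1.0
        n = 10_000
        tip_order, lengths, A = _tip_incidence(master61)
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((lengths.size, n))
        tips = A @ (np.sqrt(sigma2 * lengths)[:, None] * Z)
        shared = (A * lengths) @ A.T  # shared root-to-MRCA path length
        idx = {t: i for i, t in enumerate(tip_order)}
        pairs = [
            ("Human", "Chimp"),
            ("Human", "Gorilla"),
            ("Mouse", "Rat"),
            ("Cow", "Sheep"),
            ("Human", "Rhesus"),
        ]
        for a, b in pairs:
            i, j = idx[a], idx[b]
            expected = sigma2 * shared[i, j]
            assert expected > 0.05  # informative pair
            emp = np.cov(tips[i], tips[j])[0, 1]
            assert emp == pytest.approx(expected, rel=0.10)


class TestPermulatePhenotype:
    def test_output_is_exact_permutation(self, master61):
        rng = np.random.default_rng(2)
        observed = {t: float(rng.normal()) for t in master61.tips}
        out = rs.permulate_phenotype(master61, observed, seed=5)
        assert sorted(out.values()) == pytest.approx(
            sorted(observed.values()), abs=0
        )
        assert set(out) == set(observed)

    def test_two_tip_swap_frequency_near_half(self):
        tree = rs.read_newick("(A:1,B:1);")
        observed = {"A": 0.0, "B": 1.0}
        swapped = sum(
            rs.permulate_phenotype(tree, observed, seed=s)["A"] == 1.0
            for s in range(400)
        )
        assert 150 < swapped < 250

    def test_phylogenetic_restriction_preserves_clade_structure(self):
        # two deep clades: permulated values stay more clade-coherent than
        # unrestricted permutations of the same values
        tree = rs.read_newick(
            "((A:0.05,B:0.05,C:0.05,D:0.05):2.0,"
            "(E:0.05,F:0.05,G:0.05,H:0.05):2.0);"
        )
        clade1 = ["A", "B", "C", "D"]
        observed = dict(zip("ABCDEFGH", [0, 1, 2, 3, 10, 11, 12, 13.0]))
        vals = np.array([observed[t] for t in "ABCDEFGH"])

        def within_clade_var(assign):
            v1 = np.var([assign[t] for t in clade1])
            v2 = np.var([assign[t] for t in "EFGH"])
            return v1 + v2

        rng = np.random.default_rng(3)
        permulated = np.mean([
            within_clade_var(rs.permulate_phenotype(tree, observed, seed=s))
            for s in range(200)
        ])
        plain = np.mean([
            within_clade_var(dict(zip("ABCDEFGH", rng.permutation(vals))))
            for _ in range(200)
        ])
        assert permulated < plain

    def test_sigma2_leaves_rank_matching_invariant(self, master61):
        rng = np.random.default_rng(4)
        observed = {t: float(rng.normal()) for t in master61.tips}
        a = rs.permulate_phenotype(master61, observed, seed=9, sigma2=1.0)
        b = rs.permulate_phenotype(master61, observed, seed=9, sigma2=25.0)
        assert a == b

    def test_tie_breaking_is_deterministic(self):
        sim = np.array([0.5, 0.5, -1.0])
        out = _rank_match(sim, np.array([10.0, 20.0, 30.0]))
        # stable argsort: index 2 smallest, then ties at 0, 1 in order
        np.testing.assert_array_equal(out, [20.0, 30.0, 10.0])


class TestEmpiricalP:
    def test_boundary_cases(self):
        nulls = np.arange(1000.0)
        assert rs.empirical_p(2000.0, nulls) == 0.0
        assert rs.empirical_p(2000.0, nulls, pseudocount=True) == pytest.approx(
            1 / 1001
        )

    def test_observed_at_median(self):
        nulls = np.linspace(0, 1, 1001)
        assert rs.empirical_p(0.5, nulls) == pytest.approx(0.5, abs=0.01)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            nulls = rng.normal(size=50)
            obs = float(rng.normal())
            for direction in ("signed", "two-sided", "greater"):
                got = rs.empirical_p(obs, nulls, direction=direction)
                if direction == "greater":
                    count = sum(1 for v in nulls if v > obs)
                elif direction == "two-sided":
                    count = sum(1 for v in nulls if abs(v) > abs(obs))
                elif obs >= 0:
                    count = sum(1 for v in nulls if v > obs)
                else:
                    count = sum(1 for v in nulls if v < obs)
                assert got == pytest.approx(count / 50)

    def test_empty_nulls_rejected(self):
        with pytest.raises(ValueError):
            rs.empirical_p(1.0, np.array([]))


class TestPi1:
    def test_uniform_p_gives_near_zero(self):
        rng = np.random.default_rng(6)
        p = rng.random(5000)
        est = rs.estimate_pi1(p)
        assert abs(est.pi1) <= 2 / np.sqrt(5000) + 0.02

    def test_known_mixture_recovered(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.random(4000), rng.random(1000) * 1e-4])
        est = rs.estimate_pi1(p)
        assert est.pi1 == pytest.approx(0.20, abs=0.05)

    def test_all_small_p_gives_one(self):
        est = rs.estimate_pi1(np.full(100, 1e-6))
        assert est.pi1 == 1.0

    def test_permulation_null_mode_ratio_formula(self):
        p_real = np.array([0.1, 0.2, 0.6, 0.8, 0.9])
        p_null = np.array([0.3, 0.55, 0.6, 0.7, 0.9, 0.95])
        est = rs.estimate_pi1(p_real, p_null)
        expected_pi0 = (3 / 5) / (5 / 6)
        assert est.pi0 == pytest.approx(expected_pi0)
        assert est.null_source == "permulation"

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            rs.estimate_pi1(np.array([0.5]), lam=1.5)

    def test_lambda_sweep_shape(self):
        rng = np.random.default_rng(8)
        sweep = rs.pi1_sweep(rng.random(500))
        assert len(sweep) == 19
        assert sweep["pi1"].between(-1e-9, 1).all()


def build_correlated_study(master, n_genes=120, n_corr=30, share=0.8, seed=0):
    """RER-like matrix in which one gene set shares a latent rate pattern."""
    rng = np.random.default_rng(seed)
    labels = master.branch_labels()
    B = len(labels)
    latent = rng.standard_normal(B)
    X = rng.standard_normal((n_genes, B))
    X[:n_corr] = np.sqrt(share) * latent + np.sqrt(1 - share) * X[:n_corr]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    rers = RERMatrix(data=pd.DataFrame(X, index=genes, columns=labels))
    coll = rs.GeneSetCollection(
        sets={
            "correlated": genes[:n_corr],
            "independent": genes[n_corr : 2 * n_corr],
            "rest": genes[2 * n_corr :],
        }
    )
    return rers, coll


class TestNullStatistics:
    def test_single_replicate_shapes_and_determinism(self, master61):
        rers, coll = build_correlated_study(master61, n_genes=60, n_corr=15)
        rng = np.random.default_rng(9)
        observed = {t: float(rng.normal()) for t in master61.tips}
        config = PermulationConfig(n_reps=1, seed=4)
        a = rs.null_statistics(rers, master61, observed, coll, config)
        assert a.gene_null_stat.shape == (len(a.gene_ids), 1)
        b = rs.null_statistics(rers, master61, observed, coll, config)
        assert np.array_equal(a.gene_null_stat, b.gene_null_stat)
        assert np.array_equal(a.pathway_null_stat, b.pathway_null_stat)

    def test_observed_stats_sit_at_uniform_quantiles_under_null(self, master61):
        # phenotype-independent RERs: empirical gene p-values are uniform
        rng = np.random.default_rng(10)
        labels = master61.branch_labels()
        X = rng.standard_normal((300, len(labels)))
        rers = RERMatrix(
            data=pd.DataFrame(
                X, index=[f"g{i:03d}" for i in range(300)], columns=labels
            )
        )
        observed = {t: float(rng.normal()) for t in master61.tips}
        null = rs.null_statistics(
            rers, master61, observed, None, PermulationConfig(n_reps=100, seed=1)
        )
        emp = null.gene_empirical_p(direction="two-sided")
        assert stats.kstest(emp, "uniform").pvalue > 0.01

    def test_pathway_permulation_p_more_conservative_for_correlated_sets(
        self, master61
    ):
        # genes sharing rate covariance violate the rank-sum independence
        # assumption: the permulation p should exceed the parametric p on
        # average for the correlated set
        param_ps, perm_ps = [], []
        for seed in range(6):
            rers, coll = build_correlated_study(master61, seed=seed)
            rng = np.random.default_rng(100 + seed)
            observed = {t: float(rng.normal()) for t in master61.tips}
            tip_order, P = rs.phenotypes.paths_operator(master61)
            y = pd.Series(
                P @ np.array([observed[t] for t in tip_order]),
                index=master61.branch_labels(),
            )
            assoc = rs.associate_all(rers, y)
            enr = rs.enrich(assoc, coll)
            null = rs.null_statistics(
                rers, master61, observed, coll,
                PermulationConfig(n_reps=150, seed=seed),
            )
            p_perm = null.pathway_empirical_p(direction="two-sided")
            param_ps.append(enr.loc["correlated", "p_param"])
            perm_ps.append(p_perm["correlated"])
        assert np.mean(perm_ps) > np.mean(param_ps)
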