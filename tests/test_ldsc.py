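import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurofactors import gwas as gw
from neurofactors import ldsc
from neurofactors import simulate as sim

from _oracles import bh_reject_bruteforce, thresholded_pair_correlation


def _sumstats_from_z(z, ell_n=None, n=10_000):
    M = len(z)
    table = pd.DataFrame(
        {
            "SNP": [f"rs{j}" for j in range(M)],
            "CHR": 1,
            "BP": np.arange(1, M + 1) * 10_000,
            "A1": "A",
            "A2": "G",
            "FREQ": 0.3,
            "BETA": z / np.sqrt(n),
            "SE": 1.0 / np.sqrt(n),
            "Z": z,
            "P": 1.0,
            "N": n,
        }
    )
    return gw.GwasSummaryStats(table=table)


def _ldscores(ell):
    M = len(ell)
    t = pd.DataFrame(
        {"CHR": 1, "SNP": [f"rs{j}" for j in range(M)], "BP": np.arange(1, M + 1) * 10_000, "L2": ell}
    )
    return ldsc.LDScoreTable(table=t, M=M)


class TestComputeLdScores:
    def test_unlinked_snps_have_unit_scores(self):
        cfg = sim.SimulationConfig(
            n_individuals=20_000, n_snps=300, ld_rho=0.0, ld_rho_range=None, seed=31
        )
        g = sim.simulate_genotypes(cfg)
        scores = ldsc.compute_ld_scores(g)
        assert np.abs(scores.table["L2"] - 1.0).max() < 0.05

    def test_ar1_block_matches_geometric_oracle(self):
        rho, B = 0.9, 50
        cfg = sim.SimulationConfig(
            n_individuals=50_000, n_snps=2 * B, ld_block_size=B, ld_rho=rho,
            ld_rho_range=None, maf_range=(0.5, 0.5), seed=32,
        )
        g = sim.simulate_genotypes(cfg)
        scores = ldsc.compute_ld_scores(g)
        # closed form: l_mid = 1 + 2 sum_d r(d)^2 with r(d) the
        # thresholded-AR(1) genotype correlation at lag d
        r2 = [thresholded_pair_correlation(rho**d, 0.5, 0.5) ** 2 for d in range(1, 15)]
        mid = B // 2
        expected = 1.0 + sum(r2[: mid]) + sum(r2[: B - mid])
        got = scores.table["L2"].iloc[mid]
        assert got == pytest.approx(expected, rel=0.05)

    def test_window_smaller_than_spacing_gives_self_term(self):
        cfg = sim.SimulationConfig(
            n_individuals=5_000, n_snps=100, ld_rho=0.9, ld_rho_range=None, seed=33
        )
        g = sim.simulate_genotypes(cfg)
        scores = ldsc.compute_ld_scores(g, window_kb=5.0)  # spacing is 10 kb
        assert np.allclose(scores.table["L2"], 1.0, atol=1e-9)

    def test_nonpositive_window_rejected(self, small_genetic_cohort):
        _, g, _ = small_genetic_cohort
        with pytest.raises(ValueError, match="window"):
            ldsc.compute_ld_scores(g, window_kb=0.0)


class TestH2Regression:
    def test_recovers_slope_and_intercept_from_model_draws(self, rng):
        # chi2 drawn from the LDSC expectation directly
        M, n, h2 = 20_000, 20_000, 0.1
        ell = rng.uniform(1.0, 12.0, M)
        mean = 1.0 + n * h2 * ell / M
        z = rng.standard_normal(M) * np.sqrt(mean)
        fit = ldsc.h2_regression(_sumstats_from_z(z, n=n), _ldscores(ell))
        assert fit.h2 == pytest.approx(h2, abs=3 * fit.se_h2)
        assert fit.intercept == pytest.approx(1.0, abs=3 * fit.se_intercept)
        assert fit.se_h2 > 0

    def test_null_trait_calibration(self, rng):
        M = 10_000
        ell = rng.uniform(1.0, 8.0, M)
        z = rng.standard_normal(M)
        fit = ldsc.h2_regression(_sumstats_from_z(z), _ldscores(ell))
        assert abs(fit.h2) <= 2.5 * fit.se_h2
        assert abs(fit.intercept - 1.0) <= 2.5 * fit.se_intercept

    def test_constant_ld_scores_rejected(self, rng):
        z = rng.standard_normal(5_000)
        with pytest.raises(ValueError, match="slope is undefined"):
            ldsc.h2_regression(_sumstats_from_z(z), _ldscores(np.full(5_000, 2.0)))

    def test_fewer_snps_than_blocks_rejected(self, rng):
        z = rng.standard_normal(100)
        with pytest.raises(ValueError, match="blocks"):
            ldsc.h2_regression(_sumstats_from_z(z), _ldscores(np.linspace(1, 5, 100)),
                               n_blocks=200)

    def test_chi2_and_maf_filters_logged(self, rng):
        M = 5_000
        ell = rng.uniform(1, 5, M)
        z = rng.standard_normal(M)
        z[0] = 10.0  # chi2 = 100 > 80
        ss = _sumstats_from_z(z)
        ss.table.loc[1, "FREQ"] = 0.001
        fit = ldsc.h2_regression(ss, _ldscores(ell), n_blocks=50)
        assert fit.filters_applied["removed_chi2"] == 1
        assert fit.filters_applied["removed_maf"] == 1
        assert fit.snps_used == M - 2

    def test_scale_equivariance(self, rng):
        M = 5_000
        ell = rng.uniform(1, 9, M)
        mean = 1.0 + 0.3 * ell
        z = rng.standard_normal(M) * np.sqrt(mean)
        f1 = ldsc.h2_regression(_sumstats_from_z(z), _ldscores(ell), n_blocks=50)
        scores2 = ldsc.LDScoreTable(table=_ldscores(ell).table.assign(L2=3 * ell),
                                    M=3 * M)
        f2 = ldsc.h2_regression(_sumstats_from_z(z), scores2, n_blocks=50)
        assert f2.h2 == pytest.approx(f1.h2, rel=0.15)


class TestRgRegression:
    def test_trait_with_itself_is_one(self, rng):
        M, n, h2 = 20_000, 20_000, 0.2
        ell = rng.uniform(1.0, 12.0, M)
        mean = 1.0 + n * h2 * ell / M
        z = rng.standard_normal(M) * np.sqrt(mean)
        ss = _sumstats_from_z(z, n=n)
        scores = _ldscores(ell)
        fit = ldsc.h2_regression(ss, scores)
        r = ldsc.rg_regression(ss, ss, scores, fit, fit)
        assert r["rg"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_traits_near_zero(self, rng):
        M, n, h2 = 20_000, 20_000, 0.2
        ell = rng.uniform(1.0, 12.0, M)
        mean = 1.0 + n * h2 * ell / M
        za = rng.standard_normal(M) * np.sqrt(mean)
        zb = rng.standard_normal(M) * np.sqrt(mean)
        sa, sb = _sumstats_from_z(za, n=n), _sumstats_from_z(zb, n=n)
        scores = _ldscores(ell)
        fa = ldsc.h2_regression(sa, scores)
        fb = ldsc.h2_regression(sb, scores)
        r = ldsc.rg_regression(sa, sb, scores, fa, fb)
        assert abs(r["rg"]) <= 2.5 * r["se"]

    def test_sign_symmetry(self, rng):
        M, n = 20_000, 20_000
        ell = rng.uniform(1.0, 12.0, M)
        cov = np.sqrt(np.maximum(0, 1 + n * 0.15 * ell / M - 1))
        shared = rng.standard_normal(M)
        za = shared * cov + rng.standard_normal(M)
        zb = shared * cov + rng.standard_normal(M)
        sa, sb = _sumstats_from_z(za, n=n), _sumstats_from_z(zb, n=n)
        scores = _ldscores(ell)
        fa = ldsc.h2_regression(sa, scores)
        fb = ldsc.h2_regression(sb, scores)
        r = ldsc.rg_regression(sa, sb, scores, fa, fb)
        r_neg = ldsc.rg_regression(sa, _sumstats_from_z(-zb, n=n), scores, fa, fb)
        assert r_neg["rg"] == pytest.approx(-r["rg"], abs=1e-10)

    def test_nonpositive_h2_flagged(self, rng):
        z = rng.standard_normal(5_000)
        ss = _sumstats_from_z(z)
        scores = _ldscores(rng.uniform(1, 5, 5_000))
        good = ldsc.LdscFit(h2=0.1, intercept=1, se_h2=0.01, se_intercept=0.01,
                            n_blocks=10, snps_used=5_000)
        bad = ldsc.LdscFit(h2=-0.01, intercept=1, se_h2=0.01, se_intercept=0.01,
                           n_blocks=10, snps_used=5_000)
        with pytest.raises(ValueError, match="non-positive heritability"):
            ldsc.rg_regression(ss, ss, scores, good, bad)


class TestBhFdr:
    def test_all_ones_none_significant(self):
        sig, adj = ldsc.bh_fdr(np.ones(20), 0.05)
        assert not sig.any()
        assert np.allclose(adj, 1.0)

    def test_hand_worked_example(self):
        sig, adj = ldsc.bh_fdr([0.001, 0.02, 0.03, 0.9], 0.05)
        assert sig.tolist() == [True, True, True, False]

    def test_single_test_adjusted_equals_raw(self):
        _, adj = ldsc.bh_fdr([0.031], 0.05)
        assert adj[0] == pytest.approx(0.031)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_bruteforce_stepup(self, pvals, q):
        sig, _ = ldsc.bh_fdr(pvals, q)
        assert sig.tolist() == bh_reject_bruteforce(pvals, q).tolist()
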