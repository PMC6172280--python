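"""Statistical structure of the synthetic-data generators."""

import numpy as np
import pytest

from twaskit.exceptions import ValidationError
from twaskit.synthetic_data import (
    SimConfig,
    calibration_experiment,
    config_from_yaml,
    config_to_yaml,
    random_gene_correlation,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_sumstats,
    simulate_twas_region,
)


class TestGenotypes:
    def test_fixed_seed_is_bit_identical(self, cfg):
        a = simulate_genotypes(cfg, n=50, p=10, rng=np.random.default_rng(3))
        b = simulate_genotypes(cfg, n=50, p=10, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_independent_snps_have_small_ld(self):
        cfg = SimConfig(seed=0, rho_ld=0.0)
        g = simulate_genotypes(cfg, n=2000, p=6, rng=np.random.default_rng(4))
        r = np.corrcoef(g.dosages.T)
        assert np.abs(r[np.triu_indices(6, 1)]).mean() < 4 / np.sqrt(2000)

    def test_high_ld_attenuated_by_tetrachoric_bound(self):
        # dichotomizing latent Gaussians at the MAF-0.5 threshold caps the
        # dosage correlation at (2/pi) asin(rho) — the phi-coefficient bound
        cfg = SimConfig(seed=0, rho_ld=0.9, maf_range=(0.5, 0.5))
        g = simulate_genotypes(cfg, n=4000, p=2, rng=np.random.default_rng(5))
        r = np.corrcoef(g.dosages.T)[0, 1]
        expected = (2.0 / np.pi) * np.arcsin(0.9)
        assert r == pytest.approx(expected, abs=0.05)

    def test_dosages_are_biallelic_counts(self, geno):
        assert set(np.unique(geno.dosages)) <= {0.0, 1.0, 2.0}
        assert (geno.maf >= 0).all() and (geno.maf <= 0.5).all()


class TestExpression:
    def test_variance_fraction_exact_by_construction(self, geno):
        y, w = simulate_expression(geno, h2_expr=0.4, k_causal_snps=3, seed=2)
        g = geno.standardized() @ w
        assert np.var(g) / np.var(y) == pytest.approx(0.4, abs=1e-12)

    def test_fully_heritable_expression_is_genetic(self, geno):
        y, w = simulate_expression(geno, h2_expr=1.0, k_causal_snps=3, seed=2)
        np.testing.assert_allclose(y, geno.standardized() @ w, atol=1e-12)

    def test_null_expression_has_no_weights(self, geno):
        y, w = simulate_expression(geno, h2_expr=0.0, k_causal_snps=3, seed=2)
        assert not w.any()
        assert np.std(y) == pytest.approx(1.0)

    def test_too_many_causal_snps_rejected(self, geno):
        with pytest.raises(ValidationError):
            simulate_expression(geno, h2_expr=0.4, k_causal_snps=geno.p + 1, seed=0)


class TestGwasSumstats:
    def test_null_scores_are_standard_normal(self, geno):
        ss = simulate_gwas_sumstats(geno, np.zeros(geno.p), 0.0, 10_000, seed=6)
        z = ss.table["z"].to_numpy()
        assert abs(z.mean()) < 4 / np.sqrt(geno.p)  # correlated, loose bound
        assert 0.3 < z.std() < 2.0

    def test_causal_snp_mean_grows_with_sqrt_n(self, geno):
        _, w = simulate_expression(geno, h2_expr=0.8, k_causal_snps=1, seed=1)
        j = int(np.argmax(np.abs(w)))
        alpha = 0.05
        means = []
        for n in (10_000, 40_000):
            zj = [
                simulate_gwas_sumstats(geno, w, alpha, n, seed=s, mode="summary")
                .table["z"].iloc[j]
                for s in range(60)
            ]
            means.append(np.mean(zj))
        # quadrupling n doubles the causal expectation
        assert means[1] / means[0] == pytest.approx(2.0, abs=0.45)

    def test_individual_and_summary_modes_agree(self, cfg):
        rng = np.random.default_rng(8)
        g_ref = simulate_genotypes(cfg, n=400, p=15, rng=rng)
        _, w = simulate_expression(g_ref, h2_expr=0.6, k_causal_snps=3, seed=9)
        from twaskit.ld_reference import compute_ld
        from twaskit.twas import twas_zscore

        V = compute_ld(g_ref, ridge=0.05)
        n_gwas, alpha = 20_000, 0.03
        z_sum, z_ind = [], []
        for s in range(60):
            ss_s = simulate_gwas_sumstats(g_ref, w, alpha, n_gwas, seed=s, mode="summary")
            z_sum.append(twas_zscore(w, ss_s.table["z"].to_numpy(), V)[0])
            cohort = simulate_genotypes(cfg, n=n_gwas, p=15, rng=np.random.default_rng(1000 + s))
            ss_i = simulate_gwas_sumstats(cohort, w, alpha, n_gwas, seed=s, mode="individual")
            z_ind.append(twas_zscore(w, ss_i.table["z"].to_numpy(), V)[0])
        q1s, q3s = np.percentile(z_sum, [25, 75])
        q1i, q3i = np.percentile(z_ind, [25, 75])
        assert max(q1s, q1i) < min(q3s, q3i)  # interquartile ranges overlap


class TestTwasRegions:
    def test_null_prior_gives_standard_scores(self):
        rng = np.random.default_rng(10)
        zs = np.array(
            [simulate_twas_region(3, np.eye(3), 0, n=1000, sigma_a2=0.0, rng=rng) for _ in range(800)]
        )
        assert abs(zs.mean()) < 0.05
        assert 0.9 < zs.var() < 1.1

    def test_causal_chi2_mean_matches_moment(self):
        rng = np.random.default_rng(11)
        n, sigma_a2 = 1000, 0.03
        z2 = np.array(
            [
                simulate_twas_region(2, np.eye(2), 0, n=n, sigma_a2=sigma_a2, rng=rng)[0] ** 2
                for _ in range(5000)
            ]
        )
        expected = 1 + n * sigma_a2
        se = z2.std() / np.sqrt(z2.size)
        assert abs(z2.mean() - expected) < 3 * se

    def test_gene_correlation_matrices_are_valid(self, cfg):
        rng = np.random.default_rng(12)
        corr = random_gene_correlation(cfg, rng)
        assert corr.shape == (cfg.k_genes, cfg.k_genes)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.linalg.eigvalsh(corr).min() > -1e-8


class TestCalibration:
    def test_rho_one_has_full_coverage(self):
        cfg = SimConfig(seed=13, p=20)
        tab = calibration_experiment(cfg, n_regions=50, rho_levels=(1.0,))
        assert tab["coverage"].iloc[0] == 1.0

    def test_single_gene_regions_are_trivial(self):
        cfg = SimConfig(seed=14, p=20, k_genes=1)
        tab = calibration_experiment(cfg, n_regions=50, rho_levels=(0.9,))
        assert tab["coverage"].iloc[0] == 1.0
        assert tab["mean_set_size"].iloc[0] == 1.0

    def test_coverage_at_least_rho_under_strong_signal(self):
        cfg = SimConfig(seed=15, p=20)
        tab = calibration_experiment(cfg, n_regions=250, rho_levels=(0.5, 0.9))
        for rho, cov in zip(tab["rho"], tab["coverage"]):
            assert cov >= rho - 2 * np.sqrt(rho * (1 - rho) / 250)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path, cfg):
        path = tmp_path / "cfg.yaml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(path) == cfg

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(h2_expr=1.5)
        with pytest.raises(ValidationError):
            SimConfig(maf_range=(0.0, 0.5))
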