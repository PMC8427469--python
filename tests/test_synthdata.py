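"""Generator checks: Hardy-Weinberg dosages, tunable LD, summary-statistic
noise, the latent phenotype structure, and missingness mechanisms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsopgs.synthdata import (
    ConfigError,
    SimConfig,
    inject_missingness,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_study,
    simulate_sumstats,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_individuals": 0},
        {"n_snps": -5},
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.1, 0.6)},
        {"ld_rho": 1.0},
        {"residual_sds": np.zeros(12)},
        {"missing_rate": 1.0},
        {"pgs_effects": np.zeros((2, 5)), "n_traits": 3},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        SimConfig(**kwargs)


class TestGenotypes:
    def test_mean_dosage_at_maf_half(self):
        cfg = SimConfig(n_individuals=10_000, n_snps=20, maf_range=(0.5, 0.5), seed=0)
        geno = simulate_genotypes(cfg)
        means = geno.dosages.mean(axis=0)
        assert np.all(np.abs(means - 1.0) < 0.05)
        assert set(np.unique(geno.dosages)) <= {0, 1, 2}

    def test_zero_rho_gives_independent_adjacent_snps(self):
        cfg = SimConfig(n_individuals=5_000, n_snps=40, ld_rho=0.0,
                        ld_block_size=10, seed=1)
        geno = simulate_genotypes(cfg)
        cors = [
            abs(np.corrcoef(geno.dosages[:, j].astype(float),
                            geno.dosages[:, j + 1].astype(float))[0, 1])
            for j in range(39) if (j + 1) % 10 != 0
        ]
        assert np.mean(cors) < 0.05

    def test_adjacent_r2_matches_copula_monte_carlo_oracle(self):
        """Dosage r^2 of adjacent SNPs under the Gaussian-threshold copula
        agrees with a brute-force haplotype simulation of the same copula."""
        rho, maf = 0.9, 0.3
        # oracle: >= 1e6 haplotype pairs drawn directly from the copula
        rng = np.random.default_rng(99)
        z1 = rng.standard_normal(1_000_000)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(1_000_000)
        t = stats.norm.ppf(maf)
        h1, h2 = (z1 < t).astype(float), (z2 < t).astype(float)
        r2_oracle = np.corrcoef(h1, h2)[0, 1] ** 2  # dosage corr == haplotype corr
        cfg = SimConfig(n_individuals=20_000, n_snps=10, maf_range=(maf, maf),
                        ld_rho=rho, ld_block_size=10, seed=2)
        geno = simulate_genotypes(cfg)
        r2_emp = np.mean([
            np.corrcoef(geno.dosages[:, j].astype(float),
                        geno.dosages[:, j + 1].astype(float))[0, 1] ** 2
            for j in range(9)
        ])
        assert abs(r2_emp - r2_oracle) < 0.05

    def test_block_positions_respect_clumping_window(self):
        cfg = SimConfig(n_individuals=10, n_snps=25, ld_block_size=10, seed=3)
        geno = simulate_genotypes(cfg)
        bp = geno.snps["bp"].to_numpy()
        assert bp[9] - bp[0] < 250_000          # block inside the window
        assert bp[10] - bp[9] > 250_000         # blocks beyond the window


class TestSumstats:
    def test_infinite_discovery_sample_is_noise_free(self, small_study):
        w = np.asarray(small_study.truth["true_weights"])[0]
        ss = simulate_sumstats(small_study.genotypes, w, np.inf, seed=0)
        np.testing.assert_array_equal(ss["beta"].to_numpy(), w)

    def test_null_pvalues_are_uniform(self):
        cfg = SimConfig(n_individuals=50, n_snps=1000, ld_rho=0.0, seed=4)
        geno = simulate_genotypes(cfg)
        ss = simulate_sumstats(geno, np.zeros(1000), discovery_n=20_000, seed=5)
        frac = float((ss["p"] < 0.05).mean())
        assert abs(frac - 0.05) < 0.02

    def test_beta_noise_matches_analytic_se(self):
        """Empirical sd of the reported beta across seeds matches the
        oracle se = 1/sqrt(N * 2 f (1-f))."""
        cfg = SimConfig(n_individuals=50, n_snps=1, maf_range=(0.3, 0.3), seed=6)
        geno = simulate_genotypes(cfg)
        f = float(geno.snps["maf"].iloc[0])
        N = 10_000
        betas = [
            float(simulate_sumstats(geno, np.array([0.1]), N, seed=s)["beta"].iloc[0])
            for s in range(2000)
        ]
        se_oracle = 1.0 / np.sqrt(N * 2 * f * (1 - f))
        assert abs(np.std(betas) / se_oracle - 1.0) < 0.05

    def test_discovery_n_below_two_rejected(self, small_study):
        with pytest.raises(ConfigError):
            simulate_sumstats(
                small_study.genotypes,
                np.zeros(small_study.genotypes.n_snps),
                discovery_n=1,
            )


class TestPhenotypes:
    def test_no_common_factor_means_no_cross_substance_correlation(self):
        cfg = SimConfig(n_individuals=5000, lam_common=np.zeros(12), seed=7)
        phen, _ = simulate_phenotypes(None, cfg)
        cols = cfg.indicator_names
        corr = phen[cols].corr().to_numpy()
        cross = []
        for i in range(12):
            for j in range(i + 1, 12):
                if i // 3 != j // 3 and i % 3 != j % 3:  # different substance & wave
                    cross.append(corr[i, j])
        assert abs(np.mean(cross)) < 0.03

    def test_injected_pgs_effect_is_the_latent_correlation(self):
        """b = 0.14 on the common factor: corr(true PGS, C) ~ 0.14."""
        cfg = SimConfig(
            n_individuals=50_000, n_snps=40, n_traits=1,
            pgs_effects=[[0.14, 0, 0, 0, 0]], seed=8,
        )
        geno = simulate_genotypes(cfg, np.random.default_rng(8))
        rng = np.random.default_rng(9)
        cfg.true_weights = rng.normal(0, 0.05, (1, 40))
        phen, truth = simulate_phenotypes(geno, cfg, rng)
        r = np.corrcoef(truth["pgs_true"][:, 0], truth["common"])[0, 1]
        assert abs(r - 0.14) < 0.02

    def test_model_implied_covariance_matches_sample(self):
        """Continuous indicators: Lambda Lambda' + Theta reproduces the
        sample covariance (covariance-algebra oracle)."""
        cfg = SimConfig(n_individuals=50_000, discretise=False, seed=10)
        phen, _ = simulate_phenotypes(None, cfg)
        Y = phen[cfg.indicator_names].to_numpy()
        S = np.cov(Y, rowvar=False)
        lam_c, lam_s = cfg.lam_common, cfg.lam_specific
        implied = np.outer(lam_c, lam_c) + np.diag(cfg.residual_sds**2)
        for k in range(4):
            sl = slice(3 * k, 3 * k + 3)
            implied[sl, sl] += np.outer(lam_s[sl], lam_s[sl])
        for t in range(3):
            idx = [3 * k + t for k in range(4)]
            implied[np.ix_(idx, idx)] += 1.0
        # compare on the correlation scale (indicator variances are ~5,
        # so raw-covariance noise would swamp a fixed absolute tolerance)
        d = np.sqrt(np.diag(implied))
        err = (S - implied) / np.outer(d, d)
        assert np.max(np.abs(err)) < 0.05

    def test_latent_factors_unit_variance_and_orthogonal(self):
        cfg = SimConfig(n_individuals=20_000, seed=11)
        _, truth = simulate_phenotypes(None, cfg)
        F = np.column_stack(
            [truth["common"], truth["specific"], truth["occasion"]]
        )
        v = F.var(axis=0)
        assert np.all(np.abs(v - 1.0) < 0.05)
        corr = np.corrcoef(F, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert np.max(np.abs(corr)) < 0.03

    def test_counts_bounded_and_integer(self):
        cfg = SimConfig(n_individuals=500, seed=12)
        phen, _ = simulate_phenotypes(None, cfg)
        for k, sub in enumerate(["cig", "alc", "can", "oth"]):
            for t in ["17", "20", "22"]:
                col = phen[f"{sub}_{t}"]
                assert (col >= 0).all() and (col <= cfg.count_max[k]).all()
                assert np.allclose(col, col.round())

    def test_overlarge_structural_effects_rejected(self):
        cfg = SimConfig(
            n_individuals=300, n_snps=20, n_traits=1,
            pgs_effects=[[0.999, 0, 0, 0, 0]], sex_effects=[0.5, 0, 0, 0, 0],
            seed=13,
        )
        geno = simulate_genotypes(cfg)
        cfg.true_weights = np.random.default_rng(0).normal(0, 0.05, (1, 20))
        with pytest.raises(ConfigError, match="variance"):
            simulate_phenotypes(geno, cfg)


class TestMissingness:
    def test_zero_rate_is_identity(self):
        cfg = SimConfig(n_individuals=200, seed=14)
        phen, _ = simulate_phenotypes(None, cfg)
        out = inject_missingness(phen, 0.0, "mcar", seed=0)
        pd.testing.assert_frame_equal(out, phen)

    def test_mcar_rate_matches_target(self):
        cfg = SimConfig(n_individuals=10_000, seed=15)
        phen, _ = simulate_phenotypes(None, cfg)
        rates = np.zeros(12)
        rates[0] = 0.3
        out = inject_missingness(phen, rates, "mcar", seed=1)
        frac = out["cig_17"].isna().mean()
        assert abs(frac - 0.3) < 0.02
        assert not out[["sex", "pc1"]].isna().any().any()

    def test_mar_missingness_depends_on_covariate(self):
        """Logistic dependence on sex: observed per-group missingness
        matches a brute-force recomputation of the logistic model."""
        cfg = SimConfig(n_individuals=20_000, seed=16)
        phen, _ = simulate_phenotypes(None, cfg)
        out = inject_missingness(
            phen, 0.3, "mar_covariate", seed=2, covariate="sex", mar_strength=1.5
        )
        sex = phen["sex"].to_numpy()
        x_std = (sex - sex.mean()) / sex.std(ddof=1)
        # oracle: recompute the calibrated intercept by brute-force search
        from scipy.optimize import brentq
        from scipy.special import expit

        a = brentq(lambda a: expit(a + 1.5 * x_std).mean() - 0.3, -30, 30)
        # align rows (some dropped): merge on id
        merged = phen[["id", "sex"]].merge(
            out[["id", "cig_17"]], on="id", how="inner"
        )
        for s in (0.0, 1.0):
            grp = merged[merged.sex == s]
            p_oracle = float(expit(a + 1.5 * x_std[sex == s]).mean())
            assert abs(grp["cig_17"].isna().mean() - p_oracle) < 0.03
        f0 = merged[merged.sex == 0]["cig_17"].isna().mean()
        f1 = merged[merged.sex == 1]["cig_17"].isna().mean()
        assert f1 > f0  # direction follows the positive slope

    def test_all_missing_rows_dropped(self):
        cfg = SimConfig(n_individuals=3000, seed=17)
        phen, _ = simulate_phenotypes(None, cfg)
        out = inject_missingness(phen, 0.7, "mcar", seed=3)
        assert out.attrs["n_dropped_all_missing"] > 0
        assert len(out) + out.attrs["n_dropped_all_missing"] == len(phen)
        vals = out[cfg.indicator_names].to_numpy()
        assert not np.isnan(vals).all(axis=1).any()

    def test_rate_of_one_rejected(self):
        cfg = SimConfig(n_individuals=50, seed=18)
        phen, _ = simulate_phenotypes(None, cfg)
        with pytest.raises(ConfigError):
            inject_missingness(phen, 1.0, "mcar", seed=0)


def test_fixed_seed_reproducibility():
    cfg = dict(n_individuals=300, n_snps=60, n_traits=2, seed=123)
    a = simulate_study(SimConfig(**cfg))
    b = simulate_study(SimConfig(**cfg))
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    for sa, sb in zip(a.sumstats, b.sumstats):
        pd.testing.assert_frame_equal(sa, sb)
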