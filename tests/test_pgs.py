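"""Polygenic-score construction: harmonisation, LD, clumping, scoring,
standardisation, and end-to-end recovery of the true genetic value."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tsopgs.pgs import (
    HarmonisationError,
    ScoreError,
    UndefinedLDError,
    clump,
    compute_pgs,
    harmonise,
    ld_r2,
    score,
    standardise,
)
from tsopgs.synthdata import GenotypeMatrix, SimConfig, simulate_genotypes, simulate_sumstats


def make_genotypes(dosages, bps=None, chrs=None, a1=None, a2=None):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "snp": [f"rs{j+1}" for j in range(m)],
            "chr": chrs if chrs is not None else ["1"] * m,
            "bp": bps if bps is not None else (np.arange(m) + 1) * 1000,
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
            "maf": dosages.mean(axis=0) / 2,
        }
    )
    return GenotypeMatrix(dosages=dosages, snps=snps,
                          ids=[f"id{i}" for i in range(n)])


def make_sumstats(geno, beta, p):
    out = geno.snps[["snp", "chr", "bp", "a1", "a2"]].copy()
    out["beta"] = beta
    out["p"] = p
    return out


class TestHarmonise:
    def test_aligned_input_passes_through(self):
        geno = make_genotypes(np.zeros((4, 3)))
        ss = make_sumstats(geno, [0.1, -0.2, 0.3], [0.5, 0.1, 0.9])
        out, report = harmonise(ss, geno.snps)
        np.testing.assert_array_equal(out["beta"], [0.1, -0.2, 0.3])
        assert report["n_flipped"] == 0 and report["n_matched"] == 3

    def test_swapped_alleles_flip_beta_sign(self):
        geno = make_genotypes(np.zeros((4, 1)), a1=["A"], a2=["G"])
        ss = make_sumstats(geno, [0.2], [0.5])
        ss.loc[0, ["a1", "a2"]] = ["G", "A"]
        out, report = harmonise(ss, geno.snps)
        assert out["beta"].iloc[0] == pytest.approx(-0.2)
        assert out["a1"].iloc[0] == "A" and report["n_flipped"] == 1

    def test_ambiguous_snps_dropped(self):
        geno = make_genotypes(np.zeros((4, 2)), a1=["A", "C"], a2=["T", "G"])
        ss = make_sumstats(geno, [0.1, 0.2], [0.5, 0.5])
        with pytest.raises(HarmonisationError):
            harmonise(ss, geno.snps)  # both rows ambiguous -> nothing usable

    def test_injected_swaps_recovered_against_truth(self):
        """simulate_sumstats flips a fraction of rows; harmonisation must
        restore the panel orientation for every non-ambiguous SNP."""
        cfg = SimConfig(n_individuals=50, n_snps=200, ambiguous_fraction=0.1, seed=0)
        geno = simulate_genotypes(cfg)
        w = np.random.default_rng(1).normal(0, 0.1, 200)
        ss = simulate_sumstats(geno, w, np.inf, seed=2, flip_fraction=0.4)
        out, report = harmonise(ss, geno.snps)
        truth = pd.Series(w, index=geno.snps["snp"])
        np.testing.assert_allclose(
            out["beta"].to_numpy(), truth.loc[out["snp"]].to_numpy(), atol=1e-12
        )
        assert report["n_ambiguous_dropped"] > 0 and report["n_flipped"] > 0

    def test_no_overlap_raises(self):
        geno = make_genotypes(np.zeros((4, 2)))
        ss = make_sumstats(geno, [0.1, 0.2], [0.5, 0.5])
        ss["snp"] = ["other1", "other2"]
        with pytest.raises(HarmonisationError):
            harmonise(ss, geno.snps)


class TestLD:
    def test_self_correlation_is_one(self):
        geno = make_genotypes([[0, 0], [1, 1], [2, 2], [0, 1]])
        assert ld_r2(geno, "rs1", "rs1") == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        geno = make_genotypes(np.array([[0, 2], [1, 1], [2, 0], [0, 2]]))
        assert ld_r2(geno, "rs1", "rs2") == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        D = rng.integers(0, 3, size=(50, 2)).astype(float)
        geno = make_genotypes(D)
        x, y = D[:, 0], D[:, 1]
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert ld_r2(geno, "rs1", "rs2") == pytest.approx(r**2, abs=1e-12)

    def test_zero_variance_raises(self):
        geno = make_genotypes([[1, 0], [1, 1], [1, 2]])
        with pytest.raises(UndefinedLDError):
            ld_r2(geno, "rs1", "rs2")


def brute_force_clump(sumstats, geno, r2_threshold, window_kb):
    """Literal implementation of the greedy rule, written independently."""
    tab = sumstats.sort_values(["p", "bp", "snp"], kind="mergesort")
    alive = dict.fromkeys(tab["snp"], True)
    retained = []
    D = {s: geno.dosages[:, k].astype(float)
         for k, s in enumerate(geno.snps["snp"])}
    info = tab.set_index("snp")
    for s in tab["snp"]:
        if not alive[s]:
            continue
        retained.append(s)
        for t in tab["snp"]:
            if t == s or not alive[t]:
                continue
            if info.at[t, "chr"] != info.at[s, "chr"]:
                continue
            if abs(info.at[t, "bp"] - info.at[s, "bp"]) > window_kb * 1000:
                continue
            r = np.corrcoef(D[s], D[t])[0, 1]
            if r * r > r2_threshold:
                alive[t] = False
    return retained


class TestClump:
    def test_single_snp_retained(self):
        geno = make_genotypes([[0], [1], [2], [1]])
        ss = make_sumstats(geno, [0.1], [0.3])
        assert clump(ss, geno) == ["rs1"]

    def test_correlated_pair_keeps_smaller_p(self):
        D = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1]], float)
        geno = make_genotypes(D, bps=[1000, 11_000])
        ss = make_sumstats(geno, [0.1, 0.2], [1e-4, 1e-8])
        assert clump(ss, geno) == ["rs2"]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        for trial in range(8):
            n, m = 60, 15
            base = rng.integers(0, 3, size=(n, m)).astype(float)
            # create LD by copying some columns with noise
            for j in range(1, m):
                if rng.random() < 0.5:
                    base[:, j] = np.where(
                        rng.random(n) < 0.8, base[:, j - 1], base[:, j]
                    )
            bps = np.sort(rng.integers(1, 2_000_000, size=m))
            chrs = [str(1 + (j >= 8)) for j in range(m)]
            geno = make_genotypes(base, bps=bps, chrs=chrs)
            ss = make_sumstats(geno, rng.normal(size=m),
                               rng.choice([1e-8, 1e-5, 1e-3, 0.05, 0.5], m))
            got = clump(ss, geno, 0.10, 250)
            want = brute_force_clump(ss, geno, 0.10, 250)
            assert got == want, f"trial {trial}"

    def test_order_independence(self):
        rng = np.random.default_rng(5)
        D = rng.integers(0, 3, size=(80, 12)).astype(float)
        geno = make_genotypes(D, bps=np.arange(12) * 50_000)
        ss = make_sumstats(geno, rng.normal(size=12), rng.uniform(0.01, 1, 12))
        shuffled = ss.sample(frac=1.0, random_state=6).reset_index(drop=True)
        assert clump(ss, geno) == clump(shuffled, geno)


class TestScore:
    def test_zero_betas_zero_scores(self):
        geno = make_genotypes([[0, 1], [2, 1]])
        ss = make_sumstats(geno, [0.0, 0.0], [0.5, 0.5])
        vec = score(geno, ss)
        np.testing.assert_array_equal(vec.values.to_numpy(), [0.0, 0.0])

    def test_hand_arithmetic(self):
        geno = make_genotypes([[0, 2], [1, 1]])
        ss = make_sumstats(geno, [0.1, -0.2], [0.5, 0.5])
        vec = score(geno, ss)
        np.testing.assert_allclose(vec.values.to_numpy(), [-0.4, -0.1])

    def test_p_threshold_boundary_contributions(self):
        """Tightening the threshold below 1 removes exactly the p = 1 SNPs'
        contributions (verified by recomputing the subset sum)."""
        rng = np.random.default_rng(7)
        D = rng.integers(0, 3, size=(30, 6)).astype(float)
        geno = make_genotypes(D)
        p = np.array([0.2, 1.0, 0.7, 1.0, 0.4, 0.9])
        beta = rng.normal(size=6)
        ss = make_sumstats(geno, beta, p)
        full = score(geno, ss, p_threshold=1.0).values.to_numpy()
        tight = score(geno, ss, p_threshold=0.999999).values.to_numpy()
        removed = D[:, p == 1.0] @ beta[p == 1.0]
        np.testing.assert_allclose(full - tight, removed, atol=1e-12)

    def test_missing_dosage_mean_imputed(self):
        D = np.array([[0.0, 2.0], [np.nan, 0.0], [2.0, 1.0]])
        geno = make_genotypes(D)
        ss = make_sumstats(geno, [1.0, 1.0], [0.5, 0.5])
        vec = score(geno, ss)
        assert vec.values.iloc[1] == pytest.approx(1.0 + 0.0)  # mean dosage 1

    def test_empty_retained_set_raises(self):
        geno = make_genotypes([[0], [1]])
        ss = make_sumstats(geno, [0.1], [0.5])
        with pytest.raises(ScoreError):
            score(geno, ss, retained=[])


class TestStandardise:
    def test_symmetric_case(self):
        geno = make_genotypes([[1], [2], [3]])
        ss = make_sumstats(geno, [1.0], [0.5])
        vec = standardise(score(geno, ss))
        np.testing.assert_allclose(vec.values.to_numpy(), [-1, 0, 1])
        assert vec.standardised

    def test_idempotent_and_moments(self):
        rng = np.random.default_rng(8)
        geno = make_genotypes(rng.integers(0, 3, size=(40, 3)).astype(float))
        ss = make_sumstats(geno, rng.normal(size=3), [0.5] * 3)
        once = standardise(score(geno, ss))
        twice = standardise(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )
        assert abs(once.values.mean()) < 1e-10
        assert abs(once.values.var(ddof=1) - 1.0) < 1e-10

    def test_zero_variance_raises(self):
        geno = make_genotypes([[1], [1], [1]])
        ss = make_sumstats(geno, [1.0], [0.5])
        with pytest.raises(ScoreError):
            standardise(score(geno, ss))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=3, max_size=30)
    )
    def test_moments_for_arbitrary_scores(self, vals):
        from tsopgs.pgs import PGSVector

        x = np.asarray(vals)
        if x.std(ddof=1) < 1e-8:
            return
        vec = PGSVector(values=pd.Series(x), standardised=False)
        out = standardise(vec)
        assert abs(out.values.mean()) < 1e-10
        assert abs(out.values.var(ddof=1) - 1.0) < 1e-8


class TestEndToEnd:
    def test_recovers_true_genetic_value_without_noise(self):
        """Zero sumstats noise, no LD: the standardised score is the
        standardised true genetic value (r > 0.99)."""
        cfg = SimConfig(n_individuals=2000, n_snps=150, ld_rho=0.0,
                        ambiguous_fraction=0.0, seed=9)
        geno = simulate_genotypes(cfg)
        w = np.random.default_rng(10).normal(0, 0.1, 150)
        ss = simulate_sumstats(geno, w, np.inf, seed=11)
        vec, report = compute_pgs(geno, ss)
        true_value = geno.dosages @ w
        r = np.corrcoef(vec.values.to_numpy(), true_value)[0, 1]
        assert r > 0.99

    def test_invariance_to_joint_allele_flips(self):
        """Recoding SNPs to the other allele in both the panel and the
        sumstats leaves the standardised score unchanged."""
        cfg = SimConfig(n_individuals=300, n_snps=60, ambiguous_fraction=0.0, seed=12)
        geno = simulate_genotypes(cfg)
        w = np.random.default_rng(13).normal(0, 0.1, 60)
        ss = simulate_sumstats(geno, w, np.inf, seed=14)
        base, _ = compute_pgs(geno, ss)

        flip = np.random.default_rng(15).random(60) < 0.5
        dos = geno.dosages.astype(float).copy()
        dos[:, flip] = 2 - dos[:, flip]
        snps = geno.snps.copy()
        snps.loc[flip, ["a1", "a2"]] = snps.loc[flip, ["a2", "a1"]].to_numpy()
        snps.loc[flip, "maf"] = 1 - snps.loc[flip, "maf"]
        geno_f = GenotypeMatrix(dosages=dos, snps=snps, ids=geno.ids)
        ss_f = ss.copy()
        in_flip = ss_f["snp"].isin(snps.loc[flip, "snp"])
        ss_f.loc[in_flip, ["a1", "a2"]] = ss_f.loc[in_flip, ["a2", "a1"]].to_numpy()
        ss_f.loc[in_flip, "beta"] = -ss_f.loc[in_flip, "beta"]
        flipped, _ = compute_pgs(geno_f, ss_f)
        np.testing.assert_allclose(
            base.values.to_numpy(), flipped.values.to_numpy(), atol=1e-10
        )
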