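"""Synthetic genotypes, GWAS summary statistics and longitudinal
substance-use phenotypes with a known latent ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* LD-blocked biallelic genotypes — within a block, haplotypes follow a
  first-order autocorrelation through a Gaussian-threshold copula, so
  adjacent-SNP r^2 is tunable for clumping tests; blocks are mutually
  independent and physically separated by more than the clumping window.
* Noisy summary statistics — the reported effect is the true per-allele
  effect plus Gaussian estimation noise with the standard error implied
  by a finite discovery-sample size, and a configurable fraction of rows
  has alleles swapped (sign-flipped) to exercise harmonisation.
* Phenotypes from a trait-state-occasion structure — a common liability
  factor, four substance-specific factors and three occasion factors,
  all unit-variance and mutually orthogonal, with polygenic scores (and
  optionally sex) shifting the trait factors; continuous indicators are
  mapped onto bounded count scales (FTND 0-10, AUDIT 0-40, CAST 0-24,
  illicit-substance count 0-15) by rank-preserving quantile
  discretisation onto a right-skewed truncated negative-binomial
  marginal.

Every simulated study carries a truth record (latent factor values, true
polygenic scores, loadings and structural coefficients) for
parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .tso.spec import DEFAULT_OCCASIONS, DEFAULT_SUBSTANCES


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


# defaults chosen so the implied per-indicator variance shares average to
# the decomposition a common-liability model of this kind reports:
# 22% common, 34% specific, ~19% occasion, ~25% residual.  Loadings vary
# across indicators so the common-factor direction is not collinear with
# the sum of the specific-factor directions.
DEFAULT_LAM_COMMON = np.array(
    [0.92, 1.02, 1.12, 1.22, 1.02, 0.81, 1.12, 1.22, 1.02, 0.92, 1.32, 1.12]
)
DEFAULT_LAM_SPECIFIC = np.array(
    [1.52, 1.32, 1.22, 1.12, 1.42, 1.52, 1.32, 1.12, 1.52, 1.42, 1.22, 1.32]
)
DEFAULT_RESIDUAL_SD = np.full(12, 1.15)
DEFAULT_COUNT_MAX = (10, 40, 24, 15)  # FTND, AUDIT, CAST, illicit count

_BASES = ("A", "C", "G", "T")
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_INTRA_BLOCK_BP = 1_000
_INTER_BLOCK_GAP_BP = 500_000  # > the 250 kb clumping window


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele dosage matrix with SNP metadata."""

    dosages: np.ndarray               # n x m, values in {0,1,2}
    snps: pd.DataFrame                # snp, chr, bp, a1, a2, maf
    ids: list[str]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class SimConfig:
    """Study conditions for a simulated common-liability analysis."""

    n_individuals: int = 2000
    n_snps: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.6
    discovery_n: float = 50_000
    n_traits: int = 3
    true_weights: np.ndarray | None = None        # n_traits x n_snps
    pgs_effects: np.ndarray | None = None         # n_traits x 5 factors
    sex_effects: np.ndarray | None = None         # per-factor sex effect
    lam_common: np.ndarray = field(
        default_factory=lambda: DEFAULT_LAM_COMMON.copy()
    )
    lam_specific: np.ndarray = field(
        default_factory=lambda: DEFAULT_LAM_SPECIFIC.copy()
    )
    residual_sds: np.ndarray = field(
        default_factory=lambda: DEFAULT_RESIDUAL_SD.copy()
    )
    missing_rate: float | np.ndarray = 0.1
    missing_mechanism: Literal["mcar", "mar_covariate"] = "mcar"
    count_max: tuple[int, ...] = DEFAULT_COUNT_MAX
    discretise: bool = True
    flip_fraction: float = 0.05
    ambiguous_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ConfigError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError("ld_rho must lie in [0, 1)")
        if self.ld_block_size <= 0 or self.ld_block_size > 200:
            raise ConfigError("ld_block_size must be in 1..200")
        self.lam_common = np.asarray(self.lam_common, float)
        self.lam_specific = np.asarray(self.lam_specific, float)
        self.residual_sds = np.asarray(self.residual_sds, float)
        for name in ("lam_common", "lam_specific", "residual_sds"):
            if getattr(self, name).shape != (12,):
                raise ConfigError(f"{name} must have 12 entries (4 substances x 3 occasions)")
        if np.any(self.residual_sds <= 0):
            raise ConfigError("residual_sds must be positive")
        rates = np.broadcast_to(np.asarray(self.missing_rate, float), (12,))
        if np.any(rates < 0) or np.any(rates >= 1):
            raise ConfigError("missing rates must lie in [0, 1)")
        if self.pgs_effects is not None:
            self.pgs_effects = np.atleast_2d(np.asarray(self.pgs_effects, float))
            if self.pgs_effects.shape != (self.n_traits, 5):
                raise ConfigError(
                    "pgs_effects must be n_traits x 5 (common + 4 specific factors)"
                )

    @property
    def indicator_names(self) -> list[str]:
        return [f"{s}_{t}" for s in DEFAULT_SUBSTANCES for t in DEFAULT_OCCASIONS]


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    sumstats: list[pd.DataFrame]
    phenotypes: pd.DataFrame
    truth: dict


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------
def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw an LD-blocked dosage matrix in Hardy-Weinberg proportions.

    Each haplotype is a thresholded first-order autoregressive Gaussian
    within a block (correlation ``ld_rho``), so dosages of adjacent SNPs
    are positively correlated while blocks are independent.  Physical
    positions place a whole block inside the clumping window and
    consecutive blocks well outside it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m, L = config.n_individuals, config.n_snps, config.ld_block_size
    rho = config.ld_rho
    maf = rng.uniform(*config.maf_range, size=m)
    thresh = stats.norm.ppf(maf)

    def haplotypes() -> np.ndarray:
        lat = np.empty((n, m))
        for start in range(0, m, L):
            stop = min(start + L, m)
            z = rng.standard_normal((n, stop - start))
            lat[:, start] = z[:, 0]
            for j in range(1, stop - start):
                lat[:, start + j] = (
                    rho * lat[:, start + j - 1] + np.sqrt(1 - rho**2) * z[:, j]
                )
        return (lat < thresh).astype(np.int8)

    dosages = (haplotypes() + haplotypes()).astype(np.int8)

    # positions: intra-block 1 kb spacing, >250 kb between blocks
    bp = np.empty(m, dtype=np.int64)
    pos = 1
    for start in range(0, m, L):
        stop = min(start + L, m)
        bp[start:stop] = pos + _INTRA_BLOCK_BP * np.arange(stop - start)
        pos = int(bp[stop - 1]) + _INTER_BLOCK_GAP_BP

    n_amb = rng.random(m) < config.ambiguous_fraction
    a1 = np.empty(m, dtype="U1")
    a2 = np.empty(m, dtype="U1")
    for j in range(m):
        if n_amb[j]:
            pair = ("A", "T") if rng.random() < 0.5 else ("C", "G")
        else:
            while True:
                pair = tuple(rng.choice(_BASES, size=2, replace=False))
                if frozenset(pair) not in _AMBIGUOUS:
                    break
        if rng.random() < 0.5:
            pair = (pair[1], pair[0])
        a1[j], a2[j] = pair

    snps = pd.DataFrame(
        {
            "snp": [f"rs{j + 1}" for j in range(m)],
            "chr": "1",
            "bp": bp,
            "a1": a1,
            "a2": a2,
            "maf": maf,
        }
    )
    ids = [f"id{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, snps=snps, ids=ids)


# ----------------------------------------------------------------------
# summary statistics
# ----------------------------------------------------------------------
def simulate_sumstats(
    genotypes: GenotypeMatrix,
    true_weights: np.ndarray,
    discovery_n: float,
    seed: int | np.random.Generator = 0,
    flip_fraction: float = 0.0,
) -> pd.DataFrame:
    """GWAS-style per-SNP effects with finite-sample estimation noise.

    The reported beta is the true per-allele effect plus N(0, se^2)
    noise with se = 1 / sqrt(N * 2 f (1 - f)) — the standard error of a
    marginal regression slope on a standardised outcome.  The p-value is
    the two-sided Wald p of the reported beta.  ``discovery_n = inf``
    gives the zero-noise limit.  A ``flip_fraction`` of rows has alleles
    swapped with the beta sign flipped accordingly.
    """
    w = np.asarray(true_weights, float)
    if w.shape != (genotypes.n_snps,):
        raise ConfigError("true_weights length must equal n_snps")
    if not np.isinf(discovery_n) and discovery_n < 2:
        raise ConfigError("discovery_n must be >= 2 (or inf for the noise-free limit)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = genotypes.snps["maf"].to_numpy()
    if np.isinf(discovery_n):
        se = np.zeros_like(f)
        beta = w.copy()
        p = np.where(beta != 0.0, np.finfo(float).tiny, 1.0)
    else:
        se = 1.0 / np.sqrt(discovery_n * 2.0 * f * (1.0 - f))
        beta = w + rng.normal(0.0, se)
        z = beta / se
        # 2*Phi(-|z|) in log space to keep tiny p-values positive
        p = np.exp(np.log(2.0) + stats.norm.logsf(np.abs(z)))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = genotypes.snps[["snp", "chr", "bp", "a1", "a2"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    if flip_fraction > 0:
        flip = rng.random(len(out)) < flip_fraction
        out.loc[flip, ["a1", "a2"]] = out.loc[flip, ["a2", "a1"]].to_numpy()
        out.loc[flip, "beta"] = -out.loc[flip, "beta"]
        out.attrs["flipped"] = flip
    else:
        out.attrs["flipped"] = np.zeros(len(out), bool)
    return out


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
def _standardise_cols(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return (x - mu) / np.where(sd > 0, sd, 1.0)


def _discretise(y: np.ndarray, count_max: int) -> np.ndarray:
    """Rank-preserving quantile map onto a truncated negative binomial.

    The target marginal is right-skewed (most scores at or near zero,
    a thin upper tail), mimicking bounded screening-instrument totals.
    """
    r, mean = 1.2, 0.15 * count_max
    q = r / (r + mean)
    k = np.arange(count_max + 1)
    pmf = stats.nbinom.pmf(k, r, q)
    cdf = np.cumsum(pmf / pmf.sum())
    u = (stats.rankdata(y, method="average") - 0.5) / y.size
    return np.searchsorted(cdf, u, side="left").clip(0, count_max).astype(float)


def simulate_phenotypes(
    genotypes: GenotypeMatrix | None,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Longitudinal substance-use scores from the TSO latent structure.

    The common factor is ``sum_j b_j PGS_j + b_sex sex + residual``
    with the residual scaled so the factor variance is 1; specific and
    occasion factors likewise.  Indicators are
    ``lam_c C + lam_s S_k + O_t + resid_sd eps`` and, when
    ``config.discretise`` is set, rank-mapped onto the bounded count
    scales.  Returns the phenotype table (no missingness yet) and the
    ground-truth record.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_individuals

    # true polygenic scores (standardised genetic values)
    if config.pgs_effects is not None:
        if genotypes is None:
            raise ConfigError("pgs_effects given but no genotypes to score")
        if config.true_weights is None:
            raise ConfigError("pgs_effects given but true_weights missing")
        gvals = genotypes.dosages @ np.asarray(config.true_weights, float).T
        pgs_true = _standardise_cols(gvals)
        b = config.pgs_effects
    else:
        pgs_true = np.zeros((n, 0))
        b = np.zeros((0, 5))

    sex = (rng.random(n) < 0.5).astype(float)
    sex_std = (sex - sex.mean()) / max(sex.std(ddof=1), 1e-12)
    pcs = rng.standard_normal((n, 10))
    b_sex = np.zeros(5) if config.sex_effects is None else np.asarray(
        config.sex_effects, float
    )

    factors = np.empty((n, 5))
    for f_idx in range(5):
        systematic = pgs_true @ b[:, f_idx] + b_sex[f_idx] * sex_std
        v = systematic.var()
        if v > 1.0 - 1e-9:
            raise ConfigError(
                f"structural effects imply factor variance > 1 for factor {f_idx} "
                "(residual variance would be negative)"
            )
        factors[:, f_idx] = systematic + np.sqrt(1.0 - v) * rng.standard_normal(n)
    C = factors[:, 0]
    S = factors[:, 1:]
    O = rng.standard_normal((n, 3))

    names = config.indicator_names
    y = np.empty((n, 12))
    for k in range(4):
        for t in range(3):
            i = k * 3 + t
            y[:, i] = (
                config.lam_common[i] * C
                + config.lam_specific[i] * S[:, k]
                + O[:, t]
                + config.residual_sds[i] * rng.standard_normal(n)
            )
    y_cont = y.copy()
    if config.discretise:
        for k in range(4):
            for t in range(3):
                i = k * 3 + t
                y[:, i] = _discretise(y[:, i], config.count_max[k])

    ids = genotypes.ids if genotypes is not None else [f"id{i:06d}" for i in range(n)]
    phen = pd.DataFrame({"id": ids, "sex": sex})
    for j in range(10):
        phen[f"pc{j + 1}"] = pcs[:, j]
    for i, name in enumerate(names):
        phen[name] = y[:, i]

    truth = {
        "seed": config.seed,
        "lam_common": config.lam_common.tolist(),
        "lam_specific": config.lam_specific.tolist(),
        "residual_sds": config.residual_sds.tolist(),
        "pgs_effects": b.tolist(),
        "sex_effects": b_sex.tolist(),
        "count_max": list(config.count_max),
        "pgs_true": pgs_true,
        "common": C,
        "specific": S,
        "occasion": O,
        "y_continuous": y_cont,
    }
    return phen, truth


# ----------------------------------------------------------------------
# missingness
# ----------------------------------------------------------------------
def inject_missingness(
    phenotypes: pd.DataFrame,
    missing_rate: float | Sequence[float],
    mechanism: Literal["mcar", "mar_covariate"] = "mcar",
    seed: int | np.random.Generator = 0,
    covariate: str = "sex",
    mar_strength: float = 1.0,
    indicator_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Set indicator cells missing; drop rows with no indicator left.

    ``mcar`` blanks each cell independently at its rate; ``mar_covariate``
    makes the missingness probability logistic in the (standardised)
    covariate with slope ``mar_strength``, the intercept solved so the
    marginal rate matches the requested one.  Covariates are never
    blanked.
    """
    if indicator_cols is None:
        indicator_cols = [
            f"{s}_{t}" for s in DEFAULT_SUBSTANCES for t in DEFAULT_OCCASIONS
        ]
    rates = np.broadcast_to(
        np.asarray(missing_rate, float), (len(indicator_cols),)
    )
    if np.any(rates < 0) or np.any(rates >= 1):
        raise ConfigError("missing rates must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = phenotypes.copy()
    n = len(out)
    if mechanism == "mcar":
        probs = np.broadcast_to(rates, (n, len(indicator_cols)))
    elif mechanism == "mar_covariate":
        x = out[covariate].to_numpy(float)
        x_std = (x - x.mean()) / max(x.std(ddof=1), 1e-12)
        cols = []
        for rate in rates:
            if rate == 0.0:
                cols.append(np.zeros(n))
                continue
            # intercept such that mean expit(a + g x) == rate
            def gap(a: float) -> float:
                return special.expit(a + mar_strength * x_std).mean() - rate
            a = optimize.brentq(gap, -30.0, 30.0)
            cols.append(special.expit(a + mar_strength * x_std))
        probs = np.column_stack(cols)
    else:
        raise ConfigError(f"unknown missingness mechanism {mechanism!r}")
    mask = rng.random((n, len(indicator_cols))) < probs
    vals = out[list(indicator_cols)].to_numpy(float)
    vals[mask] = np.nan
    out[list(indicator_cols)] = vals
    all_missing = np.isnan(vals).all(axis=1)
    out = out.loc[~all_missing].reset_index(drop=True)
    out.attrs["n_dropped_all_missing"] = int(all_missing.sum())
    return out


# ----------------------------------------------------------------------
# whole study
# ----------------------------------------------------------------------
def default_true_weights(
    n_traits: int, n_snps: int, rng: np.random.Generator
) -> np.ndarray:
    """Sparse per-SNP effects: each trait draws effects on half the panel."""
    w = np.zeros((n_traits, n_snps))
    for j in range(n_traits):
        causal = rng.random(n_snps) < 0.5
        w[j, causal] = rng.normal(0.0, 0.05, causal.sum())
    return w


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the whole generator: genotypes, per-trait summary statistics,
    phenotypes with the configured latent structure, and missingness."""
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(4)
    rng_geno = np.random.default_rng(seeds[0])
    rng_sum = np.random.default_rng(seeds[1])
    rng_phen = np.random.default_rng(seeds[2])
    rng_miss = np.random.default_rng(seeds[3])

    genotypes = simulate_genotypes(config, rng_geno)
    if config.true_weights is None:
        config.true_weights = default_true_weights(
            config.n_traits, config.n_snps, rng_sum
        )
    sumstats = [
        simulate_sumstats(
            genotypes,
            config.true_weights[j],
            config.discovery_n,
            rng_sum,
            flip_fraction=config.flip_fraction,
        )
        for j in range(config.n_traits)
    ]
    phen, truth = simulate_phenotypes(genotypes, config, rng_phen)
    phen = inject_missingness(
        phen,
        config.missing_rate,
        config.missing_mechanism,
        rng_miss,
    )
    truth["true_weights"] = np.asarray(config.true_weights).tolist()
    return SimulatedStudy(
        genotypes=genotypes, sumstats=sumstats, phenotypes=phen, truth=truth
    )
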