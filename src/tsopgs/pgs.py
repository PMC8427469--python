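"""Polygenic scoring: harmonisation of GWAS summary statistics to a
genotype panel, greedy LD clumping, weighted allele-dosage scoring at a
p-value threshold of 1, and standardisation.

The score for individual *i* is the sum over retained SNPs of the
GWAS effect size times the effect-allele dosage.  Clumping removes, in
ascending p-value order, every SNP within the physical window whose
squared dosage correlation with a better SNP exceeds the r^2 threshold —
keeping one representative per LD region so correlated SNPs are not
double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import GenotypeMatrix

SUMSTATS_COLUMNS = ("snp", "chr", "bp", "a1", "a2", "beta", "p")
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

DEFAULT_R2_THRESHOLD = 0.10
DEFAULT_WINDOW_KB = 250.0
DEFAULT_P_THRESHOLD = 1.0


class HarmonisationError(ValueError):
    """Raised when sumstats and panel share no usable SNPs."""


class ScoreError(ValueError):
    """Raised for empty or degenerate polygenic scores."""


class UndefinedLDError(ValueError):
    """Raised when an LD correlation involves a zero-variance SNP."""


@dataclass
class PGSVector:
    """Per-individual polygenic score with provenance."""

    values: pd.Series                  # indexed by individual id
    standardised: bool
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


def validate_sumstats(sumstats: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUMSTATS_COLUMNS if c not in sumstats.columns]
    if missing:
        raise ValueError(f"sumstats missing columns {missing}")
    if sumstats["snp"].duplicated().any():
        raise ValueError("duplicate SNP ids in sumstats")
    p = sumstats["p"].to_numpy(float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return sumstats


# ----------------------------------------------------------------------
# harmonisation
# ----------------------------------------------------------------------
def harmonise(
    sumstats: pd.DataFrame, snp_meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Align summary statistics to the genotype panel's allele coding.

    SNPs absent from the panel are dropped; rows whose effect allele is
    the panel's alternate allele have the beta sign flipped and alleles
    swapped; strand-ambiguous SNPs (A/T, C/G) are dropped.  Returns the
    harmonised table (panel SNP order) and a report with counts.
    """
    validate_sumstats(sumstats)
    panel = snp_meta.set_index("snp")
    ss = sumstats.set_index("snp")
    common = [s for s in panel.index if s in ss.index]
    if not common:
        raise HarmonisationError("no overlapping SNPs between sumstats and panel")
    n_absent = len(ss) - len(common)
    rows = []
    n_flipped = n_ambiguous = n_mismatch = 0
    for snp in common:
        s = ss.loc[snp]
        pa1, pa2 = panel.at[snp, "a1"], panel.at[snp, "a2"]
        if frozenset((s["a1"], s["a2"])) in _AMBIGUOUS:
            n_ambiguous += 1
            continue
        if (s["a1"], s["a2"]) == (pa1, pa2):
            rows.append((snp, s["chr"], s["bp"], pa1, pa2, s["beta"], s["p"]))
        elif (s["a1"], s["a2"]) == (pa2, pa1):
            n_flipped += 1
            rows.append((snp, s["chr"], s["bp"], pa1, pa2, -s["beta"], s["p"]))
        else:
            n_mismatch += 1
    if not rows:
        raise HarmonisationError("no usable SNPs after harmonisation")
    out = pd.DataFrame(rows, columns=["snp", "chr", "bp", "a1", "a2", "beta", "p"])
    report = {
        "n_input": int(len(sumstats)),
        "n_matched": int(len(out)),
        "n_flipped": int(n_flipped),
        "n_ambiguous_dropped": int(n_ambiguous),
        "n_allele_mismatch_dropped": int(n_mismatch),
        "n_absent_from_panel": int(n_absent),
    }
    return out, report


# ----------------------------------------------------------------------
# LD
# ----------------------------------------------------------------------
def ld_r2(genotypes: GenotypeMatrix, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of two SNPs' dosage vectors."""
    idx = pd.Index(genotypes.snps["snp"])
    try:
        i = idx.get_loc(snp_i)
        j = idx.get_loc(snp_j)
    except KeyError as e:
        raise KeyError(f"SNP not in panel: {e}") from e
    x = genotypes.dosages[:, i].astype(float)
    y = genotypes.dosages[:, j].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedLDError(
            f"zero dosage variance for {snp_i if x.std() == 0 else snp_j}"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ----------------------------------------------------------------------
# clumping
# ----------------------------------------------------------------------
def clump(
    sumstats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> list[str]:
    """Greedy LD clumping; returns the retained (index) SNP ids.

    SNPs are visited in ascending p-value order (ties broken by position
    then id).  Each index SNP removes all not-yet-visited SNPs on the
    same chromosome within ``window_kb`` kilobases whose dosage r^2 with
    it exceeds ``r2_threshold``.
    """
    meta = genotypes.snps
    pos_of = {s: k for k, s in enumerate(meta["snp"])}
    tab = sumstats[["snp", "chr", "bp", "p"]].copy()
    tab = tab.sort_values(["p", "bp", "snp"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000.0
    D = genotypes.dosages.astype(float)
    sd = D.std(axis=0)
    removed: set[str] = set()
    retained: list[str] = []
    snp_arr = tab["snp"].to_numpy()
    chr_arr = tab["chr"].to_numpy()
    bp_arr = tab["bp"].to_numpy(float)
    for i in range(len(tab)):
        s = snp_arr[i]
        if s in removed:
            continue
        retained.append(s)
        near = np.flatnonzero(
            (chr_arr == chr_arr[i]) & (np.abs(bp_arr - bp_arr[i]) <= window_bp)
        )
        if near.size <= 1:
            continue
        gi = pos_of[s]
        xi = D[:, gi]
        xi_c = xi - xi.mean()
        for j in near:
            t = snp_arr[j]
            if t == s or t in removed:
                continue
            gj = pos_of[t]
            if sd[gi] == 0 or sd[gj] == 0:
                raise UndefinedLDError(f"zero dosage variance at {s} or {t}")
            yj = D[:, gj]
            r = float(xi_c @ (yj - yj.mean())) / (len(xi) * sd[gi] * sd[gj])
            if r * r > r2_threshold:
                removed.add(t)
    return retained


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------
def score(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    retained: list[str] | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    sumstats_id: str = "",
    r2_threshold: float | None = None,
    window_kb: float | None = None,
) -> PGSVector:
    """Weighted allele-dosage sum over retained SNPs with p <= threshold.

    Missing dosages (NaN) contribute the SNP's mean dosage.  Raises
    ScoreError when the retained set (after thresholding) is empty.
    """
    if retained is None:
        retained = list(sumstats["snp"])
    ss = sumstats.set_index("snp")
    use = [s for s in retained if ss.at[s, "p"] <= p_threshold]
    if not use:
        raise ScoreError("no SNPs retained at the requested p threshold")
    pos_of = {s: k for k, s in enumerate(genotypes.snps["snp"])}
    cols = [pos_of[s] for s in use]
    D = genotypes.dosages[:, cols].astype(float)
    if np.isnan(D).any():
        means = np.nanmean(D, axis=0)
        nan_r, nan_c = np.where(np.isnan(D))
        D[nan_r, nan_c] = means[nan_c]
    betas = ss.loc[use, "beta"].to_numpy(float)
    vals = D @ betas
    return PGSVector(
        values=pd.Series(vals, index=pd.Index(genotypes.ids, name="id")),
        standardised=False,
        provenance={
            "sumstats_id": sumstats_id,
            "n_snps_used": len(use),
            "r2_threshold": r2_threshold,
            "window_kb": window_kb,
            "p_threshold": p_threshold,
        },
    )


def standardise(pgs: PGSVector) -> PGSVector:
    """Zero-mean unit-variance rescaling (n-1 denominator)."""
    x = pgs.values.to_numpy(float)
    if x.size < 2:
        raise ScoreError("standardisation needs at least two individuals")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ScoreError("degenerate score: zero variance")
    vals = (x - x.mean()) / sd
    return PGSVector(
        values=pd.Series(vals, index=pgs.values.index),
        standardised=True,
        provenance=dict(pgs.provenance),
    )


def compute_pgs(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_kb: float = DEFAULT_WINDOW_KB,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    sumstats_id: str = "",
) -> tuple[PGSVector, dict]:
    """Harmonise, clump, score and standardise in one call."""
    harmonised, report = harmonise(sumstats, genotypes.snps)
    retained = clump(harmonised, genotypes, r2_threshold, window_kb)
    raw = score(
        genotypes, harmonised, retained, p_threshold,
        sumstats_id=sumstats_id, r2_threshold=r2_threshold, window_kb=window_kb,
    )
    report = dict(report)
    report["n_retained_after_clumping"] = len(retained)
    report["n_snps_scored"] = raw.provenance["n_snps_used"]
    return standardise(raw), report
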