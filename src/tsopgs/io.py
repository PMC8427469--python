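"""Readers and writers for the pipeline's text formats.

Formats: genotype dosage TSV (rows = individuals, columns = SNPs) with a
SNP metadata TSV; optional VCF export with a DS (dosage) FORMAT field;
GWAS summary-statistics TSV (SNP/CHR/BP/A1/A2/BETA/SE/P); wide phenotype
CSV with an empty cell as the missing-value convention; JSON ground-truth
and report documents.  Malformed rows are rejected with line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import GenotypeMatrix

_VALID_BASES = {"A", "C", "G", "T"}


class ParseError(ValueError):
    """Input file violates the declared dialect; message carries locations."""


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------
def write_genotypes(
    genotypes: GenotypeMatrix, dosage_path: str | Path, meta_path: str | Path
) -> None:
    dosage = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.ids, name="id"),
        columns=genotypes.snps["snp"],
    )
    dosage.to_csv(dosage_path, sep="\t")
    meta = genotypes.snps.copy()
    meta.columns = [c.upper() for c in meta.columns]
    meta.to_csv(meta_path, sep="\t", index=False)


def read_genotypes(
    dosage_path: str | Path, meta_path: str | Path
) -> GenotypeMatrix:
    dosage = pd.read_csv(dosage_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"CHR": str})
    need = {"SNP", "CHR", "BP", "A1", "A2"}
    if not need.issubset(meta.columns):
        raise ParseError(
            f"{meta_path}: SNP metadata must have columns {sorted(need)}"
        )
    meta.columns = [c.lower() for c in meta.columns]
    bad = [
        str(i + 2)
        for i, (x, y) in enumerate(zip(meta["a1"], meta["a2"]))
        if x not in _VALID_BASES or y not in _VALID_BASES or x == y
    ]
    if bad:
        raise ParseError(f"{meta_path}: invalid allele codes at lines {bad}")
    vals = dosage.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        col = dosage.columns[
            [not np.issubdtype(dosage[c].dtype, np.number) for c in dosage.columns]
        ][0]
        raise ParseError(f"{dosage_path}: non-numeric dosage in column {col!r}")
    if list(dosage.columns) != list(meta["snp"]):
        raise ParseError("dosage columns and SNP metadata disagree")
    if "maf" not in meta.columns:
        meta["maf"] = np.nanmean(vals, axis=0) / 2.0
    return GenotypeMatrix(
        dosages=vals.astype(float),
        snps=meta[["snp", "chr", "bp", "a1", "a2", "maf"]].reset_index(drop=True),
        ids=[str(i) for i in dosage.index],
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 export with per-sample DS (dosage) fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,'
            'Description="Effect-allele dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.ids)
            + "\n"
        )
        snps = genotypes.snps
        for j in range(genotypes.n_snps):
            row = snps.iloc[j]
            ds = "\t".join(f"{d:g}" for d in genotypes.dosages[:, j])
            # REF = other allele, ALT = effect allele; DS counts ALT copies
            fh.write(
                f"{row['chr']}\t{row['bp']}\t{row['snp']}\t{row['a2']}\t"
                f"{row['a1']}\t.\t.\t.\tDS\t{ds}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a dosage VCF (DS FORMAT field) into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows = []
    dosages = []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ParseError(f"{path}: variant {var.ID} lacks a DS field")
        dosages.append(np.asarray(ds, float).ravel())
        rows.append((var.ID, str(var.CHROM), var.POS, var.ALT[0], var.REF))
    snps = pd.DataFrame(rows, columns=["snp", "chr", "bp", "a1", "a2"])
    D = np.column_stack(dosages) if dosages else np.empty((len(ids), 0))
    snps["maf"] = D.mean(axis=0) / 2.0 if len(rows) else []
    return GenotypeMatrix(dosages=D, snps=snps, ids=ids)


# ----------------------------------------------------------------------
# summary statistics
# ----------------------------------------------------------------------
def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    out = sumstats.copy()
    out.columns = [c.upper() for c in out.columns]
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    need = {"SNP", "CHR", "BP", "A1", "A2", "BETA", "P"}
    if not need.issubset(tab.columns):
        raise ParseError(f"{path}: sumstats must have columns {sorted(need)}")
    tab.columns = [c.lower() for c in tab.columns]
    bad = [
        str(i + 2)
        for i, (x, y) in enumerate(zip(tab["a1"], tab["a2"]))
        if x not in _VALID_BASES or y not in _VALID_BASES
    ]
    if bad:
        raise ParseError(f"{path}: allele code outside A/C/G/T at lines {bad}")
    p = tab["p"].to_numpy(float)
    bad = [str(i + 2) for i in np.flatnonzero((p <= 0) | (p > 1))]
    if bad:
        raise ParseError(f"{path}: p-values outside (0, 1] at lines {bad}")
    return tab


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index=False, na_rep="")


def read_phenotypes(
    path: str | Path, indicator_cols: list[str] | None = None
) -> pd.DataFrame:
    tab = pd.read_csv(path)
    if "id" not in tab.columns:
        raise ParseError(f"{path}: phenotype CSV must have an 'id' column")
    if indicator_cols is None:
        reserved = {"id", "sex"} | {f"pc{i}" for i in range(1, 11)}
        indicator_cols = [c for c in tab.columns if c not in reserved]
    missing = [c for c in indicator_cols if c not in tab.columns]
    if missing:
        raise ParseError(f"{path}: missing indicator columns {missing}")
    vals = tab[indicator_cols].to_numpy(float)
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        dropped = tab.loc[all_missing, "id"].tolist()
        tab = tab.loc[~all_missing].reset_index(drop=True)
        tab.attrs["dropped_all_missing_ids"] = dropped
    tab.attrs["n_dropped_all_missing"] = int(all_missing.sum())
    return tab


# ----------------------------------------------------------------------
# scores, truth, reports
# ----------------------------------------------------------------------
def write_pgs(values: pd.Series, path: str | Path) -> None:
    frame = values.rename("score").rename_axis("id").reset_index()
    frame.to_csv(path, index=False)


def read_pgs(path: str | Path) -> pd.Series:
    tab = pd.read_csv(path)
    if not {"id", "score"}.issubset(tab.columns):
        raise ParseError(f"{path}: PGS CSV must have columns id, score")
    return tab.set_index("id")["score"]


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_truth(truth: dict, path: str | Path) -> None:
    """Persist the scalar/parameter part of a truth record as JSON.

    Per-individual arrays (latent factor values, true scores, continuous
    indicators) are summarised by their dimensions only.
    """
    slim = {}
    for key, val in truth.items():
        arr = np.asarray(val)
        if arr.ndim and arr.size > 200:
            slim[f"{key}_shape"] = list(arr.shape)
        else:
            slim[key] = val
    write_json(slim, path)
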