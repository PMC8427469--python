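"""Configuration-driven orchestration: simulate -> score -> fit ->
associate -> report, with per-stage seeding and a run manifest.

Every stage writes its outputs as plain-text files and appends a
manifest entry (stage, parameters, derived seed, output checksums), so
any stage can be re-run standalone on the files of the previous one.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import io as io_mod
from . import pgs as pgs_mod
from .synthdata import SimConfig, simulate_study
from .tso import (
    build_spec,
    fit,
    fit_indices,
    standardised_solution,
    variance_decomposition,
)

log = logging.getLogger("tsopgs")

DEFAULT_COVARIATES = ["sex"] + [f"pc{i}" for i in range(1, 11)]


class PipelineError(RuntimeError):
    """A stage failed; the manifest written so far is preserved."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    config = dict(config)
    has_sim = "simulate" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        raise PipelineError(
            "config must contain exactly one of 'simulate' or 'inputs'"
        )
    config.setdefault("seed", 0)
    config.setdefault("pgs", {})
    config.setdefault("assoc", {})
    return config


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the run manifest."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"seed": seed, "stages": []}

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": stage_seed(seed, stage),
                "params": params,
                "outputs": {p.name: _checksum(p) for p in outputs},
            }
        )
        io_mod.write_json(manifest, outdir / "manifest.json")

    try:
        # ------------------------------------------------ simulate / load
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            if "pgs_effects" in sim_kwargs and sim_kwargs["pgs_effects"] is not None:
                sim_kwargs["pgs_effects"] = np.asarray(
                    sim_kwargs["pgs_effects"], float
                )
            sim_cfg = SimConfig(seed=stage_seed(seed, "simulate"), **sim_kwargs)
            study = simulate_study(sim_cfg)
            geno, sumstats_list, phen = (
                study.genotypes, study.sumstats, study.phenotypes,
            )
            paths = {
                "dosage": outdir / "genotypes.tsv",
                "meta": outdir / "genotypes.snps.tsv",
                "phen": outdir / "phenotypes.csv",
                "truth": outdir / "truth.json",
            }
            io_mod.write_genotypes(geno, paths["dosage"], paths["meta"])
            io_mod.write_phenotypes(phen, paths["phen"])
            io_mod.write_truth(study.truth, paths["truth"])
            ss_paths = []
            for j, ss in enumerate(sumstats_list):
                path = outdir / f"sumstats_pgs{j + 1}.tsv"
                io_mod.write_sumstats(ss, path)
                ss_paths.append(path)
            record(
                "simulate",
                {k: v for k, v in config["simulate"].items()
                 if not isinstance(v, (list, np.ndarray))},
                list(paths.values()) + ss_paths,
            )
            truth = study.truth
        else:
            inputs = config["inputs"]
            geno = io_mod.read_genotypes(
                inputs["genotypes"], inputs["genotype_meta"]
            )
            sumstats_list = [io_mod.read_sumstats(p) for p in inputs["sumstats"]]
            phen = io_mod.read_phenotypes(inputs["phenotypes"])
            truth = None
            record("load", {"inputs": {k: str(v) for k, v in inputs.items()}}, [])

        # ------------------------------------------------------------ pgs
        pgs_cfg = config["pgs"]
        r2 = float(pgs_cfg.get("r2_threshold", pgs_mod.DEFAULT_R2_THRESHOLD))
        window = float(pgs_cfg.get("window_kb", pgs_mod.DEFAULT_WINDOW_KB))
        p_thr = float(pgs_cfg.get("p_threshold", pgs_mod.DEFAULT_P_THRESHOLD))
        pgs_frame = pd.DataFrame(index=pd.Index(geno.ids, name="id"))
        reports = {}
        pgs_paths = []
        for j, ss in enumerate(sumstats_list):
            name = f"pgs{j + 1}"
            vec, report = pgs_mod.compute_pgs(
                geno, ss, r2, window, p_thr, sumstats_id=name
            )
            pgs_frame[name] = vec.values
            reports[name] = report
            path = outdir / f"{name}.csv"
            io_mod.write_pgs(vec.values, path)
            pgs_paths.append(path)
        report_path = outdir / "pgs_report.json"
        io_mod.write_json(
            {"r2_threshold": r2, "window_kb": window, "p_threshold": p_thr,
             "per_pgs": reports},
            report_path,
        )
        record("pgs", {"r2": r2, "window_kb": window, "p_threshold": p_thr},
               pgs_paths + [report_path])

        # ------------------------------------------------------------ fit
        spec = build_spec(4, 3)
        data = phen.merge(pgs_frame, on="id", how="inner")
        baseline = fit(spec, data)
        indices = fit_indices(baseline)
        std = standardised_solution(baseline)
        decomp = variance_decomposition(baseline)
        params_path = outdir / "tso_parameters.tsv"
        std.to_csv(params_path, sep="\t", index=False)
        fitsum_path = outdir / "tso_fit.json"
        io_mod.write_json(
            {
                "loglik": baseline.loglik, "converged": baseline.converged,
                "n_used": baseline.n_used, "n_dropped": baseline.n_dropped,
                **indices.to_dict(),
            },
            fitsum_path,
        )
        decomp_path = outdir / "variance_decomposition.tsv"
        decomp.to_csv(decomp_path, sep="\t", index=False)
        io_mod.write_json(
            {"average_shares": decomp.attrs["average"]},
            outdir / "variance_decomposition.json",
        )
        record("fit", {"df": spec.df}, [params_path, fitsum_path, decomp_path])

        # ---------------------------------------------------------- assoc
        assoc_cfg = config["assoc"]
        alpha = float(assoc_cfg.get("alpha", 0.05))
        family = assoc_cfg.get("family", "per_factor")
        pgs_names = list(pgs_frame.columns)
        covariates = assoc_cfg.get("covariates", DEFAULT_COVARIATES)
        categories = assoc_cfg.get(
            "categories", {name: "trait" for name in pgs_names}
        )
        single = assoc_mod.run_single_pgs(data, spec, pgs_names, covariates, family)
        single_path = outdir / "assoc_single.tsv"
        single.to_csv(single_path, sep="\t", index=False)
        selected = assoc_mod.select_significant(single, alpha, categories)
        multi = assoc_mod.run_multi_pgs(data, spec, selected, covariates,
                                        family=family)
        multi_path = outdir / "assoc_multi.tsv"
        multi.to_csv(multi_path, sep="\t", index=False)
        io_mod.write_json(
            {"alpha": alpha, "family": family, "selected": selected,
             "categories": categories},
            outdir / "assoc_manifest.json",
        )
        record("assoc", {"alpha": alpha, "family": family},
               [single_path, multi_path])

        # --------------------------------------------------------- report
        report = _build_report(std, single, truth)
        report_path = outdir / "report.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        record("report", {}, [report_path])
    except PipelineError:
        raise
    except Exception as e:
        io_mod.write_json(manifest, outdir / "manifest.json")
        raise PipelineError(f"stage failed: {e}") from e
    return manifest


def _build_report(
    std: pd.DataFrame, single: pd.DataFrame, truth: dict | None
) -> pd.DataFrame:
    """Juxtapose estimates with simulated ground truth when available."""
    rows = []
    lam_c = truth.get("lam_common") if truth else None
    lam_s = truth.get("lam_specific") if truth else None
    b_true = np.asarray(truth["pgs_effects"]) if truth else None
    for i, row in std.iterrows():
        name = row["parameter"]
        true_val = np.nan
        if lam_c is not None and name.startswith("lam_c["):
            # raw-scale truth; standardised comparison happens in tests
            true_val = lam_c[_indicator_index(name)]
        elif lam_s is not None and name.startswith("lam_s["):
            true_val = lam_s[_indicator_index(name)]
        rows.append(
            {"parameter": name, "estimate_raw": row["raw"],
             "estimate_std": row["std"], "truth_raw": true_val}
        )
    out = pd.DataFrame(rows)
    if truth is not None and b_true is not None and len(b_true):
        factor_names = ["common", "spec_cig", "spec_alc", "spec_can", "spec_oth"]
        extra = []
        for _, r in single.iterrows():
            j = int(r["pgs"].replace("pgs", "")) - 1
            f_idx = factor_names.index(r["factor"])
            extra.append(
                {"parameter": f"b[{r['factor']}~{r['pgs']}]",
                 "estimate_raw": np.nan, "estimate_std": r["b_std"],
                 "truth_raw": b_true[j, f_idx] if j < len(b_true) else np.nan}
            )
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    return out


def _indicator_index(name: str) -> int:
    from .tso.spec import DEFAULT_OCCASIONS, DEFAULT_SUBSTANCES

    ind = name[name.index("[") + 1 : -1]
    names = [f"{s}_{t}" for s in DEFAULT_SUBSTANCES for t in DEFAULT_OCCASIONS]
    return names.index(ind)
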