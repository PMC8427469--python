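"""Single- and multi-PGS latent regressions with FDR-based selection.

Stage 1 (single-PGS): for each polygenic score, one TSO model in which
the common and all substance-specific factors are simultaneously
regressed on that score plus covariates (sex and 10 principal
components).  Wald p-values use sandwich robust standard errors;
Benjamini-Hochberg adjustment runs per factor across scores by default.

Stage 2 (multi-PGS): per factor, the scores surviving FDR are entered
jointly — split into a substance-use set and a trait/vulnerability set —
so each coefficient is adjusted for the genetic overlap among the
selected scores; the other factors are regressed on covariates only.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tso import ConvergenceError, TSOSpec, fit, standardised_solution

Z95 = float(stats.norm.ppf(0.975))


class CategoryError(ValueError):
    """A PGS has no declared substance/trait category."""


class CollinearityError(ValueError):
    """Selected scores are collinear beyond the condition threshold."""


class DegeneratePredictorError(ValueError):
    """A predictor is constant."""


# ----------------------------------------------------------------------
# Benjamini-Hochberg
# ----------------------------------------------------------------------
def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in the original
    order of the input.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def add_fdr(
    table: pd.DataFrame,
    family: Literal["per_factor", "global"] = "per_factor",
) -> pd.DataFrame:
    """Fill the p_fdr column, excluding non-converged rows from the family."""
    out = table.copy()
    out["p_fdr"] = np.nan
    ok = out["converged"] & out["p_raw"].notna()
    if family == "per_factor":
        for _, idx in out.loc[ok].groupby("factor").groups.items():
            out.loc[idx, "p_fdr"] = bh_fdr(out.loc[idx, "p_raw"].to_numpy())
    elif family == "global":
        idx = out.index[ok]
        out.loc[idx, "p_fdr"] = bh_fdr(out.loc[idx, "p_raw"].to_numpy())
    else:
        raise ValueError(f"unknown FDR family mode {family!r}")
    return out


# ----------------------------------------------------------------------
# model runners
# ----------------------------------------------------------------------
def _check_predictors(data: pd.DataFrame, cols: Sequence[str]) -> None:
    for c in cols:
        x = data[c].to_numpy(float)
        if np.isnan(x).any():
            raise DegeneratePredictorError(f"predictor {c!r} has missing values")
        if x.std() == 0:
            raise DegeneratePredictorError(f"predictor {c!r} is constant")


def _extract_rows(
    fitted_std: pd.DataFrame,
    fitted,
    pgs_names: Sequence[str],
    model_id: str,
    model_kind: str,
) -> list[dict]:
    """Pull (pgs, factor) coefficient rows out of a standardised solution."""
    names = fitted.param_names
    se_rob = fitted.se_robust
    raw = fitted.theta
    rows = []
    for i, name in enumerate(names):
        if not name.startswith("b["):
            continue
        inner = name[2:-1]
        factor, predictor = inner.split("~")
        if predictor not in pgs_names:
            continue
        b_std = float(fitted_std.loc[fitted_std.parameter == name, "std"].iloc[0])
        std_se = float(fitted_std.loc[fitted_std.parameter == name, "std_se"].iloc[0])
        z = raw[i] / se_rob[i] if se_rob[i] > 0 else np.nan
        p_raw = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        p_raw = min(max(p_raw, np.finfo(float).tiny), 1.0)
        rows.append(
            {
                "model": model_id,
                "model_kind": model_kind,
                "pgs": predictor,
                "factor": factor,
                "b_std": b_std,
                "ci_low": b_std - Z95 * std_se,
                "ci_high": b_std + Z95 * std_se,
                "se_robust": std_se,
                "p_raw": p_raw,
                "converged": True,
            }
        )
    return rows


def run_single_pgs(
    data: pd.DataFrame,
    spec: TSOSpec,
    pgs_names: Sequence[str],
    covariates: Sequence[str] = (),
    family: Literal["per_factor", "global"] = "per_factor",
) -> pd.DataFrame:
    """One TSO fit per PGS, all trait factors regressed on it jointly.

    ``data`` must contain the indicator columns of ``spec``, every PGS
    column (standardised) and every covariate column.  Returns the
    association table with BH-adjusted p-values.
    """
    _check_predictors(data, list(pgs_names) + list(covariates))
    rows: list[dict] = []
    # warm start every structural fit from one measurement-only fit
    try:
        base_theta = fit(spec, data, compute_se=False).theta
    except ConvergenceError:
        base_theta = None
    for pgs in pgs_names:
        struct = {f: (pgs, *covariates) for f in spec.trait_factors}
        spec_p = TSOSpec(spec.substances, spec.occasions, struct)
        try:
            fitted = fit(spec_p, data, theta0=base_theta)
            std = standardised_solution(fitted)
            rows += _extract_rows(std, fitted, [pgs], f"single:{pgs}", "single")
        except ConvergenceError:
            for factor in spec.trait_factors:
                rows.append(
                    {
                        "model": f"single:{pgs}", "model_kind": "single",
                        "pgs": pgs, "factor": factor,
                        "b_std": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "se_robust": np.nan, "p_raw": np.nan, "converged": False,
                    }
                )
    return add_fdr(pd.DataFrame(rows), family)


def select_significant(
    table: pd.DataFrame,
    alpha: float = 0.05,
    category_map: Mapping[str, str] | None = None,
) -> dict[str, dict[str, list[str]]]:
    """Per-factor PGSs with p_fdr < alpha, split by declared category.

    ``category_map`` assigns each PGS to ``"substance"`` (set A) or
    ``"trait"`` (set B); every PGS in the table must be covered.
    """
    category_map = dict(category_map or {})
    for pgs in table["pgs"].unique():
        if pgs not in category_map:
            raise CategoryError(f"PGS {pgs!r} has no substance/trait category")
        if category_map[pgs] not in ("substance", "trait"):
            raise CategoryError(
                f"category for {pgs!r} must be 'substance' or 'trait'"
            )
    out: dict[str, dict[str, list[str]]] = {}
    for factor, sub in table.groupby("factor"):
        hits = sub.loc[sub["p_fdr"] < alpha, "pgs"].tolist()
        out[factor] = {
            "substance": [g for g in hits if category_map[g] == "substance"],
            "trait": [g for g in hits if category_map[g] == "trait"],
        }
    return out


def run_multi_pgs(
    data: pd.DataFrame,
    spec: TSOSpec,
    selected_sets: Mapping[str, Mapping[str, Sequence[str]]],
    covariates: Sequence[str] = (),
    condition_threshold: float = 1e8,
    family: Literal["per_factor", "global"] = "per_factor",
) -> pd.DataFrame:
    """Joint (multivariable) TSO models for each factor and PGS set.

    For each factor and each non-empty set (A: substance-use scores,
    B: trait scores), the factor is regressed on all selected scores
    plus covariates while the other trait factors carry covariates only.
    """
    rows: list[dict] = []
    kind_of = {"substance": "multi-A-substance", "trait": "multi-B-trait"}
    base_theta = None
    if any(v for sets in selected_sets.values() for v in sets.values()):
        try:
            base_theta = fit(spec, data, compute_se=False).theta
        except ConvergenceError:
            base_theta = None
    for factor, sets in selected_sets.items():
        for set_name, pgs_list in sets.items():
            pgs_list = list(pgs_list)
            if not pgs_list:
                continue
            _check_predictors(data, pgs_list + list(covariates))
            if len(pgs_list) > 1:
                X = data[pgs_list].to_numpy(float)
                X = (X - X.mean(0)) / X.std(0, ddof=1)
                cond = np.linalg.cond(X)
                if cond > condition_threshold:
                    corr = np.corrcoef(X, rowvar=False)
                    np.fill_diagonal(corr, 0.0)
                    i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
                    raise CollinearityError(
                        f"scores {pgs_list[i]!r} and {pgs_list[j]!r} are "
                        f"collinear (design condition number {cond:.2e})"
                    )
            struct = {
                f: ((*pgs_list, *covariates) if f == factor else tuple(covariates))
                for f in spec.trait_factors
            }
            struct = {f: cols for f, cols in struct.items() if cols}
            spec_m = TSOSpec(spec.substances, spec.occasions, struct)
            model_id = f"{kind_of[set_name]}:{factor}"
            try:
                fitted = fit(spec_m, data, theta0=base_theta)
                std = standardised_solution(fitted)
                got = _extract_rows(std, fitted, pgs_list, model_id, kind_of[set_name])
                rows += [r for r in got if r["factor"] == factor]
            except ConvergenceError:
                for pgs in pgs_list:
                    rows.append(
                        {
                            "model": model_id, "model_kind": kind_of[set_name],
                            "pgs": pgs, "factor": factor,
                            "b_std": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                            "se_robust": np.nan, "p_raw": np.nan,
                            "converged": False,
                        }
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "model", "model_kind", "pgs", "factor", "b_std",
            "ci_low", "ci_high", "se_robust", "p_raw", "converged",
        ],
    )
    if len(table):
        table = add_fdr(table, family)
    else:
        table["p_fdr"] = pd.Series(dtype=float)
    return table
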