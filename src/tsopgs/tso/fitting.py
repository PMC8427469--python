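"""Estimation of TSO models: FIML point estimates, naive and sandwich
standard errors, standardised solutions, fit indices and the variance
decomposition of the indicators.

Optimisation runs in a transformed space (log residual variances) with a
quasi-Newton (L-BFGS-B) pass on the analytic gradient, followed by Newton
polishing with a finite-difference Hessian of that gradient.  One
deterministic start is used (loadings at half the indicator SD, residual
variances at half the indicator variance, intercepts at the observed
means, structural coefficients at zero); on non-convergence up to five
seeded jittered restarts are attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .likelihood import DomainError, TSOLikelihood, fit_saturated, mvn_missing_loglik
from .spec import TSOSpec, unpack


class ConvergenceError(RuntimeError):
    """Raised when the optimiser fails even after jittered restarts."""

    def __init__(self, msg: str, best_theta: np.ndarray | None = None):
        super().__init__(msg)
        self.best_theta = best_theta


class RankDeficiencyError(RuntimeError):
    """Observed information is singular; names the offending parameters."""


@dataclass
class FittedTSO:
    """A fitted TSO model and everything downstream steps need."""

    spec: TSOSpec
    theta: np.ndarray                 # natural parameters
    loglik: float
    converged: bool
    n_used: int
    n_dropped: int
    likelihood: TSOLikelihood = field(repr=False)
    grad_norm: float = np.nan
    heywood: bool = False
    se_naive: np.ndarray | None = None
    se_robust: np.ndarray | None = None
    cov_naive: np.ndarray | None = field(default=None, repr=False)
    cov_robust: np.ndarray | None = field(default=None, repr=False)

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names()

    @property
    def implied_mu(self) -> np.ndarray:
        return self.likelihood.implied_moments(self.theta)[0]

    @property
    def implied_sigma(self) -> np.ndarray:
        return self.likelihood.implied_moments(self.theta)[1]

    def parameter_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({"parameter": self.param_names, "estimate": self.theta})
        if self.se_naive is not None:
            tab["se_naive"] = self.se_naive
        if self.se_robust is not None:
            tab["se_robust"] = self.se_robust
        return tab


# ----------------------------------------------------------------------
# parameter transform: log residual variances
# ----------------------------------------------------------------------
def _to_transformed(spec: TSOSpec, theta: np.ndarray) -> np.ndarray:
    t = np.array(theta, float)
    sl = _resid_slice(spec)
    t[sl] = np.log(t[sl])
    return t


def _to_natural(spec: TSOSpec, t: np.ndarray) -> np.ndarray:
    theta = np.array(t, float)
    sl = _resid_slice(spec)
    theta[sl] = np.exp(np.clip(theta[sl], -40.0, 40.0))
    return theta


def _resid_slice(spec: TSOSpec) -> slice:
    p = spec.n_indicators
    start = spec.n_free_loadings
    return slice(start, start + p)


def _start_values(spec: TSOSpec, lik: TSOLikelihood) -> np.ndarray:
    Y = lik.Y
    sd = np.sqrt(np.nanvar(Y, axis=0))
    sd = np.where(sd > 0, sd, 1.0)
    parts = []
    if spec.has_common:
        parts.append(0.5 * sd)
    parts.append(0.5 * sd)
    parts.append(0.5 * sd**2)
    parts.append(np.nanmean(Y, axis=0))
    parts.append(np.zeros(spec.n_structural))
    return np.concatenate(parts)


def _fd_hessian(fun_grad, x: np.ndarray, eps_scale: float = 1e-5) -> np.ndarray:
    """Central finite-difference Jacobian of an analytic gradient."""
    k = x.size
    H = np.empty((k, k))
    for j in range(k):
        eps = eps_scale * (1.0 + abs(x[j]))
        xp = x.copy()
        xp[j] += eps
        xm = x.copy()
        xm[j] -= eps
        H[:, j] = (fun_grad(xp) - fun_grad(xm)) / (2.0 * eps)
    return 0.5 * (H + H.T)


def fit(
    spec: TSOSpec,
    data: pd.DataFrame,
    gtol: float = 1e-5,
    max_iter: int = 3000,
    n_restarts: int = 5,
    restart_seed: int = 20_240_101,
    compute_se: bool = True,
    theta0: np.ndarray | None = None,
) -> FittedTSO:
    """Fit a TSOSpec to a phenotype table by FIML.

    ``data`` must contain every indicator column of the model (NaN =
    missing) and every structural predictor column (complete).
    Convergence requires the maximum absolute component of the
    per-observation average score, max|grad|/n, to fall below ``gtol``.
    """
    Y = data[list(spec.indicators)].to_numpy(float)
    X = data[list(spec.predictors)].to_numpy(float) if spec.predictors else None
    return fit_arrays(
        spec, Y, X,
        gtol=gtol, max_iter=max_iter, n_restarts=n_restarts,
        restart_seed=restart_seed, compute_se=compute_se, theta0=theta0,
    )


def fit_arrays(
    spec: TSOSpec,
    Y: np.ndarray,
    X: np.ndarray | None = None,
    gtol: float = 1e-5,
    max_iter: int = 3000,
    n_restarts: int = 5,
    restart_seed: int = 20_240_101,
    compute_se: bool = True,
    theta0: np.ndarray | None = None,
) -> FittedTSO:
    lik = TSOLikelihood(spec, Y, X)
    if theta0 is None:
        theta0 = _start_values(spec, lik)
    else:
        theta0 = np.asarray(theta0, float)
        if theta0.size == spec.n_free_cov_params + spec.n_indicators:
            # warm start from a measurement-only fit: append zero b's
            theta0 = np.concatenate([theta0, np.zeros(spec.n_structural)])
    n = lik.n

    def neg_ll_grad_t(t: np.ndarray):
        theta = _to_natural(spec, t)
        try:
            ll, grad = lik.loglik_grad(theta)
        except DomainError:
            return np.inf, np.zeros_like(t)
        g = -np.asarray(grad)
        sl = _resid_slice(spec)
        g[sl] *= theta[sl]            # chain rule through log transform
        return -ll, g

    def grad_t_only(t: np.ndarray) -> np.ndarray:
        return neg_ll_grad_t(t)[1]

    rng = np.random.default_rng(restart_seed)
    best = None
    start = _to_transformed(spec, theta0)
    for attempt in range(n_restarts + 1):
        t_init = start if attempt == 0 else start + rng.normal(0, 0.2, start.size)
        res = optimize.minimize(
            neg_ll_grad_t, t_init, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
        )
        t_hat = res.x
        # Newton polish on the transformed scale
        f_cur, g_cur = neg_ll_grad_t(t_hat)
        for _ in range(8):
            if np.max(np.abs(g_cur)) / n < 0.01 * gtol:
                break
            H = _fd_hessian(grad_t_only, t_hat)
            try:
                w, Q = linalg.eigh(H)
            except linalg.LinAlgError:
                break
            w = np.maximum(w, 1e-8 * max(1.0, w.max()))
            step = -Q @ ((Q.T @ g_cur) / w)
            alpha = 1.0
            improved = False
            for _ in range(30):
                f_new, g_new = neg_ll_grad_t(t_hat + alpha * step)
                if f_new <= f_cur - 1e-12 * abs(f_cur) or (
                    np.isfinite(f_new)
                    and np.max(np.abs(g_new)) < np.max(np.abs(g_cur))
                ):
                    t_hat = t_hat + alpha * step
                    f_cur, g_cur = f_new, g_new
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                break
        gnorm = float(np.max(np.abs(g_cur))) / n
        cand = (f_cur, gnorm, t_hat)
        if best is None or cand[0] < best[0] - 1e-9 or (
            abs(cand[0] - best[0]) <= 1e-9 and cand[1] < best[1]
        ):
            best = cand
        if best[1] < gtol:
            break

    f_best, gnorm, t_hat = best
    theta_hat = _canonical_signs(spec, _to_natural(spec, t_hat))
    converged = bool(np.isfinite(f_best) and gnorm < gtol)
    heywood = bool(np.any(unpack(spec, theta_hat).resid_var < 1e-6))
    fitted = FittedTSO(
        spec=spec,
        theta=theta_hat,
        loglik=-f_best,
        converged=converged,
        n_used=lik.n,
        n_dropped=lik.n_dropped,
        likelihood=lik,
        grad_norm=gnorm,
        heywood=heywood,
    )
    if not converged:
        raise ConvergenceError(
            f"optimiser did not converge (max|grad|/n = {gnorm:.2e})",
            best_theta=theta_hat,
        )
    if compute_se:
        robust_se(fitted)
    return fitted


def _canonical_signs(spec: TSOSpec, theta: np.ndarray) -> np.ndarray:
    """Resolve the sign indeterminacy of each latent factor.

    The likelihood is invariant to jointly flipping a factor's loadings
    and structural coefficients; we fix each trait factor so its loading
    sum is positive.
    """
    par = unpack(spec, theta)
    theta = np.array(theta, float)
    p = spec.n_indicators
    sidx = spec.structural_index()
    off_b = spec.n_free_cov_params + p
    n_occ = len(spec.occasions)
    flip: dict[int, bool] = {}
    pos = 0
    if spec.has_common:
        if par.lam_common.sum() < 0:
            theta[pos : pos + p] *= -1.0
            flip[0] = True
        pos += p
    f_off = 1 if spec.has_common else 0
    for k in range(len(spec.substances)):
        rows = slice(k * n_occ, (k + 1) * n_occ)
        if par.lam_specific[rows].sum() < 0:
            theta[pos + k * n_occ : pos + (k + 1) * n_occ] *= -1.0
            flip[f_off + k] = True
    for j, (f, _) in enumerate(sidx):
        if flip.get(f):
            theta[off_b + j] *= -1.0
    return theta


# ----------------------------------------------------------------------
# standard errors
# ----------------------------------------------------------------------
def robust_se(fitted: FittedTSO) -> np.ndarray:
    """Sandwich standard errors A^-1 B A^-1 on the natural scale.

    A is the observed information (negative Hessian of the total FIML
    log-likelihood, obtained by finite-differencing the analytic
    gradient); B is the sum of outer products of casewise score vectors.
    Also fills the naive SEs sqrt(diag(A^-1)).
    """
    lik = fitted.likelihood
    spec = fitted.spec

    def grad_nat(theta: np.ndarray) -> np.ndarray:
        return lik.loglik_grad(theta)[1]

    A = -_fd_hessian(grad_nat, fitted.theta)
    w, Q = linalg.eigh(A)
    tol = 1e-10 * max(1.0, float(np.max(np.abs(w))))
    if np.any(w <= tol):
        bad = np.flatnonzero(np.abs(Q[:, w <= tol]).max(axis=1) > 0.3)
        names = [fitted.param_names[i] for i in bad]
        raise RankDeficiencyError(
            f"observed information is singular; implicated parameters: {names}"
        )
    A_inv = Q @ np.diag(1.0 / w) @ Q.T
    S = lik.casewise_scores(fitted.theta)
    B = S @ S.T
    cov_rob = A_inv @ B @ A_inv
    fitted.cov_naive = A_inv
    fitted.cov_robust = cov_rob
    fitted.se_naive = np.sqrt(np.clip(np.diag(A_inv), 0, None))
    fitted.se_robust = np.sqrt(np.clip(np.diag(cov_rob), 0, None))
    return fitted.se_robust


# ----------------------------------------------------------------------
# standardised solution
# ----------------------------------------------------------------------
def _std_map(fitted: FittedTSO, theta: np.ndarray) -> np.ndarray:
    """Fully standardised parameter vector at theta (same layout)."""
    spec = fitted.spec
    lik = fitted.likelihood
    par = unpack(spec, theta)
    _, sigma = lik.implied_moments(theta)
    sd_y = np.sqrt(np.diag(sigma))
    fvar = lik.factor_variances(theta)
    m_t = len(spec.trait_factors)
    p = spec.n_indicators
    out = np.empty_like(theta)
    pos = 0
    if spec.has_common:
        out[pos : pos + p] = par.lam_common * np.sqrt(fvar[0]) / sd_y
        pos += p
    n_occ = len(spec.occasions)
    off = 1 if spec.has_common else 0
    lam_s_std = np.empty(p)
    for k in range(len(spec.substances)):
        rows = slice(k * n_occ, (k + 1) * n_occ)
        lam_s_std[rows] = (
            par.lam_specific[rows] * np.sqrt(fvar[off + k]) / sd_y[rows]
        )
    out[pos : pos + p] = lam_s_std
    pos += p
    out[pos : pos + p] = par.resid_var / sd_y**2
    pos += p
    out[pos : pos + p] = par.intercepts / sd_y
    pos += p
    if spec.n_structural:
        sd_x = np.sqrt(np.diag(lik.x_cov))
        for j, (f, x) in enumerate(spec.structural_index()):
            out[pos + j] = par.b[j] * sd_x[x] / np.sqrt(fvar[f])
    return out


def standardised_solution(fitted: FittedTSO) -> pd.DataFrame:
    """Fully standardised estimates with delta-method standard errors.

    Loadings are rescaled by the model-implied factor and indicator SDs;
    structural coefficients by sd(predictor)/sd(factor), so a squared
    standardised coefficient is the share of factor variance the
    predictor explains on its own.  SEs propagate the robust (sandwich)
    covariance through a numerical Jacobian of the standardisation map.
    """
    std = _std_map(fitted, fitted.theta)
    if not np.all(np.isfinite(std)):
        raise DomainError("degenerate standardisation: zero implied variance")
    cov = fitted.cov_robust if fitted.cov_robust is not None else fitted.cov_naive
    se_std = np.full_like(std, np.nan)
    if cov is not None:
        k = fitted.theta.size
        J = np.empty((k, k))
        for j in range(k):
            eps = 1e-6 * (1.0 + abs(fitted.theta[j]))
            tp = fitted.theta.copy()
            tp[j] += eps
            tm = fitted.theta.copy()
            tm[j] -= eps
            J[:, j] = (_std_map(fitted, tp) - _std_map(fitted, tm)) / (2 * eps)
        se_std = np.sqrt(np.clip(np.diag(J @ cov @ J.T), 0, None))
    return pd.DataFrame(
        {
            "parameter": fitted.param_names,
            "raw": fitted.theta,
            "se_robust": fitted.se_robust,
            "std": std,
            "std_se": se_std,
        }
    )


# ----------------------------------------------------------------------
# fit indices
# ----------------------------------------------------------------------
@dataclass
class FitIndices:
    chisq: float
    df: int
    pvalue: float
    cfi: float
    rmsea: float
    srmr: float
    baseline_chisq: float
    baseline_df: int
    n_used: int
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "chisq": self.chisq, "df": self.df, "pvalue": self.pvalue,
            "cfi": self.cfi, "rmsea": self.rmsea, "srmr": self.srmr,
            "baseline_chisq": self.baseline_chisq,
            "baseline_df": self.baseline_df, "n_used": self.n_used,
            "note": self.note,
        }


def _independence_loglik(Y: np.ndarray) -> tuple[float, int]:
    """Exact FIML log-likelihood of the independence (baseline) model.

    With a diagonal covariance the FIML likelihood factorises over
    variables, so per-variable observed-data ML moments are the joint
    optimum.
    """
    ll = 0.0
    p = Y.shape[1]
    for j in range(p):
        y = Y[:, j]
        y = y[~np.isnan(y)]
        v = y.var()  # ML (n) denominator
        ll += float(np.sum(stats.norm.logpdf(y, y.mean(), np.sqrt(v))))
    return ll, p * (p + 1) // 2 - p


def fit_indices(fitted: FittedTSO) -> FitIndices:
    """Likelihood-ratio chi-square against the EM-saturated model plus
    CFI, RMSEA and SRMR.

    The chi-square compares the model's marginal implied moments with
    the saturated FIML solution; the baseline is the independence model
    (free means and variances, zero covariances).
    """
    lik = fitted.likelihood
    Y = lik.Y
    mu_s, sigma_s, ll_sat = fit_saturated(Y)
    mu_m, sigma_m = lik.implied_moments(fitted.theta)
    ll_model = mvn_missing_loglik(Y, mu_m, sigma_m)
    T = max(2.0 * (ll_sat - ll_model), 0.0)
    df = fitted.spec.df
    ll_b, df_b_free = _independence_loglik(Y)
    T_b = max(2.0 * (ll_sat - ll_b), 0.0)
    df_b = df_b_free
    note = ""
    if df == 0:
        cfi = np.nan
        rmsea = np.nan
        pval = np.nan
        note = "df = 0: saturated covariance structure; CFI/RMSEA undefined"
    else:
        denom = max(T_b - df_b, T - df, 0.0)
        cfi = 1.0 if denom == 0.0 else 1.0 - max(T - df, 0.0) / denom
        rmsea = float(np.sqrt(max(T - df, 0.0) / (df * fitted.n_used)))
        pval = float(stats.chi2.sf(T, df))
    # SRMR on correlation-metric residuals against the saturated moments
    d = np.sqrt(np.diag(sigma_s))
    resid = (sigma_s - sigma_m) / np.outer(d, d)
    iu = np.triu_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return FitIndices(
        chisq=float(T), df=df, pvalue=pval, cfi=float(cfi),
        rmsea=float(rmsea) if df else np.nan, srmr=srmr,
        baseline_chisq=float(T_b), baseline_df=df_b,
        n_used=fitted.n_used, note=note,
    )


# ----------------------------------------------------------------------
# variance decomposition
# ----------------------------------------------------------------------
def variance_decomposition(fitted: FittedTSO) -> pd.DataFrame:
    """Per-indicator variance shares of common, specific, occasion and
    residual components, plus the across-indicator averages.

    Requires a measurement-only model (no structural predictors), where
    the factors are orthogonal with unit variance and the implied
    indicator variance is exactly the sum of the four components.
    """
    spec = fitted.spec
    if spec.n_structural:
        raise DomainError(
            "variance decomposition is defined for the baseline model "
            "without structural predictors"
        )
    par = unpack(spec, fitted.theta)
    p = spec.n_indicators
    common = (par.lam_common**2) if spec.has_common else np.zeros(p)
    specific = par.lam_specific**2
    occasion = np.ones(p) if spec.has_occasion else np.zeros(p)
    resid = par.resid_var
    total = common + specific + occasion + resid
    tab = pd.DataFrame(
        {
            "indicator": spec.indicators,
            "common": common / total,
            "specific": specific / total,
            "occasion": occasion / total,
            "residual": resid / total,
        }
    )
    means = tab[["common", "specific", "occasion", "residual"]].mean()
    tab.attrs["average"] = means.to_dict()
    return tab
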