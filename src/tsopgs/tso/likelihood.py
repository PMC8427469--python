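"""FIML likelihood machinery for the TSO covariance-structure model.

The full-information maximum-likelihood (FIML) log-likelihood of partially
observed multivariate-normal rows is evaluated pattern-grouped: rows
sharing a missingness pattern share one set of cross-product matrices,
and patterns with the same number of observed variables are processed as
a single batched linear-algebra call (stacked Cholesky factorisations).
After a one-off O(n p^2) precompute, a likelihood-plus-gradient
evaluation costs O(#patterns * p^3) in C-level batches, essentially
independent of the sample size for complete data.

Exogenous predictors (polygenic scores and covariates) are treated as
fixed regressors: the likelihood is conditional on X, with per-row mean
``nu + Lambda_t B x_i`` and constant conditional covariance
``Lambda Lambda' + Theta`` (all factor residual variances fixed to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .spec import TSOSpec, unpack

_LOG2PI = float(np.log(2.0 * np.pi))


class DomainError(ValueError):
    """Raised when moments leave the parameter domain (non-PD, etc.)."""


def ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """Maximum-likelihood discrepancy F(S, Sigma) >= 0.

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p; zero iff Sigma == S.
    """
    S = np.asarray(S, float)
    sigma = np.asarray(sigma, float)
    p = S.shape[0]
    if S.shape != sigma.shape or S.shape != (p, p):
        raise DomainError("S and sigma must be square with equal dimension")
    try:
        cs = linalg.cholesky(S, lower=True)
        cg = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as e:
        raise DomainError(f"matrix not positive definite: {e}") from e
    logdet_s = 2.0 * np.sum(np.log(np.diag(cs)))
    logdet_g = 2.0 * np.sum(np.log(np.diag(cg)))
    tr = float(np.trace(linalg.cho_solve((cg, True), S)))
    return float(logdet_g - logdet_s + tr - p)


# ----------------------------------------------------------------------
# pattern grouping
# ----------------------------------------------------------------------
@dataclass
class _Pattern:
    obs: np.ndarray          # observed column indices
    rows: np.ndarray         # row indices into the (kept) data
    Y: np.ndarray            # n_g x p_g observed block
    Z: np.ndarray            # n_g x q design ([X, 1])


@dataclass
class _SizeClass:
    """All patterns with the same number of observed variables, stacked."""

    obs: np.ndarray          # G x s observed column indices
    mis: np.ndarray          # G x (p-s) missing column indices
    n: np.ndarray            # G row counts
    Syy: np.ndarray          # G x s x s
    Szy: np.ndarray          # G x q x s   (Z'Y; last Z column is 1)
    Szz: np.ndarray          # G x q x q


def _group_patterns(Y: np.ndarray, Z: np.ndarray) -> list[_Pattern]:
    """Group rows of Y (no all-missing rows) by missingness pattern."""
    n, p = Y.shape
    miss = np.isnan(Y)
    codes = miss @ (1 << np.arange(p, dtype=np.int64))
    order = np.argsort(codes, kind="stable")
    codes_sorted = codes[order]
    boundaries = np.flatnonzero(np.diff(codes_sorted)) + 1
    patterns: list[_Pattern] = []
    for chunk in np.split(order, boundaries):
        rows = chunk
        obs = np.flatnonzero(~miss[rows[0]])
        patterns.append(
            _Pattern(obs=obs, rows=rows, Y=Y[np.ix_(rows, obs)], Z=Z[rows])
        )
    return patterns


def _stack_classes(patterns: list[_Pattern], p: int) -> list[_SizeClass]:
    by_size: dict[int, list[_Pattern]] = {}
    for g in patterns:
        by_size.setdefault(g.obs.size, []).append(g)
    classes = []
    allcols = np.arange(p)
    for s, group in sorted(by_size.items()):
        obs = np.stack([g.obs for g in group])
        mis = np.stack(
            [np.setdiff1d(allcols, g.obs, assume_unique=True) for g in group]
        )
        n = np.array([g.rows.size for g in group])
        Syy = np.stack([g.Y.T @ g.Y for g in group])
        Szy = np.stack([g.Z.T @ g.Y for g in group])
        Szz = np.stack([g.Z.T @ g.Z for g in group])
        classes.append(_SizeClass(obs=obs, mis=mis, n=n, Syy=Syy, Szy=Szy, Szz=Szz))
    return classes


def _stacked_chol(Sig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Cholesky; returns (L, logdet per matrix)."""
    try:
        L = np.linalg.cholesky(Sig)
    except np.linalg.LinAlgError as e:
        raise DomainError("covariance sub-matrix not positive definite") from e
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
    return L, logdet


def _scatter_add(target: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                 contrib: np.ndarray) -> None:
    """target[rows, cols] += contrib with duplicate indices, via bincount."""
    ncol = target.shape[1]
    flat = (rows * ncol + cols).ravel()
    target += np.bincount(
        flat, weights=contrib.ravel(), minlength=target.size
    ).reshape(target.shape)


# ----------------------------------------------------------------------
# unstructured MVN likelihood and EM (saturated model)
# ----------------------------------------------------------------------
class _MVNStats:
    """Per-pattern sufficient statistics of Y alone (intercept design)."""

    def __init__(self, Y: np.ndarray):
        Y = np.asarray(Y, float)
        keep = ~np.isnan(Y).all(axis=1)
        self.n_dropped = int((~keep).sum())
        Y = Y[keep]
        self.n, self.p = Y.shape
        Z = np.ones((self.n, 1))
        self.patterns = _group_patterns(Y, Z)
        self.classes = _stack_classes(self.patterns, self.p)

    def loglik(self, mu: np.ndarray, sigma: np.ndarray) -> float:
        ll = 0.0
        for cl in self.classes:
            s = cl.obs.shape[1]
            Sig = sigma[cl.obs[:, :, None], cl.obs[:, None, :]]
            L, logdet = _stacked_chol(Sig)
            K = np.linalg.inv(Sig)
            mu_o = mu[cl.obs]                                  # G x s
            Sy = cl.Szy[:, 0, :]                               # G x s
            # sum_i u_i u_i' with u = y - mu
            U2 = (
                cl.Syy
                - np.einsum("gi,gj->gij", Sy, mu_o)
                - np.einsum("gi,gj->gij", mu_o, Sy)
                + cl.n[:, None, None] * np.einsum("gi,gj->gij", mu_o, mu_o)
            )
            quad = np.einsum("gij,gji->g", K, U2)
            ll += float(np.sum(-0.5 * (cl.n * (s * _LOG2PI + logdet) + quad)))
        return ll

    def em_step(
        self, mu: np.ndarray, sigma: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """One EM iteration; returns (mu_new, sigma_new, loglik at input)."""
        p = self.p
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for cl in self.classes:
            G, s = cl.obs.shape
            m = cl.mis.shape[1]
            Sig_oo = sigma[cl.obs[:, :, None], cl.obs[:, None, :]]
            L, logdet = _stacked_chol(Sig_oo)
            K = np.linalg.inv(Sig_oo)
            mu_o = mu[cl.obs]
            Sy = cl.Szy[:, 0, :]
            Su = Sy - cl.n[:, None] * mu_o                     # sum of u_i
            U2 = (
                cl.Syy
                - np.einsum("gi,gj->gij", Sy, mu_o)
                - np.einsum("gi,gj->gij", mu_o, Sy)
                + cl.n[:, None, None] * np.einsum("gi,gj->gij", mu_o, mu_o)
            )
            quad = np.einsum("gij,gji->g", K, U2)
            ll += float(np.sum(-0.5 * (cl.n * (s * _LOG2PI + logdet) + quad)))
            # observed-block contributions
            _scatter_add(T1[:, None], cl.obs, np.zeros_like(cl.obs), Sy)
            _scatter_add(T2, cl.obs[:, :, None], cl.obs[:, None, :], cl.Syy)
            if m == 0:
                continue
            mu_m = mu[cl.mis]
            Sig_mo = sigma[cl.mis[:, :, None], cl.obs[:, None, :]]  # G x m x s
            A = Sig_mo @ K                                          # G x m x s
            ASu = np.einsum("gms,gs->gm", A, Su)
            # E[sum y_m] = n mu_m + A sum(u)
            Em = cl.n[:, None] * mu_m + ASu
            _scatter_add(T1[:, None], cl.mis, np.zeros_like(cl.mis), Em)
            # E[sum y_m y_o'] = mu_m Sy' + A (Syy - mu_o Sy')
            Uyo = cl.Syy - np.einsum("gi,gj->gij", mu_o, Sy)        # sum u y'
            Emo = np.einsum("gm,gj->gmj", mu_m, Sy) + A @ Uyo
            _scatter_add(T2, cl.mis[:, :, None], cl.obs[:, None, :], Emo)
            _scatter_add(T2, cl.obs[:, :, None], cl.mis[:, None, :],
                         np.swapaxes(Emo, 1, 2))
            # E[sum y_m y_m'] = n mu mu' + mu (A Su)' + (A Su) mu'
            #                   + A (sum u u') A' + n C_mm
            Sig_mm = sigma[cl.mis[:, :, None], cl.mis[:, None, :]]
            C = Sig_mm - A @ np.swapaxes(Sig_mo, 1, 2)
            Emm = (
                cl.n[:, None, None] * np.einsum("gm,gk->gmk", mu_m, mu_m)
                + np.einsum("gm,gk->gmk", mu_m, ASu)
                + np.einsum("gm,gk->gmk", ASu, mu_m)
                + A @ U2 @ np.swapaxes(A, 1, 2)
                + cl.n[:, None, None] * C
            )
            _scatter_add(T2, cl.mis[:, :, None], cl.mis[:, None, :], Emm)
        mu_new = T1 / self.n
        sigma_new = T2 / self.n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        return mu_new, sigma_new, ll


def mvn_missing_loglik(Y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """FIML log-likelihood of rows Y (NaN = missing) under N(mu, sigma).

    Pattern-grouped; identical to summing the log-density of each row's
    observed sub-vector under the corresponding sub-moments.
    """
    stats = _MVNStats(Y)
    return stats.loglik(np.asarray(mu, float), np.asarray(sigma, float))


def fit_saturated(
    Y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """ML mean and covariance of multivariate-normal data with missing cells.

    EM algorithm, converged when the relative log-likelihood change drops
    below ``tol``.  On complete data the sample mean and n-denominator
    sample covariance are returned directly (the closed-form ML solution).

    Returns (mu_hat, sigma_hat, loglik).
    """
    Y = np.asarray(Y, float)
    miss = np.isnan(Y)
    if Y.size and miss.all(axis=0).any():
        j = int(np.flatnonzero(miss.all(axis=0))[0])
        raise DomainError(f"variable {j} is never observed; moments inestimable")
    Y = Y[~miss.all(axis=1)]
    if not np.isnan(Y).any():
        mu = Y.mean(axis=0)
        sigma = np.atleast_2d(np.cov(Y, rowvar=False, bias=True))
        return mu, sigma, mvn_missing_loglik(Y, mu, sigma)

    stats = _MVNStats(Y)
    mu = np.nanmean(Y, axis=0)
    var0 = np.nanvar(Y, axis=0)
    sigma = np.diag(np.maximum(var0, 1e-6))
    ll_old = -np.inf
    for _ in range(max_iter):
        mu_new, sigma_new, ll = stats.em_step(mu, sigma)
        if np.isfinite(ll_old) and ll - ll_old < tol * (abs(ll_old) + 1.0):
            break
        mu, sigma = mu_new, sigma_new
        ll_old = ll
    return mu, sigma, stats.loglik(mu, sigma)


# ----------------------------------------------------------------------
# model likelihood with analytic gradient and casewise scores
# ----------------------------------------------------------------------
class TSOLikelihood:
    """Conditional FIML likelihood of a TSOSpec given data.

    Parameters
    ----------
    spec : model structure
    Y : n x p indicator matrix, NaN = missing, columns in spec order
    X : n x q_x complete predictor matrix (columns in spec.predictors
        order) or None when the model has no structural block
    """

    def __init__(self, spec: TSOSpec, Y: np.ndarray, X: np.ndarray | None = None):
        self.spec = spec
        Y = np.asarray(Y, float)
        p = spec.n_indicators
        if Y.ndim != 2 or Y.shape[1] != p:
            raise DomainError(f"Y must have {p} columns")
        q_x = len(spec.predictors)
        if q_x:
            if X is None:
                raise DomainError("spec has structural predictors but X is None")
            X = np.asarray(X, float)
            if X.shape != (Y.shape[0], q_x):
                raise DomainError(f"X must be n x {q_x}")
            if np.isnan(X).any():
                raise DomainError("predictors must be complete")
        else:
            X = np.zeros((Y.shape[0], 0))
        self.q_x = q_x
        keep = ~np.isnan(Y).all(axis=1)
        self.n_dropped = int((~keep).sum())
        self.Y = Y[keep]
        self.X = X[keep]
        self.Z = np.hstack([self.X, np.ones((self.Y.shape[0], 1))])
        self.n = int(keep.sum())
        if self.n < 2:
            raise DomainError("need at least two rows with observed indicators")
        self.patterns = _group_patterns(self.Y, self.Z)
        self.classes = _stack_classes(self.patterns, p)
        self._sidx = spec.structural_index()
        # X sample moments (fixed-regressor view; n denominator)
        if q_x:
            self.x_mean = self.X.mean(axis=0)
            xc = self.X - self.x_mean
            self.x_cov = xc.T @ xc / self.n
        else:
            self.x_mean = np.zeros(0)
            self.x_cov = np.zeros((0, 0))

    # ------------------------------------------------------------------
    def _structures(self, theta: np.ndarray):
        """Lambda, B (trait x q_x), W (p x q), conditional Sigma."""
        spec = self.spec
        par = unpack(spec, theta)
        if np.any(par.resid_var <= 0):
            raise DomainError("residual variances must be positive")
        lam = spec.loading_matrix(par.lam_common, par.lam_specific)
        m_t = len(spec.trait_factors)
        B = np.zeros((m_t, self.q_x))
        for coef, (f, x) in zip(par.b, self._sidx):
            B[f, x] = coef
        lam_t = lam[:, :m_t]
        W = np.empty((spec.n_indicators, self.q_x + 1))
        W[:, : self.q_x] = lam_t @ B
        W[:, self.q_x] = par.intercepts
        sigma = lam @ lam.T + np.diag(par.resid_var)
        return par, lam, lam_t, B, W, sigma

    def conditional_moments(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(W, Sigma_cond): per-row mean is W @ [x_i, 1]."""
        *_, W, sigma = self._structures(theta)
        return W, sigma

    def implied_moments(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Marginal implied mean and covariance of the indicators.

        With predictors, trait factors pick up covariance B S_x B' from
        the shared regressors (S_x the sample predictor covariance), so
        sigma = Lambda Phi Lambda' + Theta with a non-diagonal Phi.
        """
        spec = self.spec
        par, lam, lam_t, B, W, _ = self._structures(theta)
        m = len(spec.factors)
        phi = np.eye(m)
        if self.q_x:
            m_t = len(spec.trait_factors)
            phi[:m_t, :m_t] += B @ self.x_cov @ B.T
        sigma = lam @ phi @ lam.T + np.diag(par.resid_var)
        mu = par.intercepts.copy()
        if self.q_x:
            mu = mu + lam_t @ (B @ self.x_mean)
        return mu, sigma

    def factor_variances(self, theta: np.ndarray) -> np.ndarray:
        """Marginal variance of each factor (trait factors first)."""
        spec = self.spec
        _, _, _, B, _, _ = self._structures(theta)
        m = len(spec.factors)
        out = np.ones(m)
        if self.q_x:
            m_t = len(spec.trait_factors)
            out[:m_t] += np.einsum("fx,xy,fy->f", B, self.x_cov, B)
        return out

    # ------------------------------------------------------------------
    def loglik(self, theta: np.ndarray) -> float:
        return self.loglik_grad(theta, need_grad=False)[0]

    def loglik_grad(
        self, theta: np.ndarray, need_grad: bool = True
    ) -> tuple[float, np.ndarray | None]:
        """Total FIML log-likelihood and its analytic gradient (natural).

        The gradient is accumulated through two adjoints: G_sigma (with
        respect to the conditional covariance) and G_w (with respect to
        the mean-coefficient matrix W), then chained onto loadings,
        residual variances, intercepts and structural coefficients.
        """
        spec = self.spec
        par, lam, lam_t, B, W, sigma = self._structures(theta)
        p = spec.n_indicators
        q = self.q_x + 1
        ll = 0.0
        if need_grad:
            G_sig = np.zeros((p, p))
            G_w = np.zeros((p, q))
        for cl in self.classes:
            G, s = cl.obs.shape
            Sig = sigma[cl.obs[:, :, None], cl.obs[:, None, :]]
            L, logdet = _stacked_chol(Sig)
            K = np.linalg.inv(Sig)
            Wg = W[cl.obs]                                      # G x s x q
            WS = Wg @ cl.Szy                                    # G x s x s
            E = cl.Syy - WS - np.swapaxes(WS, 1, 2) + Wg @ cl.Szz @ np.swapaxes(Wg, 1, 2)
            K_E = K @ E
            tr = np.einsum("gii->g", K_E)
            ll += float(np.sum(-0.5 * (cl.n * (s * _LOG2PI + logdet) + tr)))
            if need_grad:
                contrib_sig = cl.n[:, None, None] * K - K_E @ K
                _scatter_add(G_sig, cl.obs[:, :, None], cl.obs[:, None, :],
                             contrib_sig)
                contrib_w = -2.0 * K @ (np.swapaxes(cl.Szy, 1, 2) - Wg @ cl.Szz)
                qcols = np.broadcast_to(np.arange(q)[None, None, :], contrib_w.shape)
                _scatter_add(G_w, cl.obs[:, :, None], qcols, contrib_w)
        if not need_grad:
            return float(ll), None

        # chain rule onto natural parameters (gradient of -2*loglik)
        m_t = len(spec.trait_factors)
        grad = np.zeros(spec.n_free)
        G_wx = G_w[:, : self.q_x]
        # per trait factor: v_f = 2 G_sig lam_f + G_wx B_f'
        V = 2.0 * G_sig @ lam_t
        if self.q_x:
            V = V + G_wx @ B.T
        pos = 0
        if spec.has_common:
            grad[pos : pos + p] = V[:, 0]
            pos += p
        n_occ = len(spec.occasions)
        off = 1 if spec.has_common else 0
        lam_s_grad = np.empty(p)
        for k in range(len(spec.substances)):
            rows = slice(k * n_occ, (k + 1) * n_occ)
            lam_s_grad[rows] = V[rows, off + k]
        grad[pos : pos + p] = lam_s_grad
        pos += p
        grad[pos : pos + p] = np.diag(G_sig)
        pos += p
        grad[pos : pos + p] = G_w[:, self.q_x]
        pos += p
        if self._sidx:
            Gb = lam_t.T @ G_wx                                 # m_t x q_x
            for j, (f, x) in enumerate(self._sidx):
                grad[pos + j] = Gb[f, x]
        return float(ll), -0.5 * grad

    # ------------------------------------------------------------------
    def casewise_scores(self, theta: np.ndarray) -> np.ndarray:
        """Per-row gradient of the log-density: k x n matrix of scores.

        Used for the meat of the sandwich variance estimator; at the
        optimum the scores sum to (numerically) zero.
        """
        spec = self.spec
        par, lam, lam_t, B, W, sigma = self._structures(theta)
        p = spec.n_indicators
        k = spec.n_free
        S = np.zeros((k, self.n))
        n_occ = len(spec.occasions)
        has_c = spec.has_common
        off_ls = p if has_c else 0
        off_r = off_ls + p
        off_nu = off_r + p
        off_b = off_nu + p
        m_t = len(spec.trait_factors)
        for g in self.patterns:
            o = g.obs
            idx = g.rows
            Wg = W[o]
            sig_g = sigma[np.ix_(o, o)]
            c = linalg.cholesky(sig_g, lower=True)
            K = linalg.cho_solve((c, True), np.eye(o.size))
            U = (g.Y - g.Z @ Wg.T).T                            # p_g x n_g
            Vm = K @ U
            Xg = g.Z[:, : self.q_x]
            lam_o = lam[o]
            P = lam_o[:, :m_t].T @ Vm                           # m_t x n_g
            for j, (f, x) in enumerate(self._sidx):
                S[off_b + j, idx] = P[f] * Xg[:, x]
            S[np.ix_(off_nu + o, idx)] = Vm
            S[np.ix_(off_r + o, idx)] = 0.5 * (Vm**2 - np.diag(K)[:, None])
            if self.q_x:
                XB = Xg @ B.T                                   # n_g x m_t
            if has_c:
                lam_c_o = lam_o[:, 0]
                w = lam_c_o @ Vm
                const = (K @ lam_c_o)[:, None]
                rowvals = Vm * w[None, :] - const
                if self.q_x:
                    rowvals = rowvals + Vm * XB[:, 0][None, :]
                S[np.ix_(o, idx)] = rowvals
            sub_of = o // n_occ
            f_off = 1 if has_c else 0
            for kk in np.unique(sub_of):
                sel = np.flatnonzero(sub_of == kk)
                col = f_off + kk
                lam_k_o = lam_o[:, col]
                w = lam_k_o @ Vm
                const = (K @ lam_k_o)[sel, None]
                rowvals = Vm[sel] * w[None, :] - const
                if self.q_x:
                    rowvals = rowvals + Vm[sel] * XB[:, col][None, :]
                S[np.ix_(off_ls + o[sel], idx)] = rowvals
        return S
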