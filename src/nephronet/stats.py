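"""Shared statistical helpers: FDR, vectorized linear models, a profiled-ML
random-intercept fitter, and permutation machinery for Spearman correlations.

The random-intercept fitter exploits the block structure of the marginal
covariance V = sigma2_e * (I + lambda * Z Z') for a single grouping factor:
each group's block is I_m + lambda * J_m, whose inverse and log-determinant
are closed-form, so the likelihood profiles down to a 1-D search over the
variance ratio lambda = sigma2_group / sigma2_resid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LinearFit:
    """Per-response OLS results for a shared design matrix."""

    coef: np.ndarray        # (n_responses, n_params)
    se: np.ndarray          # (n_responses, n_params)
    pvalues: np.ndarray     # (n_responses, n_params), two-sided t
    df_resid: int
    resid_var: np.ndarray   # (n_responses,)


def _check_design(X: np.ndarray, names) -> None:
    n, k = X.shape
    if n <= k:
        raise ValueError(f"design has {k} columns but only {n} rows")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j in range(k):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j] if names is not None else str(j))
        raise ValueError(f"singular design; collinear columns: {bad}")


def ols_fit(Y: np.ndarray, X: np.ndarray, names=None) -> LinearFit:
    """Fit ``y ~ X`` by least squares for every row of ``Y`` at once.

    Y is (n_responses, n_obs); X is (n_obs, n_params) and shared across
    responses. Standard errors use the residual variance with n-k df.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    _check_design(X, names)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = Y @ X @ XtX_inv  # (g, k)
    resid = Y - coef @ X.T
    df = n - k
    s2 = np.einsum("ij,ij->i", resid, resid) / df
    se = np.sqrt(np.outer(s2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    return LinearFit(coef=coef, se=se, pvalues=pvals, df_resid=df, resid_var=s2)


@dataclass
class MixedFit:
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray     # two-sided Wald (normal)
    lambda_ratio: float     # sigma2_group / sigma2_resid at the ML optimum
    sigma2_resid: float
    loglik: float


def _profile_negloglik(lam: float, y, X, group_idx, group_sizes):
    """-2 * profiled log-likelihood (up to a constant) at variance ratio lam."""
    n = y.shape[0]
    # V^{-1} per block: I - (lam / (1 + lam*m)) J
    w = lam / (1.0 + lam * group_sizes)  # per group
    # group sums
    def vinv_dot(M):
        M = np.atleast_2d(M.T).T  # ensure 2-D (n, c)
        gs = np.zeros((len(group_sizes), M.shape[1]))
        np.add.at(gs, group_idx, M)
        return M - (w[group_idx, None] * gs[group_idx])

    XtVX = X.T @ vinv_dot(X)
    XtVy = X.T @ vinv_dot(y[:, None])[:, 0]
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    rss = float(r @ vinv_dot(r[:, None])[:, 0])
    logdet = float(np.sum(np.log1p(lam * group_sizes)))
    sigma2 = rss / n
    return n * np.log(sigma2) + logdet, beta, sigma2, XtVX


def fit_random_intercept(y, X, groups, names=None) -> MixedFit:
    """ML fit of ``y ~ X`` with a random intercept per level of ``groups``.

    The variance ratio is profiled out and optimized in 1-D on a log grid;
    ``lambda = 0`` (pure fixed effects) is always a candidate, so with a
    single group level the fit reduces to OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X, names)
    codes, levels = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes).astype(float)
    n = y.shape[0]

    def obj(log_lam):
        return _profile_negloglik(np.exp(log_lam), y, X, codes, sizes)[0]

    best_lam = 0.0
    best_val = _profile_negloglik(0.0, y, X, codes, sizes)[0]
    if len(levels) > 1:
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded")
        if res.fun < best_val - 1e-10:
            best_val, best_lam = res.fun, float(np.exp(res.x))
    _, beta, sigma2, XtVX = _profile_negloglik(best_lam, y, X, codes, sizes)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    ll = -0.5 * (best_val + n * (1.0 + np.log(2.0 * np.pi)))
    return MixedFit(coef=beta, se=se, pvalues=p, lambda_ratio=best_lam,
                    sigma2_resid=sigma2, loglik=ll)


def rank_standardize(x: np.ndarray) -> np.ndarray:
    """Average-tie ranks, centered and scaled to unit norm (for Spearman)."""
    r = stats.rankdata(x)
    r = r - r.mean()
    nrm = np.linalg.norm(r)
    if nrm == 0:
        raise ValueError("constant vector has no rank correlation")
    return r / nrm


def permutation_spearman(a, b, n_permutations: int, seed: int,
                         alternative: str = "two-sided"):
    """Spearman rho of ``a`` vs ``b`` with an empirical permutation p-value.

    The null permutes the pairing of one vector. Add-one estimator:
    p = (1 + #extreme) / (B + 1), so p is never exactly zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    ra, rb = rank_standardize(a), rank_standardize(b)
    rho = float(ra @ rb)
    rng = np.random.default_rng(seed)
    # permuted copies of rb, one per row; rho_perm = P @ ra
    perm = np.tile(rb, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    rho_perm = perm @ ra
    if alternative == "two-sided":
        n_extreme = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
    elif alternative == "greater":
        n_extreme = int(np.sum(rho_perm >= rho - 1e-12))
    elif alternative == "less":
        n_extreme = int(np.sum(rho_perm <= rho + 1e-12))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + n_extreme) / (n_permutations + 1.0)
    return rho, p


def spearman_onesided(x, y, alternative: str = "greater"):
    """Spearman rho with an analytic one- or two-sided p (t approximation)."""
    rho, p_two = stats.spearmanr(x, y)
    rho = float(rho)
    if alternative == "two-sided":
        return rho, float(p_two)
    p_one = p_two / 2.0 if rho > 0 else 1.0 - p_two / 2.0
    if alternative == "less":
        p_one = 1.0 - p_one
    return rho, float(p_one)
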