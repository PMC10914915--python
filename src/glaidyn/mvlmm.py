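"""Multivariate (multi-trait) mixed-model association scan.

Matrix-variate model for t traits measured on n lines:

    Y = 1 mu' + x beta' + G + E,
    rows of G ~ MN(0, K, Vg),  rows of E ~ MN(0, I, Ve),

with K a (LOCO) kinship.  In the eigenbasis of K the rows are independent
with covariance s_i Vg + Ve, so the null covariance pair (Vg, Ve) can be
estimated by an EM algorithm on the rotated residuals; each marker is then
a t-vector GLS with a Wald test of H0: beta_1 = ... = beta_t = 0 against
chi2(t).  The null fit also yields the genetic correlations between traits,
r_g(j,k) = Vg_jk / sqrt(Vg_jj Vg_kk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EIG_FLOOR = 1e-8


@dataclass
class MvNullFit:
    Vg: np.ndarray
    Ve: np.ndarray
    loglik: float
    iterations: int
    converged: bool

    def genetic_correlations(self) -> np.ndarray:
        d = np.sqrt(np.clip(np.diag(self.Vg), np.finfo(float).tiny, None))
        return self.Vg / np.outer(d, d)


def _nearest_psd(M: np.ndarray) -> np.ndarray:
    M = (M + M.T) / 2.0
    vals, vecs = np.linalg.eigh(M)
    if vals.min() >= EIG_FLOOR:
        return M
    vals = np.clip(vals, EIG_FLOOR, None)
    return (vecs * vals) @ vecs.T


def fit_mv_null(Y: np.ndarray, s: np.ndarray, U: np.ndarray,
                tol: float = 1e-6, max_iter: int = 1000) -> tuple:
    """EM fit of (Vg, Ve) for the null model (intercept only).

    ``Y`` is n x t (complete cases), ``s``/``U`` the eigendecomposition of
    the kinship.  Returns (MvNullFit, mu, rotated quantities) where the
    rotated quantities (Yr, ones_r, s) are reused by the marker scan.
    """
    n, t = Y.shape
    Yr = U.T @ Y
    ones_r = U.T @ np.ones(n)
    s = np.clip(s, EIG_FLOOR, None)

    cov = np.cov(Y.T) if t > 1 else np.atleast_2d(np.var(Y))
    Vg = 0.5 * cov + EIG_FLOOR * np.eye(t)
    Ve = 0.5 * cov + EIG_FLOOR * np.eye(t)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Sig = s[:, None, None] * Vg[None] + Ve[None]     # n x t x t
        W = np.linalg.inv(Sig)
        # GLS intercept
        A = np.einsum("i,ijk->jk", ones_r ** 2, W)
        b = np.einsum("i,ijk,ik->j", ones_r, W, Yr)
        mu = np.linalg.solve(A, b)
        R = Yr - np.outer(ones_r, mu)                    # n x t residuals
        WR = np.einsum("ijk,ik->ij", W, R)
        # log-likelihood
        sign, logdet = np.linalg.slogdet(Sig)
        quad = np.einsum("ij,ij->", R, WR)
        ll = -0.5 * (n * t * np.log(2 * np.pi) + logdet.sum() + quad)
        # E-step
        m_g = s[:, None] * (WR @ Vg)                     # posterior means of G rows
        VgW = np.einsum("jl,ilk->ijk", Vg, W)
        post_cov = s[:, None, None] * Vg[None] - (
            s[:, None, None] ** 2 * np.einsum("ijl,lk->ijk", VgW, Vg))
        Vg_new = (np.einsum("ij,ik->jk", m_g / s[:, None], m_g)
                  + np.einsum("i,ijk->jk", 1.0 / s, post_cov)) / n
        m_e = R - m_g
        Ve_new = (np.einsum("ij,ik->jk", m_e, m_e)
                  + post_cov.sum(axis=0)) / n
        Vg, Ve = _nearest_psd(Vg_new), _nearest_psd(Ve_new)
        if abs(ll - prev_ll) <= tol * max(abs(ll), 1.0):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    if not converged and it >= max_iter:
        # EM crawls near variance boundaries; the iteration cap is part of
        # the stopping rule, but flag the fit and let the caller decide
        warnings.warn(
            f"multivariate null fit stopped at the {max_iter}-iteration cap "
            f"(last loglik {prev_ll:.6g}); estimates may be near a boundary",
            stacklevel=2)
    fit = MvNullFit(Vg=Vg, Ve=Ve, loglik=float(prev_ll), iterations=it,
                    converged=converged)
    return fit, mu, (Yr, ones_r, s)


def _mv_marker_scan(Yr, ones_r, G_rot, s, Vg, Ve):
    """Per-marker joint GLS with design [1, x] (x) I_t; returns the marker
    beta vectors, their covariance diagonals and Wald statistics."""
    n, t = Yr.shape
    Sig = s[:, None, None] * Vg[None] + Ve[None]
    W = np.linalg.inv(Sig)
    A11 = np.einsum("i,ijk->jk", ones_r ** 2, W)
    b1 = np.einsum("i,ijk,ik->j", ones_r, W, Yr)
    m = G_rot.shape[1]
    A12 = np.einsum("i,im,ijk->mjk", ones_r, G_rot, W)
    A22 = np.einsum("im,ijk->mjk", G_rot ** 2, W)
    b2 = np.einsum("im,ijk,ik->mj", G_rot, W, Yr)

    betas = np.empty((m, t))
    var_diag = np.empty((m, t))
    wald = np.empty(m)
    ok = np.ones(m, dtype=bool)
    for j in range(m):
        A = np.block([[A11, A12[j]], [A12[j].T, A22[j]]])
        rhs = np.concatenate([b1, b2[j]])
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            ok[j] = False
            betas[j] = 0.0
            var_diag[j] = np.nan
            wald[j] = 0.0
            continue
        sol = Ainv @ rhs
        bm = sol[t:]
        Vb = Ainv[t:, t:]
        betas[j] = bm
        var_diag[j] = np.diag(Vb)
        try:
            wald[j] = float(bm @ np.linalg.solve(Vb, bm))
        except np.linalg.LinAlgError:
            ok[j] = False
            wald[j] = 0.0
    return betas, var_diag, np.clip(wald, 0.0, None), ok


def gwas_multivariate(
    Y: pd.DataFrame,
    panel,
    kinships: dict,
    environment: str = "env",
    loco: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
):
    """Joint scan of t traits (columns of ``Y``, rows aligned to the panel).

    Listwise deletion of incomplete rows.  Returns ``(assoc, null_fits)``:
    a per-marker table with the joint Wald test and per-trait effects/SEs,
    and the per-chromosome null fits (Vg, Ve, genetic correlations).
    """
    traits = list(Y.columns)
    t = len(traits)
    if t > 10:
        raise ValueError("at most 10 traits supported in the multivariate scan")
    Yv = Y.to_numpy(dtype=float)
    keep = np.all(np.isfinite(Yv), axis=1)
    Yv = Yv[keep]
    X = panel.b73_indicator()[keep]
    chroms = panel.markers["chrom"].to_numpy()

    beta = np.full((panel.n_markers, t), np.nan)
    se = np.full((panel.n_markers, t), np.nan)
    wald = np.full(panel.n_markers, np.nan)
    pval = np.ones(panel.n_markers)
    flags = np.zeros(panel.n_markers, dtype=bool)
    null_fits = {}

    if loco:
        groups = [(int(c), np.flatnonzero(chroms == c))
                  for c in np.unique(chroms)]
    else:
        groups = [(0, np.arange(panel.n_markers))]
    for c, cols in groups:
        K = kinships[c][np.ix_(keep, keep)]
        s, U = np.linalg.eigh(K)
        fit, mu, (Yr, ones_r, s) = fit_mv_null(Yv, s, U, tol=tol,
                                               max_iter=max_iter)
        null_fits[c] = fit
        G = X[:, cols]
        mono = G.std(axis=0) == 0
        Gr = U.T @ G
        b_c, v_c, w_c, ok = _mv_marker_scan(Yr, ones_r, Gr, s, fit.Vg, fit.Ve)
        bad = mono | ~ok
        w_c = np.where(bad, 0.0, w_c)
        p_c = stats.chi2.sf(w_c, df=t)
        p_c = np.where(bad, 1.0, p_c)
        beta[cols] = b_c
        se[cols] = np.sqrt(v_c)
        wald[cols], pval[cols] = w_c, p_c
        flags[cols] = bad

    assoc = pd.DataFrame({
        "environment": environment, "method": "MV",
        "chrom": chroms, "pos": panel.markers["pos"].to_numpy(),
        "stat": wald, "p": np.clip(pval, np.finfo(float).tiny, 1.0),
        "monomorphic": flags,
    })
    for j, tr in enumerate(traits):
        assoc[f"beta_{tr}"] = beta[:, j]
        assoc[f"se_{tr}"] = se[:, j]
    assoc.attrs["traits"] = traits
    assoc.attrs["null_fits"] = null_fits
    return assoc, null_fits


def estimate_genetic_correlations(Y: pd.DataFrame, K: np.ndarray,
                                  tol: float = 1e-6,
                                  max_iter: int = 1000) -> pd.DataFrame:
    """Genetic correlation matrix between traits from the global-kinship
    null fit (the diagonal is exactly 1)."""
    Yv = Y.to_numpy(dtype=float)
    keep = np.all(np.isfinite(Yv), axis=1)
    s, U = np.linalg.eigh(K[np.ix_(keep, keep)])
    fit, _, _ = fit_mv_null(Yv[keep], s, U, tol=tol, max_iter=max_iter)
    rg = fit.genetic_correlations()
    np.fill_diagonal(rg, 1.0)
    return pd.DataFrame(rg, index=Y.columns, columns=Y.columns)
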