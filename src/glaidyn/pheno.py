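"""Plot-to-genotype phenotype statistics.

Three layers, mirroring standard field-trial practice:

* per-environment adjusted means from a fixed genotype + block model with a
  separable AR1(rho_row) x AR1(rho_col) residual correlation, the two
  autocorrelation parameters chosen by a REML profile over a grid;
* Cullis generalized heritability H2 = 1 - vbar_Delta / (2 sigma_g^2),
  where vbar_Delta is the mean prediction-error variance of pairwise
  genotype-BLUP differences under the same model with genotype random;
* a multi-environment variance decomposition with random genotype and
  genotype-by-environment effects, each tested by a restricted
  likelihood-ratio test against the 50:50 chi2(0)/chi2(1) boundary mixture,
  plus the genetic coefficient of variation CV_g = 100 sigma_g / mu.

Trait correlation utilities (standardized PCA, Pearson r with t-tests)
operate on the adjusted-means tables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize, minimize_scalar
from sklearn.decomposition import PCA


# ---------------------------------------------------------------------------
# spatial GLS machinery


def _ar1_corr(coords: np.ndarray, rho: float) -> np.ndarray:
    d = np.abs(coords[:, None] - coords[None, :])
    return rho ** d


def _spatial_corr(rows, cols, rho_r, rho_c):
    C = _ar1_corr(np.asarray(rows, float), rho_r) * _ar1_corr(
        np.asarray(cols, float), rho_c)
    return C + 1e-9 * np.eye(len(rows))


def _sum_zero(codes: np.ndarray, k: int) -> np.ndarray:
    """Sum-to-zero contrast columns for a factor with k levels."""
    X = np.zeros((codes.size, k - 1))
    for j in range(k - 1):
        X[codes == j, j] = 1.0
    X[codes == k - 1, :] = -1.0
    return X


@dataclass
class SpatialFitRecord:
    rho_row: float
    rho_col: float
    sigma2: float
    loglik: float
    n_plots: int
    missing: dict = field(default_factory=dict)


def _gls_profile(y, X, L):
    """GLS through a Cholesky factor of the correlation matrix; returns
    (beta, rss, logdet_xtx) with the error scale profiled out."""
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    sign, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
    return beta, rss, logdet_xtx


def adjusted_means(
    plot_df: pd.DataFrame,
    value_col: str,
    rho_grid=None,
) -> tuple:
    """Per-genotype adjusted means for one trait in one environment.

    ``plot_df`` needs columns genotype, block, row, col and ``value_col``.
    Fixed genotype and block effects are estimated by generalized least
    squares under a separable AR1 x AR1 plot-error correlation; the two
    rhos are picked by REML profile over ``rho_grid`` (default
    {0, 0.1, ..., 0.9}^2).  The adjusted mean is the grand mean plus the
    sum-to-zero genotype effect.

    Returns ``(means, record)``: a Series indexed by genotype and a
    :class:`SpatialFitRecord`.
    """
    if rho_grid is None:
        rho_grid = np.arange(0.0, 0.91, 0.1)
    df = plot_df.dropna(subset=[value_col]).reset_index(drop=True)
    y = df[value_col].to_numpy(dtype=float)
    n = y.size
    geno = pd.Categorical(df["genotype"])
    blocks = pd.Categorical(df["block"])
    G, B = len(geno.categories), len(blocks.categories)
    parts = [np.ones((n, 1))]
    if B > 1:
        parts.append(_sum_zero(blocks.codes, B))
    Xg = _sum_zero(geno.codes, G)
    parts.append(Xg)
    X = np.column_stack(parts)
    p = X.shape[1]

    best = None
    for rho_r in rho_grid:
        for rho_c in rho_grid:
            C = _spatial_corr(df["row"].to_numpy(), df["col"].to_numpy(),
                              rho_r, rho_c)
            L = np.linalg.cholesky(C)
            beta, rss, logdet_xtx = _gls_profile(y, X, L)
            logdet_c = 2.0 * np.log(np.diag(L)).sum()
            m2l = (n - p) * np.log(max(rss, 1e-300)) + logdet_c + logdet_xtx
            if best is None or m2l < best[0]:
                best = (m2l, rho_r, rho_c, beta, rss)
    m2l, rho_r, rho_c, beta, rss = best
    sigma2 = rss / max(n - p, 1)

    mu = beta[0]
    offset = 1 + (B - 1 if B > 1 else 0)
    g_eff = np.empty(G)
    g_eff[: G - 1] = beta[offset: offset + G - 1]
    g_eff[G - 1] = -g_eff[: G - 1].sum()
    means = pd.Series(mu + g_eff, index=list(geno.categories), name=value_col)
    record = SpatialFitRecord(rho_row=float(rho_r), rho_col=float(rho_c),
                              sigma2=float(sigma2), loglik=float(-0.5 * m2l),
                              n_plots=n)
    return means, record


def adjusted_means_table(plot_df: pd.DataFrame, traits, rho_grid=None
                         ) -> pd.DataFrame:
    """Adjusted means for several traits across every environment in a
    plot-level table; returns a long table (genotype, environment, trait,
    value)."""
    rows = []
    for env, sub in plot_df.groupby("environment", sort=True):
        for trait in traits:
            means, _ = adjusted_means(sub, trait, rho_grid=rho_grid)
            for g, v in means.items():
                rows.append({"genotype": g, "environment": env,
                             "trait": trait, "value": v})
    return pd.DataFrame(rows)


def pivot_means(long_df: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = long_df[long_df["trait"] == trait]
    return sub.pivot(index="genotype", columns="environment", values="value")


# ---------------------------------------------------------------------------
# generalized heritability (single environment)


def generalized_heritability(
    plot_df: pd.DataFrame,
    value_col: str,
    rho: tuple = (0.0, 0.0),
) -> float:
    """Cullis generalized heritability for one trait in one environment.

    Same model as :func:`adjusted_means` but with genotype random; the
    genotype-to-error variance ratio is estimated by a 1-D REML search.
    H2 = 1 - vbar_Delta / (2 sigma_g^2), computed over all genotype pairs
    and clipped to [0, 1]; sigma_g^2 = 0 gives H2 = 0 with a warning.
    """
    df = plot_df.dropna(subset=[value_col]).reset_index(drop=True)
    y = df[value_col].to_numpy(dtype=float)
    n = y.size
    geno = pd.Categorical(df["genotype"])
    blocks = pd.Categorical(df["block"])
    G, B = len(geno.categories), len(blocks.categories)
    parts = [np.ones((n, 1))]
    if B > 1:
        parts.append(_sum_zero(blocks.codes, B))
    X = np.column_stack(parts)
    p = X.shape[1]
    Z = np.zeros((n, G))
    Z[np.arange(n), geno.codes] = 1.0
    C = _spatial_corr(df["row"].to_numpy(), df["col"].to_numpy(), *rho)
    ZZt = Z @ Z.T

    def m2l(log_lam):
        lam = np.exp(log_lam)
        V = C + lam * ZZt
        L = np.linalg.cholesky(V)
        beta, rss, logdet_xtx = _gls_profile(y, X, L)
        logdet_v = 2.0 * np.log(np.diag(L)).sum()
        return (n - p) * np.log(max(rss, 1e-300)) + logdet_v + logdet_xtx

    res = minimize_scalar(m2l, bounds=(-8.0, 8.0), method="bounded")
    lam = float(np.exp(res.x))
    V = C + lam * ZZt
    L = np.linalg.cholesky(V)
    beta, rss, _ = _gls_profile(y, X, L)
    sigma_e2 = rss / max(n - p, 1)
    sigma_g2 = lam * sigma_e2
    # variance ratio driven to the search boundary: no genotypic variance
    if res.x <= -7.9 or sigma_g2 <= 1e-12 * max(sigma_e2, 1e-300):
        warnings.warn("estimated genotypic variance is zero; H2 = 0",
                      stacklevel=2)
        return 0.0

    Vfull = sigma_e2 * V
    Vi = np.linalg.inv(Vfull)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    ZtPZ = Z.T @ P @ Z
    pev = sigma_g2 * np.eye(G) - sigma_g2 ** 2 * ZtPZ
    diag = np.diag(pev)
    off_mean = (pev.sum() - diag.sum()) / max(G * (G - 1), 1)
    vbar = 2.0 * (diag.mean() - off_mean)
    h2 = 1.0 - vbar / (2.0 * sigma_g2)
    return float(np.clip(h2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# multi-environment variance decomposition (blockwise REML)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    cv_g: float            # percent
    h2_network: float
    p_genotype: float      # RLRT p-value for the genotype term
    p_gxe: float           # RLRT p-value for the GxE term
    loglik: float
    n_obs: int


def _block_structures(df: pd.DataFrame, value_col: str):
    """Group the genotype blocks by their environment pattern so that all
    genotypes sharing a layout (the common case: balanced data, a single
    pattern) can be processed as one batched solve."""
    env = pd.Categorical(df["environment"])
    E = len(env.categories)
    env_codes = env.codes
    y_all = df[value_col].to_numpy(dtype=float)
    by_sig = {}
    for g, sub in df.groupby("genotype", sort=True):
        ridx = sub.index.to_numpy()
        eb = env_codes[ridx]
        order = np.argsort(eb, kind="mergesort")
        sig = tuple(eb[order])
        by_sig.setdefault(sig, []).append(y_all[ridx][order])
    batches = []
    for sig, ys in by_sig.items():
        eb = np.asarray(sig)
        Y = np.vstack(ys)                 # n_genotypes_in_batch x nb
        Xb = np.zeros((eb.size, E))
        Xb[np.arange(eb.size), eb] = 1.0
        batches.append((eb, Y, Xb))
    return batches, E


def _reml_m2l(theta, batches, E):
    """-2 REML log-likelihood (up to a constant) of the genotype/GxE model.

    The covariance is block-diagonal by genotype; genotypes with the same
    environment pattern share the same block matrix, so each pattern needs
    one Cholesky factorisation regardless of panel size."""
    sg2, sge2, se2 = theta
    XtVX = np.zeros((E, E))
    XtVy = np.zeros(E)
    ytVy = 0.0
    logdet = 0.0
    for eb, Y, Xb in batches:
        nb = eb.size
        V = se2 * np.eye(nb) + sg2 + sge2 * (eb[:, None] == eb[None, :])
        Lb = np.linalg.cholesky(V)
        logdet += Y.shape[0] * 2.0 * np.log(np.diag(Lb)).sum()
        Yw = solve_triangular(Lb, Y.T, lower=True)      # nb x n_g
        Xw = solve_triangular(Lb, Xb, lower=True)
        XtVX += Y.shape[0] * (Xw.T @ Xw)
        XtVy += Xw.T @ Yw.sum(axis=1)
        ytVy += float(np.sum(Yw * Yw))
    sign, logdet_x = np.linalg.slogdet(XtVX)
    beta = np.linalg.solve(XtVX, XtVy)
    quad = ytVy - float(beta @ XtVy)
    return logdet + logdet_x + quad, beta


def _fit_varcomp(df, value_col, include_g=True, include_ge=True):
    batches, E = _block_structures(df, value_col)
    y = df[value_col].to_numpy(dtype=float)
    vtot = max(float(np.var(y)), 1e-12)

    free = [include_g, include_ge, True]

    def unpack(x):
        out = [0.0, 0.0, 0.0]
        k = 0
        for j, f in enumerate(free):
            if f:
                out[j] = np.exp(x[k])
                k += 1
        return out

    def obj(x):
        theta = unpack(x)
        try:
            return _reml_m2l(theta, batches, E)[0]
        except np.linalg.LinAlgError:
            return 1e12

    x0 = np.log(np.full(sum(free), vtot / 3.0))
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    theta = unpack(res.x)
    m2l, beta = _reml_m2l(theta, batches, E)
    return theta, -0.5 * m2l, beta, batches, E


def variance_decomposition(long_df: pd.DataFrame, value_col: str = "value",
                           test: bool = True) -> VarianceComponents:
    """REML variance decomposition across environments.

    ``long_df`` needs columns genotype, environment and ``value_col`` and
    should be plot-level (replicates within genotype x environment cells)
    so that the GxE and residual variances are separable; with a single
    observation per cell the two are confounded and a warning is issued.
    """
    df = long_df.dropna(subset=[value_col]).reset_index(drop=True)
    if df.shape[0] < 4 or df["environment"].nunique() < 2:
        raise ValueError("need at least 2 environments with data")
    cell_counts = df.groupby(["genotype", "environment"]).size()
    if cell_counts.max() == 1:
        warnings.warn(
            "one observation per genotype x environment cell: GxE and "
            "residual variances are confounded", stacklevel=2)

    (sg2, sge2, se2), ll_full, beta, blocks, E = _fit_varcomp(df, value_col)
    mu = float(df[value_col].mean())
    cv_g = 100.0 * np.sqrt(sg2) / abs(mu) if mu != 0 else np.inf

    p_g = p_ge = np.nan
    if test:
        _, ll_nog, _, _, _ = _fit_varcomp(df, value_col, include_g=False)
        _, ll_noge, _, _, _ = _fit_varcomp(df, value_col, include_ge=False)
        stat_g = max(0.0, 2.0 * (ll_full - ll_nog))
        stat_ge = max(0.0, 2.0 * (ll_full - ll_noge))
        p_g = 0.5 * stats.chi2.sf(stat_g, 1) if stat_g > 0 else 1.0
        p_ge = 0.5 * stats.chi2.sf(stat_ge, 1) if stat_ge > 0 else 1.0

    h2 = _network_h2(df, value_col, sg2, sge2, se2)
    return VarianceComponents(
        sigma_g2=float(sg2), sigma_ge2=float(sge2), sigma_e2=float(se2),
        cv_g=float(cv_g), h2_network=float(h2),
        p_genotype=float(p_g), p_gxe=float(p_ge),
        loglik=float(ll_full), n_obs=int(df.shape[0]),
    )


def _network_h2(df, value_col, sg2, sge2, se2):
    """Cullis H2 at the network level from the mixed-model equations of the
    multi-environment fit (genotype BLUP prediction-error variances)."""
    if sg2 <= 1e-12:
        return 0.0
    geno = pd.Categorical(df["genotype"])
    env = pd.Categorical(df["environment"])
    G, E = len(geno.categories), len(env.categories)
    n = df.shape[0]
    X = np.zeros((n, E))
    X[np.arange(n), env.codes] = 1.0
    Zg = np.zeros((n, G))
    Zg[np.arange(n), geno.codes] = 1.0
    cell = geno.codes.astype(int) * E + env.codes.astype(int)
    cells, cell_idx = np.unique(cell, return_inverse=True)
    Zge = np.zeros((n, cells.size))
    Zge[np.arange(n), cell_idx] = 1.0
    Z = np.hstack([Zg, Zge])
    Ginv = np.concatenate([np.full(G, 1.0 / sg2),
                           np.full(cells.size, 1.0 / max(sge2, 1e-10))])
    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = Z.T @ Z
    C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + se2 * np.diag(Ginv)]]) / se2
    Cinv = np.linalg.inv(C + 1e-10 * np.eye(C.shape[0]))
    pev = Cinv[E:E + G, E:E + G]
    diag = np.diag(pev)
    off = (pev.sum() - diag.sum()) / max(G * (G - 1), 1)
    vbar = 2.0 * (diag.mean() - off)
    return float(np.clip(1.0 - vbar / (2.0 * sg2), 0.0, 1.0))


# ---------------------------------------------------------------------------
# trait correlations and PCA


def trait_pca(wide: pd.DataFrame) -> dict:
    """Standardized (correlation-matrix) PCA of an adjusted-means table.

    Constant columns are excluded with a warning; rows with any missing
    value are dropped (listwise deletion).  Returns explained-variance
    fractions, trait-axis correlations (loadings) and the row scores.
    """
    X = wide.dropna(axis=0)
    sd = X.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant traits: {list(sd.index[~keep])}",
                      stacklevel=2)
        X = X.loc[:, keep]
    Z = (X - X.mean()) / X.std(ddof=1)
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    evr = pca.explained_variance_ratio_
    loadings = pca.components_.T * np.sqrt(pca.explained_variance_)
    axes = [f"PC{i + 1}" for i in range(len(evr))]
    return {
        "explained_variance_ratio": pd.Series(evr, index=axes),
        "loadings": pd.DataFrame(loadings, index=X.columns, columns=axes),
        "scores": pd.DataFrame(scores, index=X.index, columns=axes),
    }


def trait_correlations(wide: pd.DataFrame):
    """Pairwise Pearson correlations with two-sided t-test p-values.

    Returns ``(r, p)`` DataFrames over the table's columns.
    """
    cols = list(wide.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        sub = wide.iloc[:, [i, j]].dropna()
        res = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))
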