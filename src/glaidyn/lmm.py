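"""Univariate mixed-model association scan with LOCO kinships.

Model per marker:  y = 1*mu + x*beta + u + e,  u ~ N(0, sg2 * K),
e ~ N(0, se2 * I), with K the leave-one-chromosome-out kinship of the
marker's chromosome.  After rotating into the eigenbasis of K the model is
a weighted regression with per-observation variance sg2*(s_i + delta),
delta = se2/sg2.  The variance ratio is estimated once per chromosome under
the null (no marker) by maximum likelihood on log10(delta) and reused for
every marker on that chromosome; ``exact=True`` re-optimises delta per
marker.  H0: beta = 0 is tested with a likelihood-ratio statistic against
chi2(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar


@dataclass
class NullFit:
    delta: float      # se2 / sg2
    sigma_g2: float
    loglik: float


def _reml_loglik(log10_delta, s, yr, Xr):
    """Profiled REML log-likelihood for a fixed variance ratio.

    REML (rather than plain ML) matters here: the small upward REML
    correction on delta is what keeps the per-marker plug-in tests
    calibrated at n of a few hundred.
    """
    delta = 10.0 ** log10_delta
    w = 1.0 / (s + delta)
    n, p = Xr.shape
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = (Xr * w[:, None]).T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(r * w @ r)
    sigma2 = rss / max(n - p, 1)
    sign, logdet_x = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2)
                 + np.sum(np.log(s + delta)) + logdet_x + (n - p))
    return ll, sigma2, rss


def fit_null(y_rot, X_rot, s) -> NullFit:
    """Estimate delta by REML over log10(delta) in [-5, 5] (coarse grid
    then bounded refinement, guarding against local optima)."""
    grid = np.linspace(-5, 5, 21)
    lls = [_reml_loglik(g, s, y_rot, X_rot)[0] for g in grid]
    k = int(np.argmax(lls))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(lambda g: -_reml_loglik(g, s, y_rot, X_rot)[0],
                          bounds=(lo, hi), method="bounded")
    best = res.x if -res.fun >= lls[k] else grid[k]
    ll, sigma2, _ = _reml_loglik(best, s, y_rot, X_rot)
    return NullFit(delta=float(10.0 ** best), sigma_g2=float(sigma2),
                   loglik=float(ll))


def _marker_scan(y_rot, ones_rot, G_rot, s, delta):
    """Vectorised GLS of [1, x_m] for every marker column of G_rot.

    Returns beta, se, lrt statistics (arrays of length m).
    """
    w = 1.0 / (s + delta)
    n = y_rot.size
    a = ones_rot
    S11 = float(a * w @ a)
    S1y = float(a * w @ y_rot)
    Syy = float(y_rot * w @ y_rot)
    S1x = (a * w) @ G_rot
    Sxy = (y_rot * w) @ G_rot
    Sxx = np.einsum("ij,ij->j", G_rot * w[:, None], G_rot)
    det = S11 * Sxx - S1x ** 2
    ok = det > 1e-12 * max(S11, 1.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (S11 * Sxy - S1x * S1y) / det
        mu = (Sxx * S1y - S1x * Sxy) / det
        rss1 = Syy - mu * S1y - beta * Sxy
    # null RSS with intercept only
    rss0 = Syy - S1y ** 2 / S11
    rss1 = np.clip(rss1, np.finfo(float).tiny, None)
    lrt = n * (np.log(rss0) - np.log(rss1))
    lrt = np.clip(lrt, 0.0, None)
    sigma2 = rss1 / max(n - 2, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 * S11 / det)
    return beta, se, lrt, ok


def gwas_univariate(
    y,
    panel,
    kinships: dict,
    trait: str = "trait",
    environment: str = "env",
    exact: bool = False,
    loco: bool = True,
) -> pd.DataFrame:
    """Association scan of one trait-environment vector against every marker.

    ``y`` must be aligned with ``panel.sample_ids`` (NaNs dropped listwise).
    ``kinships`` is the dict from :func:`glaidyn.kinship.loco_kinships`;
    with ``loco=False`` the global matrix (key 0) is used everywhere.
    Marker effects are expressed on the B73-allele scale (0/1 indicator).
    Monomorphic markers get p = 1 and are flagged.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    X = panel.b73_indicator()[keep]
    y = y[keep]
    n = y.size
    chroms = panel.markers["chrom"].to_numpy()
    out = {
        "trait": trait, "environment": environment, "method": "UV",
        "chrom": chroms, "pos": panel.markers["pos"].to_numpy(),
    }
    beta = np.full(panel.n_markers, np.nan)
    se = np.full(panel.n_markers, np.nan)
    stat = np.full(panel.n_markers, np.nan)
    pval = np.ones(panel.n_markers)
    flags = np.zeros(panel.n_markers, dtype=bool)
    null_fits = {}

    if loco:
        groups = [(int(c), np.flatnonzero(chroms == c))
                  for c in np.unique(chroms)]
    else:  # one fit with the global matrix covers every marker
        groups = [(0, np.arange(panel.n_markers))]
    for c, cols in groups:
        K = kinships[c][np.ix_(keep, keep)]
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
        yr = U.T @ y
        ones = U.T @ np.ones(n)
        null = fit_null(yr, ones[:, None], s)
        null_fits[c] = null
        G = X[:, cols]
        mono = G.std(axis=0) == 0
        Gr = U.T @ G
        if exact:
            b_c = np.empty(cols.size)
            se_c = np.empty(cols.size)
            t_c = np.empty(cols.size)
            ok = np.ones(cols.size, dtype=bool)
            for j in range(cols.size):
                # re-optimise delta with the marker in the model, then test
                # with that plug-in ratio
                Xj = np.column_stack([ones, Gr[:, j]])
                nf = fit_null(yr, Xj, s)
                b1, s1, t1, o1 = _marker_scan(yr, ones, Gr[:, j:j + 1], s,
                                              nf.delta)
                b_c[j], se_c[j], t_c[j], ok[j] = b1[0], s1[0], t1[0], o1[0]
        else:
            b_c, se_c, t_c, ok = _marker_scan(yr, ones, Gr, s, null.delta)
        bad = mono | ~ok
        b_c = np.where(bad, 0.0, b_c)
        t_c = np.where(bad, 0.0, t_c)
        p_c = stats.chi2.sf(t_c, df=1)
        p_c = np.where(bad, 1.0, p_c)
        beta[cols], se[cols], stat[cols], pval[cols] = b_c, se_c, t_c, p_c
        flags[cols] = bad

    out.update({"beta": beta, "se": se, "stat": stat,
                "p": np.clip(pval, np.finfo(float).tiny, 1.0),
                "monomorphic": flags})
    df = pd.DataFrame(out)
    df.attrs["null_fits"] = null_fits
    return df
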