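"""Multi-environment backward QTL selection and variance explained.

Candidate SNP clusters (deduplicated by peak marker) enter a joint model
for the genotype x environment adjusted means of one trait:

    y_ge = mu_e + sum_c x_g(c) * beta_{c,e} + g + eps,

with an environment-specific fixed allele effect per candidate (x is the
0/1 B73-allele indicator at the peak marker), an iid random genotype
effect and iid residuals.  Each candidate is tested by a joint Wald test
of its full set of environment effects when added last; the candidate with
the least significant effect is removed, iterating until every survivor
is significant at alpha (0.01 by default).  Survivors are QTLs; their
per-environment effects are then re-estimated and tested a posteriori.

The genotype-to-residual variance ratio is re-estimated by REML at each
elimination step.  Because both random terms are iid, the covariance is
block-diagonal by genotype and a per-genotype orthonormal (Helmert)
rotation makes the model a weighted least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

QTL_ALPHA = 0.01


@dataclass
class Qtl:
    trait: str
    chrom: int
    peak: int              # marker index
    peak_pos: int
    start: int             # extended interval, half-open
    end: int
    joint_p: float
    effects: pd.DataFrame  # per environment: beta, se, p, significant
    cluster: object = None
    partial_r2: dict = field(default_factory=dict)

    def significant_envs(self, alpha: float = QTL_ALPHA) -> list:
        return list(self.effects.index[self.effects["p"] <= alpha])


def _helmert_rotation(groups):
    """Per-genotype orthonormal rotation; returns (row order, d) where d is
    the ZZ' eigenvalue per rotated row (group size for the mean row, 0 for
    contrasts)."""
    blocks = []
    d = []
    for rows in groups:
        nb = len(rows)
        Q = np.linalg.qr(np.column_stack(
            [np.full((nb, 1), 1.0 / np.sqrt(nb)), np.eye(nb)[:, : nb - 1]]
        ))[0][:, :nb]
        # ensure first basis vector is the normalized mean
        if Q[0, 0] < 0:
            Q[:, 0] *= -1
        blocks.append((rows, Q))
        d.extend([nb] + [0.0] * (nb - 1))
    return blocks, np.asarray(d)


def _rotate(blocks, M):
    out = np.empty_like(M, dtype=float)
    k = 0
    for rows, Q in blocks:
        out[k:k + len(rows)] = Q.T @ M[rows]
        k += len(rows)
    return out


def _reml_lambda(y_rot, X_rot, d):
    n, p = X_rot.shape

    def m2l(log_lam):
        lam = np.exp(log_lam)
        w = 1.0 / (1.0 + lam * d)
        Xw = X_rot * w[:, None]
        XtWX = Xw.T @ X_rot
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ y_rot)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtWX, Xw.T @ y_rot, rcond=None)[0]
        r = y_rot - X_rot @ beta
        rss = float(r * w @ r)
        sign, logdet = np.linalg.slogdet(XtWX)
        return ((n - p) * np.log(max(rss, 1e-300))
                - np.sum(np.log(w)) + logdet)

    res = minimize_scalar(m2l, bounds=(-10.0, 10.0), method="bounded")
    return float(np.exp(res.x))


def _gls(y_rot, X_rot, d, lam):
    n, p = X_rot.shape
    w = 1.0 / (1.0 + lam * d)
    Xw = X_rot * w[:, None]
    XtWX = Xw.T @ X_rot
    XtWX_inv = np.linalg.pinv(XtWX)
    beta = XtWX_inv @ (Xw.T @ y_rot)
    r = y_rot - X_rot @ beta
    rss = float(r * w @ r)
    sigma2 = rss / max(n - p, 1)
    cov = sigma2 * XtWX_inv
    return beta, cov, sigma2, rss


def backward_select_qtls(
    candidates: list,
    means_df: pd.DataFrame,
    panel,
    trait: str = "trait",
    alpha: float = QTL_ALPHA,
    extended_intervals: Optional[dict] = None,
) -> list:
    """Backward elimination of candidate clusters on multi-environment
    adjusted means.

    ``candidates`` is a list of :class:`~glaidyn.clustering.SnpCluster`
    (non-discarded); ``means_df`` a long table (genotype, environment,
    value).  Returns the surviving clusters as :class:`Qtl` objects with
    per-environment effects on the B73-allele scale.
    """
    cands = [c for c in candidates if not getattr(c, "discarded", False)]
    if not cands:
        return []
    # deduplicate by peak marker, order-invariant processing order
    by_peak = {}
    for c in cands:
        if c.peak not in by_peak or c.peak_p < by_peak[c.peak].peak_p:
            by_peak[c.peak] = c
    cands = sorted(by_peak.values(), key=lambda c: (c.chrom, c.start, c.peak))

    df = means_df.dropna(subset=["value"]).copy()
    genotypes = sorted(df["genotype"].unique())
    g_pos = {g: i for i, g in enumerate(genotypes)}
    sample_pos = {s: i for i, s in enumerate(panel.sample_ids)}
    envs = sorted(df["environment"].unique())
    E = len(envs)
    e_pos = {e: i for i, e in enumerate(envs)}
    df = df.sort_values(["genotype", "environment"], kind="mergesort")
    df = df.reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    gi = df["genotype"].map(g_pos).to_numpy()
    ei = df["environment"].map(e_pos).to_numpy()
    n = y.size

    xg = panel.b73_indicator()
    x_by_cand = {}
    for c in cands:
        xi = np.array([xg[sample_pos[g], c.peak] for g in genotypes])
        x_by_cand[c.peak] = xi

    # drop perfectly collinear candidates (identical peak genotype vectors)
    kept, seen = [], {}
    for c in cands:
        key = tuple(x_by_cand[c.peak].astype(int))
        inv_key = tuple((1 - x_by_cand[c.peak]).astype(int))
        prior = seen.get(key) or seen.get(inv_key)
        if prior is not None:
            drop = c if c.peak_p >= prior.peak_p else prior
            keep = prior if drop is c else c
            warnings.warn(
                f"collinear candidates at markers {prior.peak}/{c.peak}: "
                f"keeping {keep.peak}", stacklevel=2)
            if drop is prior:
                kept[kept.index(prior)] = c
                seen[key] = c
            continue
        seen[key] = c
        kept.append(c)
    cands = kept

    groups = [list(np.flatnonzero(gi == k)) for k in range(len(genotypes))]
    blocks, d = _helmert_rotation(groups)
    y_rot = _rotate(blocks, y[:, None])[:, 0]

    env_X = np.zeros((n, E))
    env_X[np.arange(n), ei] = 1.0

    def design(active):
        cols = [env_X]
        for c in active:
            xc = x_by_cand[c.peak][gi]
            M = np.zeros((n, E))
            M[np.arange(n), ei] = xc
            cols.append(M)
        return np.hstack(cols)

    active = list(cands)
    while active:
        X = design(active)
        X_rot = _rotate(blocks, X)
        lam = _reml_lambda(y_rot, X_rot, d)
        beta, cov, sigma2, _ = _gls(y_rot, X_rot, d, lam)
        pvals = []
        for k, c in enumerate(active):
            sl = slice(E + k * E, E + (k + 1) * E)
            b = beta[sl]
            V = cov[sl, sl]
            try:
                w = float(b @ np.linalg.solve(V, b))
            except np.linalg.LinAlgError:
                w = 0.0
            pvals.append(stats.chi2.sf(max(w, 0.0), df=E))
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha:
            break
        # ties broken by position: among equal p, drop the larger position
        worst_p = pvals[worst]
        tied = [k for k, p in enumerate(pvals) if p == worst_p]
        worst = max(tied, key=lambda k: (active[k].chrom, active[k].start))
        active.pop(worst)

    qtls = []
    if not active:
        return qtls
    X = design(active)
    X_rot = _rotate(blocks, X)
    lam = _reml_lambda(y_rot, X_rot, d)
    beta, cov, sigma2, _ = _gls(y_rot, X_rot, d, lam)
    crit = stats.chi2  # per-env Wald against chi2(1)
    for k, c in enumerate(active):
        sl = slice(E + k * E, E + (k + 1) * E)
        b = beta[sl]
        V = cov[sl, sl]
        joint = float(b @ np.linalg.solve(V, b))
        joint_p = float(stats.chi2.sf(max(joint, 0.0), df=E))
        se = np.sqrt(np.clip(np.diag(V), 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            z2 = (b / se) ** 2
        p_env = crit.sf(z2, df=1)
        eff = pd.DataFrame({
            "beta": b, "se": se, "p": p_env,
            "significant": p_env <= alpha,
        }, index=envs)
        start, end = c.start, c.end
        if extended_intervals and c.peak in extended_intervals:
            start, end = extended_intervals[c.peak]
        qtls.append(Qtl(
            trait=trait, chrom=c.chrom, peak=c.peak,
            peak_pos=int(panel.markers["pos"].iloc[c.peak]),
            start=int(start), end=int(end), joint_p=joint_p,
            effects=eff, cluster=c,
        ))
    return qtls


# ---------------------------------------------------------------------------
# variance explained


def _r2(y, X):
    X1 = np.column_stack([np.ones(len(y)), X]) if X is not None else (
        np.ones((len(y), 1)))
    beta, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    rss = float(np.sum((y - X1 @ beta) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return max(0.0, 1.0 - rss / tss)


def variance_explained(qtls: list, means_df: pd.DataFrame, panel,
                       scope: str = "network") -> dict:
    """Phenotypic variance captured by a QTL set on adjusted means.

    ``scope="per-environment"``: within each environment, r2 of the
    regression of the means on all QTL peak indicators.  ``"network"``:
    r2 on environment-centred means with common peak effects.  Both report
    per-QTL partial r2 by leave-one-out difference.
    """
    if not qtls:
        raise ValueError("need at least one QTL")
    df = means_df.dropna(subset=["value"]).copy()
    sample_pos = {s: i for i, s in enumerate(panel.sample_ids)}
    xg = panel.b73_indicator()

    def xmat(sub, subset=None):
        use = qtls if subset is None else subset
        return np.column_stack([
            [xg[sample_pos[g], q.peak] for g in sub["genotype"]]
            for q in use
        ])

    out = {}
    if scope == "per-environment":
        for env, sub in df.groupby("environment", sort=True):
            y = sub["value"].to_numpy(dtype=float)
            full = _r2(y, xmat(sub))
            partial = {}
            for q in qtls:
                rest = [r for r in qtls if r is not q]
                r2_rest = _r2(y, xmat(sub, rest)) if rest else 0.0
                partial[q.peak] = full - r2_rest
            out[env] = {"r2": full, "partial_r2": partial}
    elif scope == "network":
        df["value_c"] = df["value"] - df.groupby("environment")[
            "value"].transform("mean")
        y = df["value_c"].to_numpy(dtype=float)
        full = _r2(y, xmat(df))
        partial = {}
        for q in qtls:
            rest = [r for r in qtls if r is not q]
            r2_rest = _r2(y, xmat(df, rest)) if rest else 0.0
            partial[q.peak] = full - r2_rest
        out = {"r2": full, "partial_r2": partial}
    else:
        raise ValueError("scope must be 'per-environment' or 'network'")
    return out
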