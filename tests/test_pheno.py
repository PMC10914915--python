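"""Adjusted means, generalized heritability, variance decomposition, PCA."""

import numpy as np
import pandas as pd
import pytest

from glaidyn.pheno import (adjusted_means, generalized_heritability,
                           trait_correlations, trait_pca,
                           variance_decomposition)


def _balanced_trial(rng, n_geno=60, block_effects=(0.0, 0.0), noise=0.0,
                    g_sd=1.0, n_cols=10, spatial=None):
    g = rng.normal(0.0, g_sd, n_geno)
    rows = []
    n_rows = int(np.ceil(n_geno / n_cols))
    for b, be in enumerate(block_effects, start=1):
        order = rng.permutation(n_geno)
        for k, gi in enumerate(order):
            r, c = divmod(k, n_cols)
            row = r + (b - 1) * n_rows
            val = g[gi] + be + rng.normal(0.0, noise)
            if spatial is not None:
                val += spatial[row, c]
            rows.append({"genotype": f"g{gi:03d}", "block": b,
                         "row": row, "col": c, "y": val})
    return pd.DataFrame(rows), pd.Series(g, index=[f"g{i:03d}"
                                                   for i in range(n_geno)])


def test_iid_limit_equals_raw_means():
    rng = np.random.default_rng(0)
    df, g = _balanced_trial(rng, noise=0.3)
    means, rec = adjusted_means(df, "y", rho_grid=[0.0])
    raw = df.groupby("genotype")["y"].mean()
    assert np.abs(means - raw.reindex(means.index)).max() < 1e-8


def test_block_offsets_exactly_removed():
    rng = np.random.default_rng(1)
    b = 2.5
    df, g = _balanced_trial(rng, block_effects=(b, -b), noise=0.0)
    means, _ = adjusted_means(df, "y", rho_grid=[0.0])
    # planted block offsets are +-b: the block-corrected genotype mean is
    # the true genotypic value (block effects average out exactly)
    assert np.abs(means - g.reindex(means.index)).max() < 1e-6


def test_spatial_model_beats_raw_means():
    """Under a planted AR1 x AR1 field the spatial GLS means are closer to
    the true genotype values than raw means, in most replicates."""
    wins = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n_rows, n_cols = 12, 10
        def ar1_chol(n, rho):
            idx = np.arange(n)
            return np.linalg.cholesky(
                rho ** np.abs(idx[:, None] - idx[None, :])
                + 1e-9 * np.eye(n))
        fld = 0.8 * (ar1_chol(n_rows, 0.5)
                     @ rng.standard_normal((n_rows, n_cols))
                     @ ar1_chol(n_cols, 0.5).T)
        df, g = _balanced_trial(rng, noise=0.2, spatial=fld, n_cols=n_cols)
        means, rec = adjusted_means(df, "y",
                                    rho_grid=[0.0, 0.3, 0.5, 0.7])
        raw = df.groupby("genotype")["y"].mean()
        truth = g.reindex(means.index)
        rmse_adj = np.sqrt(((means - truth) ** 2).mean())
        rmse_raw = np.sqrt(((raw.reindex(means.index) - truth) ** 2).mean())
        wins += rmse_adj <= rmse_raw
    assert wins >= 4


def test_h2_zero_when_no_genetic_variance():
    """Genotype means carry less spread than the replicate noise implies:
    the genotypic variance estimate hits zero and H2 = 0 by definition."""
    rows = []
    rng = np.random.default_rng(2)
    for i in range(60):
        sign = 1.0 if i % 2 == 0 else -1.0
        for b, s in ((1, sign), (2, -sign)):
            r, c = divmod(i, 10)
            rows.append({"genotype": f"g{i:03d}", "block": b,
                         "row": r + (b - 1) * 6, "col": c, "y": s})
    df = pd.DataFrame(rows)
    with pytest.warns(UserWarning, match="H2 = 0"):
        h2 = generalized_heritability(df, "y")
    assert h2 == 0.0


def test_h2_one_in_noiseless_limit():
    rng = np.random.default_rng(3)
    df, _ = _balanced_trial(rng, g_sd=1.0, noise=1e-4)
    assert generalized_heritability(df, "y") > 0.99


def test_h2_matches_balanced_closed_form():
    """Balanced iid two-replicate design: H2 = 1/(1 + se2/(r*sg2))."""
    vals = []
    for seed in range(5):
        rng = np.random.default_rng(40 + seed)
        df, _ = _balanced_trial(rng, n_geno=150, g_sd=1.0, noise=1.0)
        vals.append(generalized_heritability(df, "y"))
    assert np.mean(vals) == pytest.approx(1 / (1 + 1 / 2), abs=0.05)


def _network(rng, G=120, E=4, r=2, sg=2.0, sge=1.0, se=1.0):
    g = rng.normal(0, sg, G)
    rows = []
    for e in range(E):
        ge = rng.normal(0, sge, G)
        for rep in range(r):
            y = 5.0 * e + g + ge + rng.normal(0, se, G)
            rows.extend({"genotype": f"g{i:03d}", "environment": f"E{e}",
                         "value": y[i]} for i in range(G))
    return pd.DataFrame(rows)


def test_variance_components_recovered():
    rng = np.random.default_rng(5)
    vc = variance_decomposition(_network(rng, G=200, sg=2.0, sge=1.0, se=1.0))
    assert vc.sigma_g2 == pytest.approx(4.0, rel=0.35)
    assert vc.sigma_ge2 == pytest.approx(1.0, rel=0.45)
    assert vc.sigma_e2 == pytest.approx(1.0, rel=0.35)
    assert vc.p_genotype < 1e-6 and vc.p_gxe < 1e-6
    assert 0.0 <= vc.h2_network <= 1.0
    # CV_g definition: 100 * sigma_g / mean
    mu = _network(np.random.default_rng(5), G=200)["value"].mean()
    assert vc.cv_g == pytest.approx(100 * np.sqrt(vc.sigma_g2) / abs(mu),
                                    rel=1e-6)


def test_rlrt_null_gxe_not_overrejected():
    """With sigma_ge2 = 0 planted, the boundary-mixture RLRT rejects near
    its nominal 5% level."""
    rng = np.random.default_rng(6)
    rejections = 0
    n_reps = 40
    for _ in range(n_reps):
        df = _network(rng, G=50, E=3, r=2, sg=1.0, sge=0.0, se=1.0)
        vc = variance_decomposition(df)
        rejections += vc.p_gxe <= 0.05
    # 95% binomial envelope around 0.05 for 40 replicates
    assert rejections <= 8


def test_single_obs_per_cell_warns():
    rng = np.random.default_rng(7)
    df = _network(rng, G=30, E=2, r=1)
    with pytest.warns(UserWarning, match="confounded"):
        variance_decomposition(df, test=False)


def test_pca_matches_eigendecomposition():
    rng = np.random.default_rng(8)
    base = rng.standard_normal(200)
    X = pd.DataFrame({
        "a": base, "b": base + rng.normal(0, 1e-6, 200),
        "c": rng.standard_normal(200), "d": rng.standard_normal(200),
    })
    res = trait_pca(X)
    corr = np.corrcoef(((X - X.mean()) / X.std(ddof=1)).T)
    eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    # explained-variance fractions equal the correlation-matrix spectrum
    got = res["explained_variance_ratio"].to_numpy()
    want = eigvals / eigvals.sum()
    np.testing.assert_allclose(np.sort(got)[::-1], want, atol=1e-10)
    assert res["explained_variance_ratio"].sum() == pytest.approx(1.0)


def test_constant_trait_excluded():
    rng = np.random.default_rng(9)
    X = pd.DataFrame({"a": rng.standard_normal(50), "b": np.ones(50)})
    with pytest.warns(UserWarning, match="constant"):
        res = trait_pca(X)
    assert "b" not in res["loadings"].index


def test_pearson_self_correlation():
    rng = np.random.default_rng(10)
    X = pd.DataFrame({"a": rng.standard_normal(80),
                      "b": rng.standard_normal(80)})
    r, p = trait_correlations(X)
    assert r.loc["a", "a"] == 1.0
    assert r.loc["a", "b"] == r.loc["b", "a"]


def test_planted_correlation_recovered(sim_study):
    tt = sim_study["truth"].true_traits.query("environment == '16WW'")
    r, p = trait_correlations(tt[["GY", "AUC_S", "D_V"]])
    assert r.loc["GY", "AUC_S"] > 0.15
    assert p.loc["GY", "AUC_S"] < 0.05
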