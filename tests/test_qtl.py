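"""Backward QTL selection and variance explained."""

import numpy as np
import pandas as pd
import pytest

from glaidyn.clustering import SnpCluster
from glaidyn.qtl import backward_select_qtls, variance_explained


def _cluster(panel, marker, peak_p=1e-6):
    mk = panel.markers
    return SnpCluster(trait="T", environment="net",
                      chrom=int(mk["chrom"].iloc[marker]), members=[marker],
                      peak=marker, peak_p=peak_p,
                      start=int(mk["pos"].iloc[marker]),
                      end=int(mk["pos"].iloc[marker]) + 1)


def _simulate_means(panel, rng, qtl_marker=None, effect=0.0, envs=4,
                    g_sd=0.7, e_sd=0.7, env_effects=None):
    x = panel.b73_indicator()
    g = rng.normal(0, g_sd, panel.n_samples)
    rows = []
    for e in range(envs):
        beta = effect if env_effects is None else env_effects[e]
        y = g + rng.normal(0, e_sd, panel.n_samples)
        if qtl_marker is not None:
            y = y + beta * x[:, qtl_marker]
        rows.extend({"genotype": s, "environment": f"E{e}", "value": v}
                    for s, v in zip(panel.sample_ids, y))
    return pd.DataFrame(rows)


def test_empty_candidates_give_empty_result(small_panel):
    means = _simulate_means(small_panel, np.random.default_rng(0))
    assert backward_select_qtls([], means, small_panel) == []


@pytest.fixture(scope="module")
def balanced_marker(small_panel):
    freqs = small_panel.b73_indicator().mean(axis=0)
    return int(np.argmin(np.abs(freqs - 0.5)))


def test_planted_qtl_retained_decoys_dropped(small_panel, balanced_marker):
    rng = np.random.default_rng(1)
    retained, decoys = 0, 0
    n_seeds = 10
    freqs = small_panel.b73_indicator().mean(axis=0)
    usable = np.flatnonzero((freqs > 0.2) & (freqs < 0.8))
    for _ in range(n_seeds):
        means = _simulate_means(small_panel, rng, qtl_marker=balanced_marker,
                                effect=0.5, g_sd=0.5, e_sd=0.5)
        decoy_markers = rng.choice(usable[usable != balanced_marker], 5,
                                   replace=False)
        cands = [_cluster(small_panel, balanced_marker, 1e-9)]
        cands += [_cluster(small_panel, int(m), 1e-4) for m in decoy_markers]
        qtls = backward_select_qtls(cands, means, small_panel)
        peaks = {q.peak for q in qtls}
        retained += balanced_marker in peaks
        decoys += len(peaks - {balanced_marker})
    assert retained >= 9
    assert decoys / n_seeds <= 2 * 0.01 * 5 + 0.5  # near-alpha decoy rate


def test_single_environment_effect_localised(small_panel, balanced_marker):
    """An effect planted only in environment 1 yields a per-environment
    Wald significance in that environment."""
    hits_e0, hits_other = 0, 0
    rng = np.random.default_rng(2)
    for _ in range(5):
        means = _simulate_means(small_panel, rng, qtl_marker=balanced_marker,
                                env_effects=[0.8, 0.0, 0.0, 0.0],
                                g_sd=0.5, e_sd=0.5)
        qtls = backward_select_qtls([_cluster(small_panel, balanced_marker)],
                                    means, small_panel, alpha=0.05)
        for q in qtls:
            sig = q.effects["significant"]
            hits_e0 += bool(sig.loc["E0"])
            hits_other += int(sig.loc[["E1", "E2", "E3"]].sum())
    assert hits_e0 >= 4
    assert hits_other <= 3


def test_collinear_candidates_resolved(small_panel, balanced_marker):
    """Two distinct markers with identical genotype vectors collapse to the
    candidate with the smaller peak p."""
    import copy
    panel = copy.copy(small_panel)
    panel.dosage = small_panel.dosage.copy()
    panel.markers = small_panel.markers.copy()
    other = balanced_marker + 1
    panel.dosage[:, other] = panel.dosage[:, balanced_marker]
    fa = small_panel.founder_alleles.copy()
    fa[:, other] = fa[:, balanced_marker]
    panel.founder_alleles = fa
    rng = np.random.default_rng(3)
    means = _simulate_means(panel, rng, qtl_marker=balanced_marker,
                            effect=0.8, g_sd=0.3, e_sd=0.3)
    dup = _cluster(panel, other, peak_p=1e-3)
    best = _cluster(panel, balanced_marker, peak_p=1e-9)
    with pytest.warns(UserWarning, match="collinear"):
        qtls = backward_select_qtls([dup, best], means, panel)
    assert {q.peak for q in qtls} == {balanced_marker}


def test_selection_is_order_invariant(small_panel, balanced_marker):
    rng = np.random.default_rng(4)
    means = _simulate_means(small_panel, rng, qtl_marker=balanced_marker,
                            effect=0.5)
    freqs = small_panel.b73_indicator().mean(axis=0)
    usable = np.flatnonzero((freqs > 0.25) & (freqs < 0.75))
    others = [int(m) for m in usable[:4] if m != balanced_marker][:3]
    cands = [_cluster(small_panel, balanced_marker, 1e-9)]
    cands += [_cluster(small_panel, m, 1e-4) for m in others]
    a = backward_select_qtls(list(cands), means, small_panel)
    b = backward_select_qtls(list(reversed(cands)), means, small_panel)
    assert [q.peak for q in a] == [q.peak for q in b]


def test_variance_explained_exact_linear(small_panel, balanced_marker):
    x = small_panel.b73_indicator()[:, balanced_marker]
    rows = [{"genotype": s, "environment": "E0", "value": 2.0 * xi + 1.0}
            for s, xi in zip(small_panel.sample_ids, x)]
    means = pd.DataFrame(rows)
    q = backward_select_qtls([_cluster(small_panel, balanced_marker)],
                             means, small_panel)
    res = variance_explained(q, means, small_panel, scope="per-environment")
    assert res["E0"]["r2"] > 1 - 1e-8


def test_variance_explained_null_is_small(small_panel):
    rng = np.random.default_rng(5)
    freqs = small_panel.b73_indicator().mean(axis=0)
    usable = np.flatnonzero((freqs > 0.2) & (freqs < 0.8))
    low = 0
    for seed in range(5):
        rng2 = np.random.default_rng(50 + seed)
        means = _simulate_means(small_panel, rng2, envs=1)
        qtls = [SnpCluster(trait="T", environment="e", chrom=1, members=[m],
                           peak=int(m), peak_p=1e-3, start=1, end=2)
                for m in rng2.choice(usable, 5, replace=False)]
        from glaidyn.qtl import Qtl
        fake = [Qtl(trait="T", chrom=1, peak=c.peak, peak_pos=1, start=1,
                    end=2, joint_p=1.0,
                    effects=pd.DataFrame({"beta": [0.0], "se": [1.0],
                                          "p": [1.0],
                                          "significant": [False]},
                                         index=["E0"]))
                for c in qtls]
        r2 = variance_explained(fake, means, small_panel,
                                scope="per-environment")["E0"]["r2"]
        low += r2 <= 0.08
    assert low >= 4


def test_variance_explained_requires_qtls(small_panel):
    with pytest.raises(ValueError, match="at least one"):
        variance_explained([], pd.DataFrame(), small_panel)
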