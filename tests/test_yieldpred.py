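"""Grain-yield prediction from GLAI QTLs across a drought network."""

import numpy as np
import pandas as pd
import pytest

from glaidyn.qtl import Qtl, variance_explained
from glaidyn.synthetic import simulate_gy_network
from glaidyn.yieldpred import predict_gy_from_glai_qtls, unique_regions


def _fake_qtl(panel, marker, trait="GLAI_M", joint_p=1e-6, pad=10_000):
    mk = panel.markers
    pos = int(mk["pos"].iloc[marker])
    eff = pd.DataFrame({"beta": [0.3], "se": [0.1], "p": [1e-4],
                        "significant": [True]}, index=["E0"])
    return Qtl(trait=trait, chrom=int(mk["chrom"].iloc[marker]), peak=marker,
               peak_pos=pos, start=pos - pad, end=pos + pad, joint_p=joint_p,
               effects=eff)


def test_unique_regions_merge_overlaps(small_panel):
    mk = small_panel.markers
    on1 = np.flatnonzero(mk["chrom"].to_numpy() == 1)
    a, b = int(on1[0]), int(on1[1])
    qa = _fake_qtl(small_panel, a, "GLAI_M", joint_p=1e-8,
                   pad=abs(int(mk["pos"].iloc[b]) - int(mk["pos"].iloc[a])))
    qb = _fake_qtl(small_panel, b, "AUC_S", joint_p=1e-4, pad=10_000)
    regions = unique_regions([qa, qb])
    assert len(regions) == 1
    assert regions[0].peak == a  # smallest joint p wins
    far = int(on1[len(on1) // 2])
    qc = _fake_qtl(small_panel, far, "D_S")
    assert len(unique_regions([qa, qb, qc])) == 2


@pytest.fixture(scope="module")
def planted_network(small_panel):
    freqs = small_panel.b73_indicator().mean(axis=0)
    usable = np.flatnonzero((freqs > 0.25) & (freqs < 0.75))
    mk = small_panel.markers
    chosen = [int(usable[i]) for i in (0, len(usable) // 2, -1)]
    markers = [(int(mk["chrom"].iloc[m]), int(mk["pos"].iloc[m]))
               for m in chosen]
    gy, truth = simulate_gy_network(small_panel, markers, n_envs=11,
                                    qtl_r2=0.18, seed=21)
    gy = gy.rename(columns={"GY": "value"})
    return {"markers": chosen, "gy": gy, "truth": truth}


def test_planted_architecture_recovered(small_panel, planted_network):
    qtls = [_fake_qtl(small_panel, m) for m in planted_network["markers"]]
    res = predict_gy_from_glai_qtls(qtls, planted_network["gy"], small_panel)
    assert len(res.selected) >= 2
    assert res.network_r2 == pytest.approx(0.18, abs=0.08)
    assert all(0 <= v <= 1 for v in res.per_env_r2.values())
    # heritability heterogeneity was planted in the stated range
    h2 = planted_network["truth"]["h2_per_env"]
    assert h2.min() >= 0.55 and h2.max() <= 0.85


def test_null_candidates_explain_little(small_panel):
    rng = np.random.default_rng(5)
    gy, _ = simulate_gy_network(small_panel, [], n_envs=6, qtl_r2=0.0,
                                seed=22)
    gy = gy.rename(columns={"GY": "value"})
    freqs = small_panel.b73_indicator().mean(axis=0)
    usable = np.flatnonzero((freqs > 0.25) & (freqs < 0.75))
    qtls = [_fake_qtl(small_panel, int(m), joint_p=1e-3)
            for m in rng.choice(usable, 4, replace=False)]
    res = predict_gy_from_glai_qtls(qtls, gy, small_panel)
    # selection at alpha=0.05 admits some overfit r2 of order k/n at this
    # panel size (120 genotypes)
    assert res.network_r2 <= 0.08


def test_sign_flipping_effect_recovered(small_panel):
    """A QTL whose yield effect reverses sign between environments is still
    selected and the per-environment signs are recovered."""
    freqs = small_panel.b73_indicator().mean(axis=0)
    m = int(np.argmin(np.abs(freqs - 0.5)))
    mk = small_panel.markers
    marker = (int(mk["chrom"].iloc[m]), int(mk["pos"].iloc[m]))
    gy, truth = simulate_gy_network(
        small_panel, [marker], n_envs=6, qtl_r2=0.25,
        env_effect_sign_flip={marker: (0, 1)}, seed=23)
    gy = gy.rename(columns={"GY": "value"})
    res = predict_gy_from_glai_qtls([_fake_qtl(small_panel, m)], gy,
                                    small_panel)
    assert len(res.selected) == 1
    eff = res.selected[0].effects["beta"]
    signs = np.sign(eff.to_numpy())
    assert len(set(signs)) == 2  # both directions present


def test_network_r2_monotone_in_qtls(small_panel, planted_network):
    """Adding a genuinely associated QTL never decreases the nested-fit
    network r2."""
    gy = planted_network["gy"]
    qtls = [_fake_qtl(small_panel, m) for m in planted_network["markers"]]
    r2_nested = []
    for k in range(1, len(qtls) + 1):
        r2_nested.append(
            variance_explained(qtls[:k], gy, small_panel, "network")["r2"])
    assert all(b >= a - 1e-12 for a, b in zip(r2_nested, r2_nested[1:]))


def test_empty_candidates_yield_zero(small_panel, planted_network):
    res = predict_gy_from_glai_qtls([], planted_network["gy"], small_panel)
    assert res.network_r2 == 0.0 and res.selected == []
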