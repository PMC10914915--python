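"""Synthetic MAGIC panel and trial-phenotype generator."""

import numpy as np
import pytest

from glaidyn.kinship import ibs_kinship
from glaidyn.synthetic import (Environment, PlantedQtl, TruthConfig,
                               make_trial_design, simulate_magic_genotypes,
                               simulate_trial_phenotypes)


def test_dosages_are_homozygous(small_panel):
    assert set(np.unique(small_panel.dosage)) <= {0, 2}


def test_mosaics_tile_each_chromosome(small_panel):
    for sid in small_panel.sample_ids[:10]:
        for c, segs in small_panel.founder_mosaic[sid].items():
            assert segs[0][0] == 1
            assert segs[-1][1] == small_panel.chrom_lengths[c] + 1
            for (a0, a1, _), (b0, b1, _) in zip(segs, segs[1:]):
                assert a1 == b0  # no gap, no overlap


def test_no_recombination_gives_single_segments():
    panel = simulate_magic_genotypes(n_lines=20, n_chrom=2,
                                     n_markers_per_chrom=30,
                                     recomb_rate=0.0, seed=1)
    for sid in panel.sample_ids:
        for segs in panel.founder_mosaic[sid].values():
            assert len(segs) == 1


def test_same_seed_is_bit_identical():
    a = simulate_magic_genotypes(n_lines=30, n_chrom=2,
                                 n_markers_per_chrom=40, seed=9)
    b = simulate_magic_genotypes(n_lines=30, n_chrom=2,
                                 n_markers_per_chrom=40, seed=9)
    assert np.array_equal(a.dosage, b.dosage)
    assert a.markers.equals(b.markers)


def test_maf_filter_boundary(small_panel):
    assert small_panel.maf().min() >= 0.035
    # same seed without the filter shows markers that the filter removed
    raw = simulate_magic_genotypes(n_lines=120, n_chrom=3,
                                   n_markers_per_chrom=80, seed=101,
                                   maf_threshold=0.0)
    assert (raw.maf() < 0.035).any()
    assert raw.n_markers > small_panel.n_markers


def test_degenerate_frequencies_fail_loudly():
    with pytest.raises(ValueError, match="MAF filter"):
        simulate_magic_genotypes(n_lines=20, n_chrom=1,
                                 n_markers_per_chrom=10,
                                 founder_freq_range=(0.0001, 0.0002), seed=2)


def test_design_layout_invariants(small_panel):
    design = make_trial_design(small_panel.sample_ids, seed=5)
    for env, sub in design.plots.groupby("environment"):
        assert sub.groupby("genotype")["block"].nunique().max() <= 2
        assert not sub.duplicated(["row", "col"]).any()
        # every genotype replicated once per block
        assert (sub.groupby(["genotype", "block"]).size() == 1).all()


def test_degenerate_generator_identical_curves(small_panel):
    cfg = TruthConfig(
        genetic_sd={k: 0.0 for k in TruthConfig().genetic_sd},
        gxe_sd={k: 0.0 for k in TruthConfig().gxe_sd},
        qtls=[],
    )
    envs = [Environment("WW", 2016, "WW", None)]
    design = make_trial_design(small_panel.sample_ids[:30], envs, seed=6)
    obs, agro, truth = simulate_trial_phenotypes(small_panel, design, cfg,
                                                 seed=7)
    tt = truth.true_traits[truth.true_traits["environment"] == "WW"]
    for col in ("GLAI_M", "AUC_C", "D_C"):
        assert tt[col].nunique() == 1


def test_planted_qtl_effect_recovered_on_true_traits(sim_study):
    panel = sim_study["panel"]
    truth = sim_study["truth"]
    i1 = sim_study["qtl_markers"][0]
    x = panel.b73_indicator()[:, i1]
    tt = truth.true_traits[truth.true_traits["environment"] == "16WW"]
    tt = tt.set_index("genotype").loc[panel.sample_ids]
    diff = tt["GLAI_M"][x == 1].mean() - tt["GLAI_M"][x == 0].mean()
    assert diff == pytest.approx(0.4, abs=0.1)


def test_wd_stress_reduces_glai_max(sim_study):
    truth = sim_study["truth"]
    ww = truth.true_traits.query("environment == '16WW'")["GLAI_M"].mean()
    wd = truth.true_traits.query("environment == '16WD'")["GLAI_M"].mean()
    assert wd / ww == pytest.approx(0.80, abs=0.03)


def test_gy_tracks_stay_green_area(sim_study):
    tt = sim_study["truth"].true_traits.query("environment == '16WW'")
    r = np.corrcoef(tt["GY"], tt["AUC_S"])[0, 1]
    assert r > 0.2  # positive whenever the AUC_S weight is positive


def test_planted_qtl_must_be_on_retained_marker(small_panel):
    cfg = TruthConfig(qtls=[PlantedQtl(1, 1, "glai_max", 0.3)])
    envs = [Environment("WW", 2016, "WW", None)]
    design = make_trial_design(small_panel.sample_ids[:10], envs, seed=8)
    with pytest.raises(KeyError, match="not in panel"):
        simulate_trial_phenotypes(small_panel, design, cfg, seed=9)


def test_family_structure_shows_in_kinship(small_panel):
    K = ibs_kinship(small_panel.dosage)
    fam = small_panel.families
    same = K[np.equal.outer(fam, fam) & ~np.eye(len(fam), dtype=bool)]
    diff = K[~np.equal.outer(fam, fam)]
    assert same.mean() > diff.mean()
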