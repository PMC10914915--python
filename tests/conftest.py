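import numpy as np
import pytest

from glaidyn.kinship import loco_kinships
from glaidyn.synthetic import (Environment, PlantedQtl, TruthConfig,
                               make_trial_design, simulate_magic_genotypes,
                               simulate_trial_phenotypes)


@pytest.fixture(scope="session")
def small_panel():
    """120 DH lines, 3 chromosomes, ~230 retained markers."""
    return simulate_magic_genotypes(n_lines=120, n_chrom=3,
                                    n_markers_per_chrom=80, seed=101)


@pytest.fixture(scope="session")
def small_kinships(small_panel):
    return loco_kinships(small_panel)


@pytest.fixture(scope="session")
def sim_study(small_panel):
    """Two-environment trial with planted QTLs on GLAI_M and senescence
    timing, plus a direct grain-yield QTL."""
    panel = small_panel
    mk = panel.markers
    freqs = panel.b73_indicator().mean(axis=0)
    # balanced markers on different chromosomes
    i1 = int(np.argmin(np.abs(freqs - 0.5)))
    on2 = np.flatnonzero(mk["chrom"].to_numpy() == 2)
    i2 = int(on2[np.argmin(np.abs(freqs[on2] - 0.5))])
    qtls = [
        PlantedQtl(int(mk["chrom"][i1]), int(mk["pos"][i1]), "glai_max", 0.4),
        PlantedQtl(int(mk["chrom"][i2]), int(mk["pos"][i2]), "tau_s", 80.0),
        PlantedQtl(int(mk["chrom"][i1]), int(mk["pos"][i1]), "GY", 4.0),
    ]
    envs = [Environment("16WW", 2016, "WW", None),
            Environment("16WD", 2016, "WD", (900, 1600))]
    design = make_trial_design(panel.sample_ids, envs, seed=102)
    config = TruthConfig(qtls=qtls)
    obs, agro, truth = simulate_trial_phenotypes(panel, design, config,
                                                 seed=103)
    return {"panel": panel, "design": design, "config": config,
            "obs": obs, "agro": agro, "truth": truth,
            "qtl_markers": [i1, i2]}
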