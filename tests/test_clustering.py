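"""LD clustering of significant SNPs and interval extension."""

import numpy as np
import pandas as pd
import pytest

from glaidyn.clustering import (SnpCluster, _r2_vector, cluster_snps,
                                extend_interval)
from glaidyn.synthetic import GenotypePanel


def _toy_panel(columns, positions, chrom_len=1_000_000):
    """Panel with hand-built dosage columns on one chromosome."""
    dosage = np.column_stack(columns).astype(np.int8)
    markers = pd.DataFrame({
        "chrom": 1, "pos": positions, "ref": "A", "alt": "T",
        "is_b73_allele": True,
    })
    return GenotypePanel(sample_ids=[f"s{i}" for i in range(dosage.shape[0])],
                         markers=markers, dosage=dosage,
                         chrom_lengths={1: chrom_len})


def test_perfect_ld_forms_one_cluster():
    x = np.array([0, 0, 2, 2, 0, 2, 0, 2])
    panel = _toy_panel([x, x], [1000, 5000])
    sig = pd.DataFrame({"chrom": [1, 1], "pos": [1000, 5000],
                        "p": [1e-8, 1e-6]})
    cls = cluster_snps(sig, panel)
    assert len(cls) == 1
    assert cls[0].peak == 0  # smaller p
    assert cls[0].start == 1000 and cls[0].end == 5001


def test_unlinked_markers_form_two_clusters():
    rng = np.random.default_rng(0)
    x = rng.choice([0, 2], 40)
    y = rng.choice([0, 2], 40)
    while abs(np.corrcoef(x, y)[0, 1]) > 0.2:
        y = rng.choice([0, 2], 40)
    panel = _toy_panel([x, y], [1000, 500_000])
    sig = pd.DataFrame({"chrom": [1, 1], "pos": [1000, 500_000],
                        "p": [1e-8, 1e-6]})
    cls = cluster_snps(sig, panel)
    assert len(cls) == 2


def test_span_filter_discards_wide_cluster():
    x = np.array([0, 0, 2, 2, 0, 2, 0, 2])
    # two perfectly linked markers spanning 35% of a 1 Mb chromosome
    panel = _toy_panel([x, x], [100_000, 450_000])
    sig = pd.DataFrame({"chrom": [1, 1], "pos": [100_000, 450_000],
                        "p": [1e-8, 1e-7]})
    cls = cluster_snps(sig, panel)
    assert len(cls) == 1
    assert cls[0].discarded and cls[0].reason == "span"
    # at 25% span the same pair is kept
    panel2 = _toy_panel([x, x], [100_000, 350_000])
    sig2 = pd.DataFrame({"chrom": [1, 1], "pos": [100_000, 350_000],
                         "p": [1e-8, 1e-7]})
    assert not cluster_snps(sig2, panel2)[0].discarded


def test_overlapping_clusters_aggregate():
    """Two seeds whose member intervals overlap merge into one cluster."""
    rng = np.random.default_rng(1)
    a = rng.choice([0, 2], 60)
    b = a.copy(); b[:6] = 2 - b[:6]        # high LD with a
    c = rng.choice([0, 2], 60)
    d = c.copy(); d[:6] = 2 - d[:6]
    # positions interleave so [a..b] and [c..d] intervals overlap
    panel = _toy_panel([a, c, b, d], [1000, 2000, 3000, 4000])
    sig = pd.DataFrame({"chrom": [1] * 4, "pos": [1000, 2000, 3000, 4000],
                        "p": [1e-9, 1e-8, 1e-7, 1e-6]})
    cls = cluster_snps(sig, panel)
    assert len(cls) == 1
    assert sorted(cls[0].members) == [0, 1, 2, 3]


@pytest.mark.parametrize("method", ["greedy", "chain"])
def test_clustering_partitions_significant_markers(small_panel, method):
    rng = np.random.default_rng(2)
    mk = small_panel.markers
    take = rng.choice(small_panel.n_markers, 60, replace=False)
    sig = pd.DataFrame({"chrom": mk["chrom"].iloc[take],
                        "pos": mk["pos"].iloc[take],
                        "p": rng.uniform(1e-10, 1e-3, 60)})
    cls = cluster_snps(sig, small_panel, method=method)
    all_members = [m for c in cls for m in c.members]
    assert sorted(all_members) == sorted(set(all_members))
    assert set(all_members) == set(take.tolist())
    for c in cls:
        assert c.peak in c.members
        pos = mk["pos"].to_numpy()
        assert all(c.start <= pos[m] < c.end for m in c.members)


def test_extend_interval_rules():
    x = np.array([0, 0, 2, 2, 0, 2, 0, 2] * 5)
    rng = np.random.default_rng(3)
    unrelated = rng.choice([0, 2], 40)
    linked = x.copy(); linked[:3] = 2 - linked[:3]
    # cluster at [200k, 300k); linked marker 50 kb right, unrelated left
    panel = _toy_panel([unrelated, x, x, linked],
                       [150_000, 200_000, 300_000, 350_000])
    cl = SnpCluster(trait="t", environment="e", chrom=1, members=[1, 2],
                    peak=1, peak_p=1e-8, start=200_000, end=300_001)
    start, end = extend_interval(cl, panel)
    assert start == 200_000            # no qualifying marker on the left
    assert end == 350_001              # extended by the linked marker


def test_extend_interval_matches_brute_force(small_panel):
    rng = np.random.default_rng(4)
    mk = small_panel.markers
    pos = mk["pos"].to_numpy()
    chrom = mk["chrom"].to_numpy()
    for _ in range(20):
        m = int(rng.integers(0, small_panel.n_markers))
        cl = SnpCluster(trait="t", environment="e", chrom=int(chrom[m]),
                        members=[m], peak=m, peak_p=1e-8,
                        start=int(pos[m]), end=int(pos[m]) + 1)
        start, end = extend_interval(cl, small_panel, window=2_000_000)
        # brute force over every marker in the window
        best_s, best_e = cl.start, cl.end
        for j in range(small_panel.n_markers):
            if chrom[j] != cl.chrom or j == m:
                continue
            r2 = _r2_vector(small_panel.dosage, m, np.array([j]))[0]
            if r2 >= 0.6:
                if cl.start - 2_000_000 <= pos[j] < cl.start:
                    best_s = min(best_s, int(pos[j]))
                if cl.end <= pos[j] < cl.end + 2_000_000:
                    best_e = max(best_e, int(pos[j]) + 1)
        assert (start, end) == (best_s, best_e)


def test_discarded_cluster_cannot_extend():
    x = np.array([0, 2] * 4)
    panel = _toy_panel([x], [1000])
    cl = SnpCluster(trait="t", environment="e", chrom=1, members=[0], peak=0,
                    peak_p=1e-8, start=1000, end=1001, discarded=True,
                    reason="span")
    with pytest.raises(ValueError, match="discarded"):
        extend_interval(cl, panel)


def test_empty_input_gives_empty_list(small_panel):
    sig = pd.DataFrame(columns=["chrom", "pos", "p"])
    assert cluster_snps(sig, small_panel) == []
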