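"""Grain-yield variance explained by GLAI QTLs across a drought network.

The GLAI QTLs from the reference trials are first reduced to unique genomic
regions (connected components of the interval-overlap graph, one
representative peak per region — the smallest joint p).  The regions then
enter the multi-environment backward-selection model against grain yield
adjusted means over the larger water-deficit network, at the less
conservative alpha = 0.05 appropriate for candidates that already survived
one selection; the result quantifies how much yield variance the GLAI
genetic architecture captures, per environment and network-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import SnpCluster
from .qtl import backward_select_qtls, variance_explained

GY_ALPHA = 0.05


@dataclass
class YieldNetworkResult:
    selected: list                 # surviving Qtl objects
    network_r2: float
    per_env_r2: dict               # env -> r2
    per_env_significant: dict      # env -> number of QTLs with Wald p <= alpha
    effects: pd.DataFrame          # long: peak, environment, beta, se, p
    candidate_regions: list        # (chrom, start, end, peak) before selection


def unique_regions(qtls: list) -> list:
    """Merge overlapping QTL intervals into unique regions.

    Returns one representative :class:`SnpCluster`-like candidate per
    region, carrying the peak of the member QTL with the smallest joint p.
    """
    regions = []
    for chrom in sorted({q.chrom for q in qtls}):
        members = sorted((q for q in qtls if q.chrom == chrom),
                         key=lambda q: (q.start, q.end))
        current = []
        cur_end = None
        for q in members:
            if current and q.start < cur_end:
                current.append(q)
                cur_end = max(cur_end, q.end)
            else:
                if current:
                    regions.append(current)
                current = [q]
                cur_end = q.end
        if current:
            regions.append(current)
    out = []
    for group in regions:
        rep = min(group, key=lambda q: (q.joint_p, q.peak_pos))
        out.append(SnpCluster(
            trait="+".join(sorted({q.trait for q in group})),
            environment="network", chrom=rep.chrom,
            members=sorted({q.peak for q in group}),
            peak=rep.peak, peak_p=rep.joint_p,
            start=min(q.start for q in group),
            end=max(q.end for q in group),
            source="GLAI_QTL",
        ))
    return out


def predict_gy_from_glai_qtls(
    glai_qtls: list,
    gy_means: pd.DataFrame,
    panel,
    alpha: float = GY_ALPHA,
) -> YieldNetworkResult:
    """Backward selection of GLAI QTLs on network grain-yield means.

    ``gy_means`` is a long table (genotype, environment, value) of GY
    adjusted means over the water-deficit network.  Returns the selected
    subset with network and per-environment r2 (fixed-effects refit on
    peak indicators) and per-environment significant-QTL counts.
    """
    regions = unique_regions(glai_qtls) if glai_qtls else []
    selected = backward_select_qtls(regions, gy_means, panel, trait="GY",
                                    alpha=alpha)
    envs = sorted(gy_means["environment"].unique())
    if not selected:
        return YieldNetworkResult(
            selected=[], network_r2=0.0,
            per_env_r2={e: 0.0 for e in envs},
            per_env_significant={e: 0 for e in envs},
            effects=pd.DataFrame(columns=["peak", "environment", "beta",
                                          "se", "p"]),
            candidate_regions=[(r.chrom, r.start, r.end, r.peak)
                               for r in regions],
        )
    net = variance_explained(selected, gy_means, panel, scope="network")
    per_env = variance_explained(selected, gy_means, panel,
                                 scope="per-environment")
    eff_rows = []
    sig_counts = {}
    for e in envs:
        cnt = 0
        for q in selected:
            rec = q.effects.loc[e]
            eff_rows.append({"peak": q.peak, "environment": e,
                             "beta": rec["beta"], "se": rec["se"],
                             "p": rec["p"]})
            if rec["p"] <= alpha:
                cnt += 1
        sig_counts[e] = cnt
    return YieldNetworkResult(
        selected=selected,
        network_r2=float(net["r2"]),
        per_env_r2={e: float(per_env[e]["r2"]) for e in envs},
        per_env_significant=sig_counts,
        effects=pd.DataFrame(eff_rows),
        candidate_regions=[(r.chrom, r.start, r.end, r.peak)
                           for r in regions],
    )
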