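"""Linkage-disequilibrium clustering of significant SNPs.

Significant markers of one trait-environment combination are grouped per
chromosome: the most significant unassigned marker seeds a cluster that
absorbs every unassigned significant marker with pairwise LD R^2 above a
threshold (0.6 by default); clusters whose physical intervals overlap are
then aggregated.  Clusters spanning more than 30% of their chromosome are
discarded as artifacts.  Each cluster is described by its peak SNP
(smallest p, ties to the smaller position) and the half-open base-pair
interval covered by its members.  A single-linkage chaining variant is
available behind ``method="chain"``.

LD R^2 is the squared Pearson correlation of allele dosages, which is the
appropriate measure for fully homozygous lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LD_R2_THRESHOLD = 0.6
MAX_SPAN_FRACTION = 0.30


@dataclass
class SnpCluster:
    trait: str
    environment: str
    chrom: int
    members: list          # marker indices into the panel
    peak: int              # marker index of the smallest-p member
    peak_p: float
    start: int             # bp, half-open [start, end)
    end: int
    source: str = "M_ALL"  # M_UV, M_MV or M_ALL
    discarded: bool = False
    reason: Optional[str] = None

    @property
    def span(self) -> int:
        return self.end - self.start - 1


def ld_r2(dosage: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation between two dosage columns."""
    x, y = dosage[:, i], dosage[:, j]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_vector(dosage, seed_idx, others):
    x = dosage[:, seed_idx].astype(float)
    Y = dosage[:, others].astype(float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * np.einsum("ij,ij->j", Yc, Yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / denom
    r = np.nan_to_num(r)
    return r * r


def _merge_overlapping(groups, positions):
    """Aggregate clusters whose [start, end) intervals overlap."""
    ivals = []
    for g in groups:
        pos = positions[g]
        ivals.append((int(pos.min()), int(pos.max()) + 1, g))
    ivals.sort(key=lambda t: (t[0], t[1]))
    merged = []
    for start, end, g in ivals:
        if merged and start < merged[-1][1]:
            ps, pe, pg = merged[-1]
            merged[-1] = (ps, max(pe, end), pg + g)
        else:
            merged.append((start, end, list(g)))
    return merged


def cluster_snps(
    significant: pd.DataFrame,
    panel,
    trait: str = "trait",
    environment: str = "env",
    source: str = "M_ALL",
    r2_threshold: float = LD_R2_THRESHOLD,
    max_span_frac: float = MAX_SPAN_FRACTION,
    method: str = "greedy",
) -> list:
    """Cluster the significant markers of one trait-environment combination.

    ``significant`` needs columns chrom, pos, p; markers are matched to the
    panel map.  Returns a list of :class:`SnpCluster` (discarded clusters
    included, flagged)."""
    if significant.empty:
        return []
    pos_all = panel.markers["pos"].to_numpy()
    chrom_all = panel.markers["chrom"].to_numpy()
    lookup = {(int(c), int(p)): i
              for i, (c, p) in enumerate(zip(chrom_all, pos_all))}
    idx = np.array([lookup[(int(c), int(p))]
                    for c, p in zip(significant["chrom"], significant["pos"])])
    pvals = significant["p"].to_numpy(dtype=float)

    clusters = []
    for c in np.unique(chrom_all[idx]):
        sel = np.flatnonzero(chrom_all[idx] == c)
        midx = idx[sel]
        mp = pvals[sel]
        order = np.lexsort((pos_all[midx], mp))  # by p then position
        if method == "greedy":
            unassigned = np.ones(midx.size, dtype=bool)
            groups = []
            for k in order:
                if not unassigned[k]:
                    continue
                cand = np.flatnonzero(unassigned)
                r2 = _r2_vector(panel.dosage, midx[k], midx[cand])
                take = cand[r2 >= r2_threshold]
                if k not in take:
                    take = np.append(take, k)
                groups.append([int(midx[j]) for j in take])
                unassigned[take] = False
        elif method == "chain":
            # single-linkage connected components over the R^2 graph
            D = panel.dosage[:, midx].astype(float)
            Dc = D - D.mean(axis=0)
            norms = np.sqrt(np.einsum("ij,ij->j", Dc, Dc))
            norms[norms == 0] = 1.0
            R = (Dc.T @ Dc) / np.outer(norms, norms)
            adj = R ** 2 >= r2_threshold
            seen = np.zeros(midx.size, dtype=bool)
            groups = []
            for k in range(midx.size):
                if seen[k]:
                    continue
                stack, comp = [k], []
                seen[k] = True
                while stack:
                    u = stack.pop()
                    comp.append(u)
                    for v in np.flatnonzero(adj[u] & ~seen):
                        seen[v] = True
                        stack.append(v)
                groups.append([int(midx[j]) for j in comp])
        else:
            raise ValueError(f"unknown clustering method {method!r}")

        p_by_idx = {int(m): float(p) for m, p in zip(midx, mp)}
        for start, end, members in _merge_overlapping(groups, pos_all):
            members = sorted(set(members))
            peak = min(members, key=lambda m: (p_by_idx[m], pos_all[m]))
            span = end - start - 1
            chrom_len = panel.chrom_lengths[int(c)]
            discarded = span > max_span_frac * chrom_len
            clusters.append(SnpCluster(
                trait=trait, environment=environment, chrom=int(c),
                members=members, peak=int(peak), peak_p=p_by_idx[peak],
                start=int(start), end=int(end), source=source,
                discarded=bool(discarded),
                reason="span" if discarded else None,
            ))
    clusters.sort(key=lambda cl: (cl.chrom, cl.start))
    return clusters


def extend_interval(
    cluster: SnpCluster,
    panel,
    r2_threshold: float = LD_R2_THRESHOLD,
    window: int = 1_000_000,
) -> tuple:
    """Extend a cluster interval by the local LD extent at each extremity.

    At each end the markers within ``window`` bp outward are scanned; the
    interval is pushed to the most distant marker whose R^2 with the
    extremity member reaches the threshold.  Returns the (start, end)
    half-open extended interval.
    """
    if cluster.discarded:
        raise ValueError("cannot extend a discarded cluster")
    pos = panel.markers["pos"].to_numpy()
    chrom = panel.markers["chrom"].to_numpy()
    on_c = chrom == cluster.chrom
    left_member = min(cluster.members, key=lambda m: pos[m])
    right_member = max(cluster.members, key=lambda m: pos[m])

    start, end = cluster.start, cluster.end
    left_zone = np.flatnonzero(on_c & (pos < start) & (pos >= start - window))
    if left_zone.size:
        r2 = _r2_vector(panel.dosage, left_member, left_zone)
        good = left_zone[r2 >= r2_threshold]
        if good.size:
            start = int(pos[good].min())
    right_zone = np.flatnonzero(on_c & (pos >= end) & (pos < end + window))
    if right_zone.size:
        r2 = _r2_vector(panel.dosage, right_member, right_zone)
        good = right_zone[r2 >= r2_threshold]
        if good.size:
            end = int(pos[good].max()) + 1
    return start, end
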