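"""Identity-by-state kinship for homozygous lines, global and LOCO.

K_ij is the fraction of markers at which lines i and j carry the same
(homozygous) genotype; missing genotypes are excluded pairwise.  Leave-one-
chromosome-out (LOCO) matrices exclude every marker on the focal chromosome
so that a tested marker never contributes to its own correction, avoiding
proximal contamination in mixed-model association scans.
"""

from __future__ import annotations

import numpy as np


def ibs_kinship(dosage: np.ndarray, marker_mask=None) -> np.ndarray:
    """IBS kinship from an n x m dosage matrix with values in {0, 2} (NaN
    allowed for missing calls).

    ``marker_mask`` selects the markers to include (boolean or index array).
    """
    X = np.asarray(dosage, dtype=float)
    if marker_mask is not None:
        X = X[:, marker_mask]
    if X.shape[1] == 0:
        raise ValueError("zero markers included in kinship computation")
    obs = np.isfinite(X)
    A = np.where(obs, X / 2.0, 0.0)  # alt-allele indicator, 0 where missing
    B = obs.astype(float) - A        # ref-allele indicator
    count_eq = A @ A.T + B @ B.T
    denom = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = count_eq / denom
    K[denom == 0] = np.nan
    return K


def loco_kinships(panel) -> dict:
    """Global + per-chromosome LOCO IBS kinships for a GenotypePanel.

    Returns {0: global K, c: K^(-c) for each chromosome c}.
    """
    chrom = panel.markers["chrom"].to_numpy()
    out = {0: ibs_kinship(panel.dosage)}
    for c in np.unique(chrom):
        mask = chrom != c
        if not mask.any():
            raise ValueError(f"no markers left when excluding chromosome {c}")
        out[int(c)] = ibs_kinship(panel.dosage, mask)
    return out
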