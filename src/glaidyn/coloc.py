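"""QTL colocalization: physical overlap of (extended) QTL intervals.

Two QTLs colocalize when their half-open intervals overlap on the same
chromosome; [100, 200) and [200, 300) touch but do not overlap.  For each
colocalized pair the direction concordance compares the signs of the
B73-allele effects in the environments where both QTLs are significant:
"same" when every shared significant environment agrees in sign,
"opposite" when every one disagrees, "mixed" otherwise, and None when the
two QTLs share no significant environment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .qtl import QTL_ALPHA


def intervals_overlap(a_start, a_end, b_start, b_end) -> bool:
    """Half-open interval overlap."""
    return a_start < b_end and b_start < a_end


def colocalize(qtls: list, alpha: float = QTL_ALPHA) -> pd.DataFrame:
    """All colocalized QTL pairs with effect-direction concordance.

    The relation is symmetric; each unordered pair appears once.
    """
    rows = []
    for qa, qb in itertools.combinations(qtls, 2):
        if qa.chrom != qb.chrom:
            continue
        if not intervals_overlap(qa.start, qa.end, qb.start, qb.end):
            continue
        shared = [e for e in qa.effects.index
                  if e in qb.effects.index
                  and qa.effects.loc[e, "p"] <= alpha
                  and qb.effects.loc[e, "p"] <= alpha]
        if shared:
            signs = [np.sign(qa.effects.loc[e, "beta"])
                     * np.sign(qb.effects.loc[e, "beta"]) for e in shared]
            if all(s > 0 for s in signs):
                concordance = "same"
            elif all(s < 0 for s in signs):
                concordance = "opposite"
            else:
                concordance = "mixed"
        else:
            concordance = None
        rows.append({
            "trait_a": qa.trait, "peak_a": qa.peak,
            "trait_b": qb.trait, "peak_b": qb.peak,
            "chrom": qa.chrom,
            "start_a": qa.start, "end_a": qa.end,
            "start_b": qb.start, "end_b": qb.end,
            "shared_significant_envs": len(shared),
            "direction": concordance,
        })
    return pd.DataFrame(rows, columns=[
        "trait_a", "peak_a", "trait_b", "peak_b", "chrom",
        "start_a", "end_a", "start_b", "end_b",
        "shared_significant_envs", "direction",
    ])
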