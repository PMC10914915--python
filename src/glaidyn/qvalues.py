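"""Storey false-discovery-rate q-values and a-posteriori trait assignment.

The null proportion pi0 is estimated with the smoother method: pi0(lambda)
is evaluated on lambda = 0.05, 0.10, ..., 0.95, a cubic smoother is fitted
through the points and read off at lambda = 0.95, then clipped to (0, 1].
q-values follow the usual step-up construction and are monotone
non-decreasing in p.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

SIGNIFICANCE_Q = 0.05  # q-value threshold for declaring an association

# chi2(1) quantile used for the per-trait a-posteriori Wald screen
TRAIT_ASSIGN_ALPHA = 0.01


def estimate_pi0(p: np.ndarray) -> float:
    """Smoother estimate of the proportion of true nulls.

    Falls back to 1.0 (with a warning) for fewer than 100 tests, where the
    smoother is unstable.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 100:
        warnings.warn("fewer than 100 p-values: pi0 fixed at 1", stacklevel=2)
        return 1.0
    lams = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lams])
    coef = np.polynomial.polynomial.polyfit(lams, pi0_lam, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(0.95, coef))
    return float(np.clip(pi0, np.finfo(float).tiny, 1.0))


def storey_qvalues(p, pi0: float | None = None):
    """q-values for a vector of p-values in (0, 1].

    Returns ``(q, pi0)``.  ``pi0`` may be forced (e.g. to 1 for a pure
    Benjamini-Hochberg behaviour).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), 1.0
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out, float(pi0)


def assign_mv_traits(beta: np.ndarray, se: np.ndarray,
                     alpha: float = TRAIT_ASSIGN_ALPHA):
    """Assign each jointly significant marker to the traits whose individual
    effect passes a Wald test at ``alpha``.

    ``beta`` and ``se`` are m x t.  Returns ``(assigned, unassigned)``: a
    list of per-marker trait-index tuples and a boolean flag for markers
    with an empty set.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    se = np.atleast_2d(np.asarray(se, dtype=float))
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z2 = (beta / se) ** 2
    hits = z2 > crit
    assigned = [tuple(np.flatnonzero(row)) for row in hits]
    unassigned = np.array([len(a) == 0 for a in assigned])
    return assigned, unassigned
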