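"""Bent-cable (quadratic-bend segmented) regression.

A bent cable is two straight lines joined by a quadratic arc of half-width
``gamma`` centred at ``tau``:

    f(t) = b0 + b1*t + b2 * q(t; tau, gamma)

with the bend basis

    q(t) = 0                          for t <= tau - gamma
    q(t) = (t - tau + gamma)^2/(4g)   for |t - tau| < gamma
    q(t) = t - tau                    for t >= tau + gamma.

The incoming slope is ``b1``, the outgoing slope ``b1 + b2`` and the abscissa
of the intersection of the two linear parts is ``tau``.  The fitted function
is continuous with a continuous first derivative whenever ``gamma > 0``.

Fitting is least squares: the linear coefficients (b0, b1, b2) are solved
exactly for each candidate (tau, gamma) on a grid, and the best grid node is
polished with a Nelder--Mead search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize


def bend_basis(t, tau: float, gamma: float):
    """Evaluate the bend basis q(t; tau, gamma)."""
    t = np.asarray(t, dtype=float)
    if gamma <= 0:
        return np.maximum(t - tau, 0.0)
    return np.where(
        t <= tau - gamma,
        0.0,
        np.where(t >= tau + gamma, t - tau, (t - tau + gamma) ** 2 / (4.0 * gamma)),
    )


@dataclass
class BentCableFit:
    """Result of a bent-cable least-squares fit.

    ``identifiable`` is False when the bent model does not improve on a
    single straight line (relative RSS improvement below 1e-6), e.g. when
    the data are exactly linear.
    """

    b0: float
    b1: float
    b2: float
    tau: float
    gamma: float
    rss: float
    identifiable: bool

    @property
    def incoming_slope(self) -> float:
        return self.b1

    @property
    def outgoing_slope(self) -> float:
        return self.b1 + self.b2

    def predict(self, t):
        return self.b0 + self.b1 * np.asarray(t, float) + self.b2 * bend_basis(
            t, self.tau, self.gamma
        )


def _solve_linear(times, values, tau, gamma):
    X = np.column_stack(
        [np.ones_like(times), times, bend_basis(times, tau, gamma)]
    )
    coef, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ coef
    return coef, float(resid @ resid)


def fit_bent_cable(
    times,
    values,
    n_tau: int = 60,
    n_gamma: int = 12,
    refine: bool = True,
) -> BentCableFit:
    """Fit a bent-cable regression by grid search plus local refinement.

    Parameters
    ----------
    times, values
        Observation abscissae (strictly increasing, at least 5 points) and
        ordinates.
    n_tau
        Maximum number of interior grid points used as tau candidates (the
        interior points are subsampled evenly if there are more).
    n_gamma
        Number of gamma candidates on a geometric grid from 1 to half the
        time range.
    refine
        Polish the best grid node with Nelder--Mead on (tau, gamma).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 5:
        raise ValueError(
            f"bent-cable fit requires at least 5 points, got {times.size}"
        )
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    interior = times[1:-1]
    if interior.size == 0:
        raise ValueError("empty tau candidate grid")
    if interior.size > n_tau:
        idx = np.linspace(0, interior.size - 1, n_tau).round().astype(int)
        interior = interior[np.unique(idx)]
    t_range = times[-1] - times[0]
    gammas = np.geomspace(1.0, max(t_range / 2.0, 1.0 + 1e-9), n_gamma)

    nodes = []
    for tau in interior:
        node_best = None
        for gamma in gammas:
            coef, rss = _solve_linear(times, values, tau, gamma)
            if node_best is None or rss < node_best[2]:
                node_best = (tau, gamma, rss, coef)
        nodes.append(node_best)
    nodes.sort(key=lambda n: n[2])
    tau, gamma, rss, coef = nodes[0]

    if refine:
        lo, hi = times[1], times[-2]

        def objective(p):
            ta = float(np.clip(p[0], lo, hi))
            ga = float(np.clip(p[1], 1e-3, t_range / 2.0))
            return _solve_linear(times, values, ta, ga)[1]

        # polish from the best few tau nodes: a single start can settle in
        # a slightly worse local basin
        for tau0, gamma0, _, _ in nodes[:3]:
            res = minimize(
                objective,
                x0=[tau0, gamma0],
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 400},
            )
            ta = float(np.clip(res.x[0], lo, hi))
            ga = float(np.clip(res.x[1], 1e-3, t_range / 2.0))
            coef2, rss2 = _solve_linear(times, values, ta, ga)
            if rss2 < rss:
                tau, gamma, rss, coef = ta, ga, rss2, coef2

    # single-line reference fit for identifiability
    Xl = np.column_stack([np.ones_like(times), times])
    cl, _, _, _ = np.linalg.lstsq(Xl, values, rcond=None)
    rl = values - Xl @ cl
    rss_line = float(rl @ rl)
    # data exactly on a line (up to float noise) carry no bend information
    scale = float(np.sum((values - values.mean()) ** 2))
    if rss_line <= 1e-12 * max(scale, np.finfo(float).tiny):
        identifiable = False
    else:
        identifiable = (rss_line - rss) / rss_line >= 1e-6

    return BentCableFit(
        b0=float(coef[0]),
        b1=float(coef[1]),
        b2=float(coef[2]),
        tau=float(tau),
        gamma=float(gamma),
        rss=rss,
        identifiable=bool(identifiable),
    )


def brute_force_bent_cable(times, values, taus, gammas):
    """Exhaustive (tau, gamma) lattice minimiser, used as an oracle in tests.

    Returns the (tau, gamma, rss) of the best lattice node with linear
    coefficients solved exactly at each node.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    best = (np.nan, np.nan, np.inf)
    for tau in taus:
        for gamma in gammas:
            _, rss = _solve_linear(times, values, tau, gamma)
            if rss < best[2]:
                best = (float(tau), float(gamma), rss)
    return best
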