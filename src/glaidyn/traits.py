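"""Phase delimitation and trait extraction from green-leaf-area-index curves.

A seasonal GLAI curve (m2 green leaf per m2 soil, on a 1-GDD6 thermal-time
grid) is segmented into five phases:

* early vegetative (EV): emergence ``t_e`` to the vegetative break ``t_1``,
* late vegetative (LV): ``t_1`` to the time of maximum ``t_M``,
* flowering plateau (F): ``t_M`` to senescence onset ``t_o`` (the first time
  the curve drops below 95% of its maximum),
* slow senescence (SS): ``t_o`` to the senescence break ``t_2``,
* rapid senescence (RS): ``t_2`` to complete senescence ``t_z``.

The two interior breaks ``t_1`` and ``t_2`` come from bent-cable regressions
fitted on the rising and falling limbs.  Twenty-four traits are derived:
four slopes, eight durations, eight areas under the curve, the maximum
GLAI_M and three relative-threshold durations (D_75, D_50, D_25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .bentcable import BentCableFit, fit_bent_cable

TRAIT_NAMES = [
    "S_EV", "S_LV", "S_SS", "S_RS",
    "D_EV", "D_LV", "D_V", "D_F", "D_SS", "D_RS", "D_S", "D_C",
    "AUC_EV", "AUC_LV", "AUC_V", "AUC_F", "AUC_SS", "AUC_RS", "AUC_S", "AUC_C",
    "GLAI_M",
    "D_75", "D_50", "D_25",
]

SENESCENCE_ONSET_FRACTION = 0.95  # onset = first time below 95% of the max


@dataclass
class GlaiDynamics:
    """A per-plot GLAI curve on a unit thermal-time grid.

    ``times`` are integer GDD6 steps of 1; ``values`` the smooth curve.
    Raw flight observations, when the curve was interpolated from them, are
    kept in ``obs_times``/``obs_values``.
    """

    plot_id: str
    times: np.ndarray
    values: np.ndarray
    obs_times: Optional[np.ndarray] = None
    obs_values: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have the same length")
        d = np.diff(self.times)
        if self.times.size > 1 and not np.all(d == 1):
            raise ValueError("GlaiDynamics requires a strictly increasing unit grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GLAI values must be finite")


def interpolate_observations(obs_times, obs_values, grid=None, plot_id="plot"):
    """Monotone cubic (PCHIP) interpolation of flight observations onto the
    unit GDD6 grid, clipped at zero.  Used when only sparse observations are
    available instead of a continuous curve."""
    obs_times = np.asarray(obs_times, float)
    obs_values = np.asarray(obs_values, float)
    order = np.argsort(obs_times)
    obs_times, obs_values = obs_times[order], obs_values[order]
    if grid is None:
        grid = np.arange(int(np.floor(obs_times[0])), int(np.ceil(obs_times[-1])) + 1)
    interp = PchipInterpolator(obs_times, obs_values, extrapolate=False)
    vals = interp(grid)
    vals = np.nan_to_num(vals, nan=0.0)
    return GlaiDynamics(plot_id, grid, np.maximum(vals, 0.0),
                        obs_times=obs_times, obs_values=obs_values)


@dataclass
class PhaseBoundaries:
    t_e: float
    t_1: float
    t_M: float
    t_o: float
    t_2: float
    t_z: float
    truncated: bool = False
    vegetative_fit: Optional[BentCableFit] = None
    senescence_fit: Optional[BentCableFit] = None

    def __post_init__(self):
        seq = [self.t_e, self.t_1, self.t_M, self.t_o, self.t_2, self.t_z]
        if any(b < a - 1e-9 for a, b in zip(seq, seq[1:])):
            raise ValueError(f"phase boundaries out of order: {seq}")


LIMB_TRIM = 60.0  # GDD6 trimmed off each end of a limb before fitting


def _limb_fit(times, values, lo, hi, trim: float = LIMB_TRIM):
    """Bent-cable fit restricted to grid window [lo, hi]; returns (fit, tau)
    with tau clipped into the window.

    The window ends are contaminated by the curvature around emergence /
    the plateau shoulders, which biases a single-bend fit; a short margin
    (``trim``, capped at 10% of the window) is excluded from each end when
    enough points remain.  Degenerate windows (< 5 points) fall back to a
    straight-line pseudo-fit with the break at the midpoint.
    """
    t_lo, t_hi = lo, hi
    margin = min(trim, 0.1 * (hi - lo))
    if hi - lo - 2 * margin >= 15:
        t_lo, t_hi = lo + margin, hi - margin
    mask = (times >= t_lo) & (times <= t_hi)
    if mask.sum() < 5:  # fall back to the untrimmed window
        mask = (times >= lo) & (times <= hi)
    t, v = np.asarray(times, float)[mask], np.asarray(values, float)[mask]
    if t.size > 250:
        # dense unit grids carry no extra information for a 5-parameter
        # fit; thin evenly (endpoints kept) before the grid search
        idx = np.unique(np.linspace(0, t.size - 1, 250).round().astype(int))
        t, v = t[idx], v[idx]
    if t.size >= 5:
        fit = fit_bent_cable(t, v)
        tau = float(np.clip(fit.tau, lo, hi))
        return fit, tau
    if t.size >= 2:
        slope = (v[-1] - v[0]) / (t[-1] - t[0])
        b0 = v[0] - slope * t[0]
    else:
        slope, b0 = 0.0, float(v[0]) if v.size else 0.0
    mid = (lo + hi) / 2.0
    fit = BentCableFit(b0=b0, b1=slope, b2=0.0, tau=mid, gamma=0.0,
                       rss=0.0, identifiable=False)
    return fit, mid


def delimit_phases(curve: GlaiDynamics) -> PhaseBoundaries:
    """Locate the five phase boundaries of a GLAI curve.

    Raises ``ValueError`` if the curve is nowhere positive.
    """
    t = np.asarray(curve.times, float)
    v = curve.values
    pos = np.flatnonzero(v > 0)
    if pos.size == 0:
        raise ValueError("curve is nowhere positive; cannot delimit phases")
    t_e = float(t[pos[0]])
    glai_m = float(np.max(v))
    # earliest time attaining the maximum (relative tolerance so that a
    # float-flat plateau counts as a tie)
    i_max = int(np.argmax(v >= glai_m * (1.0 - 1e-9)))
    t_M = float(t[i_max])

    veg_fit, t_1 = _limb_fit(t, v, t_e, t_M)

    after = np.flatnonzero((t > t_M) & (v < SENESCENCE_ONSET_FRACTION * glai_m))
    truncated = False
    if after.size:
        t_o = float(t[after[0]])
    else:
        t_o = float(t[-1])
        truncated = True

    zero = np.flatnonzero((t > t_o) & (v <= 0))
    if zero.size:
        t_z = float(t[zero[0]])
    else:
        t_z = float(t[-1])
        truncated = True

    sen_fit, t_2 = _limb_fit(t, v, t_o, t_z)

    # clipping guarantees the ordering invariant
    t_1 = float(np.clip(t_1, t_e, t_M))
    t_2 = float(np.clip(t_2, t_o, t_z))
    return PhaseBoundaries(t_e=t_e, t_1=t_1, t_M=t_M, t_o=t_o, t_2=t_2, t_z=t_z,
                           truncated=truncated,
                           vegetative_fit=veg_fit, senescence_fit=sen_fit)


def _auc(times, values, a, b):
    """Trapezoidal integral of the curve between grid times a and b."""
    if b <= a:
        return 0.0
    i0 = int(np.searchsorted(times, a))
    i1 = int(np.searchsorted(times, b))
    if i1 <= i0:
        return 0.0
    return float(np.trapezoid(values[i0:i1 + 1], times[i0:i1 + 1]))


def extract_traits(curve: GlaiDynamics, bounds: PhaseBoundaries | None = None,
                   fits=None) -> dict:
    """Compute the 24 dynamics traits from a curve and its phase boundaries.

    ``fits`` may override the bent-cable fits attached to ``bounds``
    (vegetative, senescence); slopes S_EV/S_LV come from the vegetative fit
    and S_SS/S_RS from the senescence fit.
    """
    if bounds is None:
        bounds = delimit_phases(curve)
    veg = bounds.vegetative_fit
    sen = bounds.senescence_fit
    if fits is not None:
        veg, sen = fits
    t = np.asarray(curve.times, float)
    v = curve.values
    glai_m = float(np.max(v))

    out = {
        "S_EV": veg.incoming_slope if veg else np.nan,
        "S_LV": veg.outgoing_slope if veg else np.nan,
        "S_SS": sen.incoming_slope if sen else np.nan,
        "S_RS": sen.outgoing_slope if sen else np.nan,
        "D_EV": bounds.t_1 - bounds.t_e,
        "D_LV": bounds.t_M - bounds.t_1,
        "D_V": bounds.t_M - bounds.t_e,
        "D_F": bounds.t_o - bounds.t_M,
        "D_SS": bounds.t_2 - bounds.t_o,
        "D_RS": bounds.t_z - bounds.t_2,
        "D_S": bounds.t_z - bounds.t_o,
        "D_C": bounds.t_z - bounds.t_e,
        "AUC_EV": _auc(t, v, bounds.t_e, bounds.t_1),
        "AUC_LV": _auc(t, v, bounds.t_1, bounds.t_M),
        "AUC_V": _auc(t, v, bounds.t_e, bounds.t_M),
        "AUC_F": _auc(t, v, bounds.t_M, bounds.t_o),
        "AUC_SS": _auc(t, v, bounds.t_o, bounds.t_2),
        "AUC_RS": _auc(t, v, bounds.t_2, bounds.t_z),
        "AUC_S": _auc(t, v, bounds.t_o, bounds.t_z),
        "AUC_C": _auc(t, v, bounds.t_e, bounds.t_z),
        "GLAI_M": glai_m,
    }
    for x in (75, 50, 25):
        out[f"D_{x}"] = float(np.count_nonzero(v >= (x / 100.0) * glai_m))
    assert set(out) == set(TRAIT_NAMES)
    return out


def extract_trait_table(curves, with_boundaries: bool = False) -> pd.DataFrame:
    """Run phase delimitation + trait extraction over an iterable of curves.

    Returns a plot-level table with one row per curve: plot_id, the 24
    traits and the truncation flag (optionally the six boundaries too).
    """
    rows = []
    for curve in curves:
        bounds = delimit_phases(curve)
        rec = {"plot_id": curve.plot_id}
        rec.update(extract_traits(curve, bounds))
        rec["truncated"] = bounds.truncated
        if with_boundaries:
            rec.update({k: getattr(bounds, k)
                        for k in ("t_e", "t_1", "t_M", "t_o", "t_2", "t_z")})
        rows.append(rec)
    return pd.DataFrame(rows)


def trait_table_from_long(obs: pd.DataFrame) -> pd.DataFrame:
    """Trait table from a long observation table (plot_id, gdd6, glai).

    Each plot's observations are interpolated onto the unit grid first.
    """
    curves = []
    for pid, grp in obs.groupby("plot_id", sort=True):
        curves.append(interpolate_observations(
            grp["gdd6"].to_numpy(), grp["glai"].to_numpy(), plot_id=str(pid)))
    return extract_trait_table(curves)
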