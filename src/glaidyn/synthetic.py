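"""Synthetic MAGIC doubled-haploid panel, field trials and GLAI dynamics.

The generator emulates the study system the analysis modules assume: a
16-founder multi-parent (MAGIC) population funnelled into fully homozygous
doubled-haploid (DH) lines on 10 chromosomes, evaluated in multi-environment
field trials (two blocks, row/column layout) under well-watered (WW) and
water-deficient (WD) regimes.  Each plot carries a smooth seasonal GLAI
curve built from genotype-, environment- and QTL-perturbed phase parameters;
observations are the curve sampled at a handful of "flight" times plus block,
spatially autocorrelated (AR1 x AR1) and independent noise.  Agronomic traits
(grain yield GY, flowering date FF, kernel number KN, thousand-kernel weight
TKW, anthesis-silking interval ASI) are causally tied to the true curve.

Everything is driven by one seed; a ground-truth record (planted QTLs, true
curve parameters, true trait values, variance components) is returned for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .bentcable import bend_basis
from .traits import SENESCENCE_ONSET_FRACTION as SEN_FRAC
from .traits import TRAIT_NAMES

N_FOUNDERS = 16
B73_FOUNDER = 0  # founder index playing the role of B73

# ordered phase-parameter names of the true curve
CURVE_PARAMS = ["t_e", "tau_v", "t_M", "t_o", "tau_s", "t_z", "glai_max"]


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypePanel:
    """Homozygous-line dosage panel with marker map and founder-mosaic truth.

    ``dosage`` counts the alternate allele, so entries are 0 or 2 (DH lines
    carry no heterozygous calls).  ``founder_alleles`` is the 16 x m matrix
    of alternate-allele indicators per founder haplotype; row ``B73_FOUNDER``
    defines the B73 allele at every marker.
    """

    sample_ids: list
    markers: pd.DataFrame  # chrom, pos, ref, alt, is_b73_allele
    dosage: np.ndarray  # n x m, values in {0, 2}
    founder_alleles: Optional[np.ndarray] = None  # 16 x m in {0, 1}
    founder_mosaic: Optional[dict] = None  # sample -> chrom -> segments
    chrom_lengths: Optional[dict] = None  # chrom -> bp
    families: Optional[np.ndarray] = None  # family index per sample

    def __post_init__(self):
        if self.chrom_lengths is None:
            self.chrom_lengths = {
                int(c): int(self.markers.loc[self.markers["chrom"] == c,
                                             "pos"].max())
                for c in self.markers["chrom"].unique()
            }

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def maf(self) -> np.ndarray:
        freq = self.dosage.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def b73_indicator(self) -> np.ndarray:
        """n x m matrix: 1 where a line carries the B73 allele at a marker."""
        if self.founder_alleles is not None:
            b73 = self.founder_alleles[B73_FOUNDER]
        else:
            b73 = self.markers["is_b73_allele"].to_numpy().astype(float)
        return (self.dosage / 2.0 == b73).astype(float)

    def marker_index(self, chrom: int, pos: int) -> int:
        hit = np.flatnonzero(
            (self.markers["chrom"].to_numpy() == chrom)
            & (self.markers["pos"].to_numpy() == pos)
        )
        if hit.size == 0:
            raise KeyError(f"marker {chrom}:{pos} not in panel (filtered out?)")
        return int(hit[0])


def simulate_magic_genotypes(
    n_lines: int = 324,
    n_chrom: int = 10,
    n_markers_per_chrom: int = 100,
    chrom_length_bp: int = 200_000_000,
    recomb_rate: float = 6.0,
    maf_threshold: float = 0.035,
    n_families: int = 8,
    founder_freq_range: tuple = (0.1, 0.9),
    seed: int = 0,
) -> GenotypePanel:
    """Simulate a MAGIC DH panel as founder mosaics.

    Founder alternate-allele frequencies are drawn per marker from
    ``founder_freq_range``; each DH chromosome is a Markov mosaic of the 16
    founders with Poisson(``recomb_rate``) breakpoints (funnel-equivalent
    crossovers per chromosome).  Funnel structure is approximated by
    ``n_families`` line families sharing a Dirichlet founder-usage prior.
    Markers with minor allele frequency below ``maf_threshold`` are removed.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    if recomb_rate < 0:
        raise ValueError("recomb_rate must be >= 0")
    rng = np.random.default_rng(seed)
    m_total = n_chrom * n_markers_per_chrom

    # marker map: sorted unique positions per chromosome, 1-based
    chroms = np.repeat(np.arange(1, n_chrom + 1), n_markers_per_chrom)

    def _positions():
        draw = np.unique(rng.integers(1, chrom_length_bp,
                                      size=3 * n_markers_per_chrom))
        while draw.size < n_markers_per_chrom:  # astronomically unlikely
            draw = np.unique(np.concatenate(
                [draw, rng.integers(1, chrom_length_bp,
                                    size=n_markers_per_chrom)]))
        return np.sort(rng.permutation(draw)[:n_markers_per_chrom])

    pos = np.concatenate([_positions() for _ in range(n_chrom)])
    freqs = rng.uniform(*founder_freq_range, size=m_total)
    founder_alleles = (rng.random((N_FOUNDERS, m_total)) < freqs).astype(np.int8)

    # family-level founder-usage priors (shared mosaic prior per family)
    fam_weights = rng.dirichlet(np.full(N_FOUNDERS, 2.0), size=n_families)
    families = np.arange(n_lines) % n_families

    chrom_lengths = {c: chrom_length_bp for c in range(1, n_chrom + 1)}
    sample_ids = [f"L{i:04d}" for i in range(n_lines)]
    dosage = np.zeros((n_lines, m_total), dtype=np.int8)
    mosaic = {}
    col0 = {c: (c - 1) * n_markers_per_chrom for c in range(1, n_chrom + 1)}

    for i, sid in enumerate(sample_ids):
        w = fam_weights[families[i]]
        per_chrom = {}
        for c in range(1, n_chrom + 1):
            n_break = rng.poisson(recomb_rate)
            breaks = np.sort(rng.integers(2, chrom_length_bp, size=n_break))
            edges = np.concatenate([[1], breaks, [chrom_length_bp + 1]])
            n_seg = len(edges) - 1
            cw = np.cumsum(w)
            draw = np.searchsorted(cw, rng.random(n_seg) * cw[-1])
            founders = list(np.clip(draw, 0, N_FOUNDERS - 1))
            # Markov constraint: consecutive segments change founder
            for k in range(1, n_seg):
                while founders[k] == founders[k - 1]:
                    founders[k] = int(np.clip(
                        np.searchsorted(cw, rng.random() * cw[-1]),
                        0, N_FOUNDERS - 1))
            segments = [(int(a), int(b), f)
                        for a, b, f in zip(edges[:-1], edges[1:], founders)]
            per_chrom[c] = segments
            # dosage from the mosaic
            cpos = pos[col0[c]:col0[c] + n_markers_per_chrom]
            seg_idx = np.searchsorted(edges, cpos, side="right") - 1
            fvec = np.asarray(founders)[seg_idx]
            dosage[i, col0[c]:col0[c] + n_markers_per_chrom] = (
                2 * founder_alleles[fvec, np.arange(col0[c], col0[c] + n_markers_per_chrom)]
            )
        mosaic[sid] = per_chrom

    markers = pd.DataFrame({
        "chrom": chroms,
        "pos": pos,
        "ref": "A",
        "alt": "T",
    })
    markers["is_b73_allele"] = founder_alleles[B73_FOUNDER].astype(bool)

    freq = dosage.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_threshold
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 polymorphic markers survive the MAF filter "
            f"(threshold {maf_threshold})"
        )
    panel = GenotypePanel(
        sample_ids=sample_ids,
        markers=markers.loc[keep].reset_index(drop=True),
        dosage=dosage[:, keep],
        founder_alleles=founder_alleles[:, keep],
        founder_mosaic=mosaic,
        chrom_lengths=chrom_lengths,
        families=families,
    )
    return panel


# ---------------------------------------------------------------------------
# trial design


@dataclass
class Environment:
    name: str
    year: int
    treatment: str  # "WW" or "WD"
    stress_window: Optional[tuple] = None  # (start, end) in GDD6


DEFAULT_ENVIRONMENTS = [
    Environment("16WW", 2016, "WW", None),
    Environment("16WD", 2016, "WD", (900, 1600)),
    Environment("17WW", 2017, "WW", None),
    Environment("17WD", 2017, "WD", (600, 1100)),
]


@dataclass
class TrialDesign:
    environments: list
    plots: pd.DataFrame  # plot, environment, genotype, block, row, col


def make_trial_design(sample_ids, environments=None, seed: int = 0,
                      n_cols: Optional[int] = None) -> TrialDesign:
    """Two-replicate row/column layout per environment (alpha-lattice style):
    each genotype appears once in each of two blocks, blocks stacked in the
    row direction, genotype order randomised within block."""
    if environments is None:
        environments = list(DEFAULT_ENVIRONMENTS)
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    rows = []
    for env in environments:
        for block in (1, 2):
            order = rng.permutation(n)
            for k, gi in enumerate(order):
                r, c = divmod(k, n_cols)
                rows.append({
                    "plot": f"{env.name}_B{block}_{k:04d}",
                    "environment": env.name,
                    "genotype": sample_ids[gi],
                    "block": block,
                    "row": r + (block - 1) * n_rows,
                    "col": c,
                })
    return TrialDesign(environments=list(environments), plots=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# truth configuration


@dataclass
class PlantedQtl:
    """A causal marker: additive effect of the B73 allele on one curve
    parameter (or directly on an agronomic trait, param="GY"/"FF").

    ``effect`` may be a scalar (same in all environments) or a dict
    environment-name -> effect.
    """

    chrom: int
    pos: int
    param: str
    effect: object  # float or dict env -> float

    def effect_in(self, env_name: str) -> float:
        if isinstance(self.effect, dict):
            return float(self.effect.get(env_name, 0.0))
        return float(self.effect)


@dataclass
class TruthConfig:
    """Generator settings: baseline curve parameters (GDD6 / m2 m-2), the
    genetic and GxE standard deviations of each parameter, planted QTLs,
    observation schedule and the noise structure.

    Defaults give a panel on the scale of a temperate maize MAGIC study:
    GLAI_M around 3.2 m2 m-2, vegetative duration ~740 GDD6, senescence
    duration ~800 GDD6, grain yield ~95 (WW) / 70 (WD) q ha-1 with genetic
    CV near 7% and corr(GY, AUC_S) ~ 0.4.
    """

    base_params: dict = field(default_factory=lambda: {
        "t_e": 80.0, "tau_v": 350.0, "t_M": 820.0, "t_o": 1020.0,
        "tau_s": 1500.0, "t_z": 1850.0, "glai_max": 3.2,
    })
    v_frac: float = 0.6   # relative GLAI at the EV/LV break
    s_frac: float = 0.5   # relative GLAI at the SS/RS break
    bend_gamma: float = 30.0  # quadratic bend half-width, GDD6
    genetic_sd: dict = field(default_factory=lambda: {
        "t_e": 6.0, "tau_v": 20.0, "t_M": 35.0, "t_o": 35.0,
        "tau_s": 40.0, "t_z": 40.0, "glai_max": 0.32,
    })
    gxe_sd: dict = field(default_factory=lambda: {
        "t_e": 2.0, "tau_v": 6.0, "t_M": 10.0, "t_o": 10.0,
        "tau_s": 12.0, "t_z": 12.0, "glai_max": 0.08,
    })
    qtls: list = field(default_factory=list)  # list[PlantedQtl]
    # water-deficit stress: multiplicative on glai_max, additive shifts on
    # senescence timing (applied when the environment treatment is WD)
    wd_glai_max_mult: float = 0.8
    wd_param_shift: dict = field(default_factory=lambda: {
        "t_o": -40.0, "tau_s": -60.0, "t_z": -60.0,
    })
    # observation model
    flight_times: tuple = tuple(np.linspace(150, 1800, 10).round().astype(int))
    obs_noise_sd: float = 0.25
    block_sd: float = 0.15
    spatial_sd: float = 0.20
    spatial_rho_row: float = 0.5
    spatial_rho_col: float = 0.5
    grid_max: int = 2000
    # agronomic model
    gy_mean: dict = field(default_factory=lambda: {"WW": 95.0, "WD": 70.0})
    w_aucf: float = 0.006   # q ha-1 per m2 m-2 GDD6 of AUC_F
    w_aucs: float = 0.012   # q ha-1 per m2 m-2 GDD6 of AUC_S
    gy_genetic_sd: float = 4.0
    gy_gxe_sd: float = 2.0
    gy_plot_sd: float = 4.0
    ff_base: float = 1000.0
    w_ff_dv: float = 0.35   # GDD6 of FF per GDD6 of D_V
    ff_plot_sd: float = 6.0
    kn_base: float = 3400.0
    w_kn_gy: float = 30.0
    kn_plot_sd: float = 150.0
    tkw_base: float = 265.0
    w_tkw_gy: float = 0.3
    tkw_plot_sd: float = 10.0
    asi_base: float = 30.0
    w_asi_gy: float = -0.05
    asi_plot_sd: float = 8.0


@dataclass
class TruthSet:
    """Ground truth: planted QTLs, per-(genotype, environment) true curve
    parameters and trait values, and the variance components used."""

    qtls: list
    true_params: pd.DataFrame  # genotype, environment, 7 curve parameters
    true_traits: pd.DataFrame  # genotype, environment, 24 traits (+GY etc.)
    config: TruthConfig
    child_seeds: dict


# ---------------------------------------------------------------------------
# curve construction


def build_true_curve(params: dict, v_frac: float, s_frac: float,
                     gamma: float, grid: np.ndarray) -> np.ndarray:
    """Smooth seasonal curve from phase parameters: piecewise linear through
    the phase knots, each kink replaced by a quadratic bend of half-width
    ``gamma``; exactly zero outside [t_e - gamma, t_z + gamma]."""
    t_e, tau_v, t_M = params["t_e"], params["tau_v"], params["t_M"]
    t_o, tau_s, t_z = params["t_o"], params["tau_s"], params["t_z"]
    m = max(params["glai_max"], 0.1)

    # enforce ordering with a margin wide enough for the bends
    gap = 2 * gamma + 5
    tau_v = max(tau_v, t_e + gap)
    t_M = max(t_M, tau_v + gap)
    t_o = max(t_o, t_M + gap)
    tau_s = max(tau_s, t_o + gap)
    t_z = max(t_z, tau_s + gap)

    s1 = v_frac * m / (tau_v - t_e)
    s2 = (1 - v_frac) * m / (t_M - tau_v)
    s4 = (s_frac - 1) * m / (tau_s - t_o)
    s5 = -s_frac * m / (t_z - tau_s)
    knots = [t_e, tau_v, t_M, t_o, tau_s, t_z]
    dslopes = [s1, s2 - s1, -s2, s4, s5 - s4, -s5]
    f = np.zeros_like(grid, dtype=float)
    for k, ds in zip(knots, dslopes):
        f += ds * bend_basis(grid, k, gamma)
    f[(grid <= t_e - gamma) | (grid >= t_z + gamma)] = 0.0
    return np.maximum(f, 0.0)


def _effective_params(params: dict, v_frac, s_frac, gamma):
    """Same ordering enforcement as build_true_curve, returned as a dict."""
    p = dict(params)
    gap = 2 * gamma + 5
    p["tau_v"] = max(p["tau_v"], p["t_e"] + gap)
    p["t_M"] = max(p["t_M"], p["tau_v"] + gap)
    p["t_o"] = max(p["t_o"], p["t_M"] + gap)
    p["tau_s"] = max(p["tau_s"], p["t_o"] + gap)
    p["t_z"] = max(p["t_z"], p["tau_s"] + gap)
    p["glai_max"] = max(p["glai_max"], 0.1)
    return p


def analytic_true_traits(params: dict, v_frac: float, s_frac: float,
                         gamma: float, grid: np.ndarray,
                         curve: Optional[np.ndarray] = None) -> dict:
    """True trait values implied by the planted parameters.

    Boundary positions are the analytic ones of the smoothed curve (support
    edges at t_e - gamma and t_z + gamma, plateau start at t_M + gamma, 95%
    crossing solved on the senescence limb); AUCs and relative-threshold
    durations are integrals of the noise-free curve itself.
    """
    p = _effective_params(params, v_frac, s_frac, gamma)
    m = p["glai_max"]
    if curve is None:
        curve = build_true_curve(p, v_frac, s_frac, gamma, grid)

    t_e = p["t_e"] - gamma
    t_1 = p["tau_v"]
    t_M = p["t_M"] + gamma
    t_2 = p["tau_s"]
    t_z = p["t_z"] + gamma
    s4 = (s_frac - 1) * m / (p["tau_s"] - p["t_o"])
    # 95% crossing on the senescence-onset bend or the SS line
    drop = (1 - SEN_FRAC) * m
    bend_drop = -s4 * gamma / 4.0
    if drop <= bend_drop:
        t_o = p["t_o"] - gamma + float(np.sqrt(drop * 4 * gamma / (-s4)))
    else:
        t_o = p["t_o"] + drop / (-s4)

    s1 = v_frac * m / (p["tau_v"] - p["t_e"])
    s2 = (1 - v_frac) * m / (p["t_M"] - p["tau_v"])
    s5 = -s_frac * m / (p["t_z"] - p["tau_s"])

    def auc(a, b):
        if b <= a:
            return 0.0
        i0, i1 = int(np.searchsorted(grid, a)), int(np.searchsorted(grid, b))
        if i1 <= i0:
            return 0.0
        return float(np.trapezoid(curve[i0:i1 + 1], grid[i0:i1 + 1]))

    out = {
        "S_EV": s1, "S_LV": s2, "S_SS": s4, "S_RS": s5,
        "D_EV": t_1 - t_e, "D_LV": t_M - t_1, "D_V": t_M - t_e,
        "D_F": t_o - t_M, "D_SS": t_2 - t_o, "D_RS": t_z - t_2,
        "D_S": t_z - t_o, "D_C": t_z - t_e,
        "AUC_EV": auc(t_e, t_1), "AUC_LV": auc(t_1, t_M),
        "AUC_V": auc(t_e, t_M), "AUC_F": auc(t_M, t_o),
        "AUC_SS": auc(t_o, t_2), "AUC_RS": auc(t_2, t_z),
        "AUC_S": auc(t_o, t_z), "AUC_C": auc(t_e, t_z),
        "GLAI_M": m,
    }
    for x in (75, 50, 25):
        out[f"D_{x}"] = float(np.count_nonzero(curve >= (x / 100.0) * m))
    return out


# ---------------------------------------------------------------------------
# phenotype simulation


def _ar1_field(n_rows, n_cols, rho_r, rho_c, sd, rng):
    """Separable AR1 x AR1 Gaussian field over the plot grid."""
    def chol(n, rho):
        idx = np.arange(n)
        corr = rho ** np.abs(idx[:, None] - idx[None, :])
        return np.linalg.cholesky(corr + 1e-10 * np.eye(n))
    z = rng.standard_normal((n_rows, n_cols))
    return sd * chol(n_rows, rho_r) @ z @ chol(n_cols, rho_c).T


def simulate_trial_phenotypes(
    panel: GenotypePanel,
    design: TrialDesign,
    config: Optional[TruthConfig] = None,
    seed: int = 0,
):
    """Simulate plot-level GLAI observations and agronomic traits.

    Returns ``(glai_obs, agro, truth)``: a long observation table
    (plot_id, gdd6, glai), a plot-level agronomic table and the TruthSet.
    """
    if config is None:
        config = TruthConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4)
    rng_g, rng_ge, rng_field, rng_obs = (np.random.default_rng(c) for c in children)
    child_seeds = {
        "genetic": children[0].entropy, "gxe": children[1].entropy,
        "field": children[2].entropy, "obs": children[3].entropy,
    }

    n = panel.n_samples
    envs = design.environments
    grid = np.arange(0, config.grid_max + 1)

    # planted QTLs must sit on retained markers
    qtl_idx = []
    for q in config.qtls:
        qtl_idx.append(panel.marker_index(q.chrom, q.pos))
    x_b73 = panel.b73_indicator()

    # per-genotype genetic deviations, shared across environments
    g_dev = {p: rng_g.normal(0.0, config.genetic_sd.get(p, 0.0), size=n)
             for p in CURVE_PARAMS}
    gy_g = rng_g.normal(0.0, config.gy_genetic_sd, size=n)

    sample_pos = {s: i for i, s in enumerate(panel.sample_ids)}
    true_param_rows, true_trait_rows = [], []
    curves = {}  # (genotype, env) -> curve

    for env in envs:
        ge_dev = {p: rng_ge.normal(0.0, config.gxe_sd.get(p, 0.0), size=n)
                  for p in CURVE_PARAMS}
        gy_ge = rng_ge.normal(0.0, config.gy_gxe_sd, size=n)
        for sid in panel.sample_ids:
            i = sample_pos[sid]
            params = {}
            for p in CURVE_PARAMS:
                val = config.base_params[p] + g_dev[p][i] + ge_dev[p][i]
                params[p] = val
            if env.treatment == "WD":
                params["glai_max"] *= config.wd_glai_max_mult
                for p, shift in config.wd_param_shift.items():
                    params[p] += shift
            for q, mi in zip(config.qtls, qtl_idx):
                if q.param in CURVE_PARAMS:
                    params[q.param] += q.effect_in(env.name) * x_b73[i, mi]
            curve = build_true_curve(params, config.v_frac, config.s_frac,
                                     config.bend_gamma, grid)
            curves[(sid, env.name)] = curve
            tt = analytic_true_traits(params, config.v_frac, config.s_frac,
                                      config.bend_gamma, grid, curve=curve)
            eff = _effective_params(params, config.v_frac, config.s_frac,
                                    config.bend_gamma)
            true_param_rows.append({"genotype": sid, "environment": env.name,
                                    **eff})
            # agronomic truth at the genotype x environment level
            gy = (config.gy_mean[env.treatment]
                  + config.w_aucf * tt["AUC_F"] + config.w_aucs * tt["AUC_S"]
                  + gy_g[i] + gy_ge[i])
            for q, mi in zip(config.qtls, qtl_idx):
                if q.param == "GY":
                    gy += q.effect_in(env.name) * x_b73[i, mi]
            ff = config.ff_base + config.w_ff_dv * (tt["D_V"] - 800.0)
            for q, mi in zip(config.qtls, qtl_idx):
                if q.param == "FF":
                    ff += q.effect_in(env.name) * x_b73[i, mi]
            tt.update({"GY": gy, "FF": ff})
            true_trait_rows.append({"genotype": sid, "environment": env.name,
                                    **tt})

    true_traits = pd.DataFrame(true_trait_rows)
    # centre the AUC contributions so gy_mean is the realised env mean
    for env in envs:
        sel = true_traits["environment"] == env.name
        true_traits.loc[sel, "GY"] -= (
            config.w_aucf * true_traits.loc[sel, "AUC_F"].mean()
            + config.w_aucs * true_traits.loc[sel, "AUC_S"].mean()
        )

    tt_lookup = true_traits.set_index(["genotype", "environment"])

    # plot-level observations
    obs_rows = []
    agro_rows = []
    flights = np.asarray(config.flight_times, dtype=int)
    for env in envs:
        plots = design.plots[design.plots["environment"] == env.name]
        n_rows = int(plots["row"].max()) + 1
        n_cols = int(plots["col"].max()) + 1
        fld = _ar1_field(n_rows, n_cols, config.spatial_rho_row,
                         config.spatial_rho_col, config.spatial_sd, rng_field)
        blocks = {b: rng_field.normal(0.0, config.block_sd)
                  for b in sorted(plots["block"].unique())}
        agro_blocks = {
            trait: {b: rng_field.normal(0.0, sd)
                    for b in sorted(plots["block"].unique())}
            for trait, sd in (("GY", config.gy_plot_sd / 2),
                              ("FF", config.ff_plot_sd / 2),
                              ("KN", config.kn_plot_sd / 2),
                              ("TKW", config.tkw_plot_sd / 2),
                              ("ASI", config.asi_plot_sd / 2))
        }
        for rec in plots.itertuples(index=False):
            curve = curves[(rec.genotype, env.name)]
            base = curve[flights]
            noise = rng_obs.normal(0.0, config.obs_noise_sd, size=flights.size)
            vals = base + blocks[rec.block] + fld[rec.row, rec.col] + noise
            for ft, val in zip(flights, vals):
                obs_rows.append({"plot_id": rec.plot, "gdd6": int(ft),
                                 "glai": float(max(val, 0.0))})
            truth_row = tt_lookup.loc[(rec.genotype, env.name)]
            gy = (truth_row["GY"] + agro_blocks["GY"][rec.block]
                  + rng_obs.normal(0.0, config.gy_plot_sd))
            ff = (truth_row["FF"] + agro_blocks["FF"][rec.block]
                  + rng_obs.normal(0.0, config.ff_plot_sd))
            kn = (config.kn_base + config.w_kn_gy * (truth_row["GY"]
                  - config.gy_mean[env.treatment])
                  + agro_blocks["KN"][rec.block]
                  + rng_obs.normal(0.0, config.kn_plot_sd))
            tkw = (config.tkw_base + config.w_tkw_gy * (truth_row["GY"]
                   - config.gy_mean[env.treatment])
                   + agro_blocks["TKW"][rec.block]
                   + rng_obs.normal(0.0, config.tkw_plot_sd))
            asi = (config.asi_base + config.w_asi_gy * (truth_row["GY"]
                   - config.gy_mean[env.treatment])
                   + agro_blocks["ASI"][rec.block]
                   + rng_obs.normal(0.0, config.asi_plot_sd))
            agro_rows.append({
                "plot_id": rec.plot, "environment": env.name,
                "genotype": rec.genotype, "block": rec.block,
                "row": rec.row, "col": rec.col,
                "GY": gy, "FF": ff, "KN": kn, "TKW": tkw, "ASI": asi,
            })

    truth = TruthSet(
        qtls=list(config.qtls),
        true_params=pd.DataFrame(true_param_rows),
        true_traits=true_traits,
        config=config,
        child_seeds=child_seeds,
    )
    return pd.DataFrame(obs_rows), pd.DataFrame(agro_rows), truth


def curves_for(panel: GenotypePanel, design: TrialDesign,
               config: TruthConfig, seed: int):
    """Noise-free true curves keyed by (genotype, environment).  Re-derives
    the same genotype effects as simulate_trial_phenotypes under the same
    seed (shared child-seed derivation)."""
    obs, agro, truth = simulate_trial_phenotypes(panel, design, config, seed)
    return truth


# ---------------------------------------------------------------------------
# multi-environment yield network


def simulate_gy_network(
    panel: GenotypePanel,
    qtl_markers: list,         # list of (chrom, pos)
    n_envs: int = 11,
    qtl_r2: float = 0.18,
    var_polygenic: float = 0.42,
    var_gxe: float = 0.10,
    err_range: tuple = (0.05, 0.25),
    total_sd: float = 8.0,
    env_mean_range: tuple = (53.0, 89.0),
    env_effect_sign_flip: Optional[dict] = None,
    seed: int = 0,
):
    """Genotype x environment grain-yield table for a WD trial network.

    The planted QTL signal explains ``qtl_r2`` of the environment-centred
    phenotypic variance; per-environment error variances are drawn from
    ``err_range`` (variance-fraction units) so generalized heritability is
    heterogeneous across the network, mimicking a multi-site drought series.
    ``env_effect_sign_flip`` maps marker -> set of environment indices where
    the QTL effect sign is reversed (unstable QTL scenario).

    Returns ``(gy, truth)`` where ``gy`` is a long table (genotype,
    environment, GY) of adjusted-mean-like values and ``truth`` records the
    per-environment allele effects and variance fractions.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    x = panel.b73_indicator()
    idx = [panel.marker_index(c, p) for c, p in qtl_markers]
    X = x[:, idx]
    Xc = X - X.mean(axis=0)

    env_means = rng.uniform(*env_mean_range, size=n_envs)
    err_vars = rng.uniform(*err_range, size=n_envs)
    # scale the QTL signal so it explains qtl_r2 of the total
    # environment-centred variance (QTL + polygenic + GxE + mean error)
    var_rest = var_polygenic + var_gxe + float(err_vars.mean())
    var_qtl = qtl_r2 / (1.0 - qtl_r2) * var_rest if qtl_r2 < 1 else var_rest

    raw = rng.uniform(0.5, 1.0, size=len(idx)) * rng.choice([-1.0, 1.0], len(idx))
    g_q = Xc @ raw if len(idx) else np.zeros(n)
    vq = g_q.var() if len(idx) else 0.0
    scale = np.sqrt(var_qtl / vq) if vq > 0 else 0.0
    beta = raw * scale

    g_poly = rng.normal(0.0, np.sqrt(var_polygenic), size=n)

    rows = []
    effects = np.tile(beta, (n_envs, 1))
    if env_effect_sign_flip:
        for j, (c, p) in enumerate(qtl_markers):
            flips = env_effect_sign_flip.get((c, p), ())
            for e in flips:
                effects[e, j] *= -1.0
    for e in range(n_envs):
        ge = rng.normal(0.0, np.sqrt(var_gxe), size=n)
        err = rng.normal(0.0, np.sqrt(err_vars[e]), size=n)
        y = Xc @ effects[e] + g_poly + ge + err
        y = env_means[e] + total_sd * y
        for i, sid in enumerate(panel.sample_ids):
            rows.append({"genotype": sid, "environment": f"NET{e:02d}",
                         "GY": float(y[i])})
    gy = pd.DataFrame(rows)
    truth = {
        "qtl_markers": list(qtl_markers),
        "effects_var_frac": effects,
        "effects_trait_units": effects * total_sd,
        "qtl_r2": qtl_r2,
        "env_means": env_means,
        "err_vars": err_vars,
        "h2_per_env": (var_qtl + var_polygenic)
        / (var_qtl + var_polygenic + var_gxe + err_vars),
    }
    return gy, truth
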