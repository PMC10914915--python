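"""Calibration and recovery studies.

Each function simulates a study under known truth, runs the corresponding
analysis path and reports how well it behaves: null-test calibration of the
univariate and multivariate scans, the multivariate power advantage on
pleiotropic architectures, backward-selection operating characteristics,
recovery of a planted grain-yield architecture across an 11-environment
network, and Cullis heritability against the balanced-design closed form.
These studies back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bentcable import brute_force_bent_cable, fit_bent_cable
from .clustering import SnpCluster
from .kinship import loco_kinships
from .lmm import gwas_univariate
from .mvlmm import gwas_multivariate
from .pheno import generalized_heritability
from .qtl import backward_select_qtls
from .qvalues import storey_qvalues
from .synthetic import (Environment, PlantedQtl, TruthConfig,
                        make_trial_design, simulate_gy_network,
                        simulate_magic_genotypes, simulate_trial_phenotypes)
from .yieldpred import predict_gy_from_glai_qtls


def _seed_stream(seed, n):
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def reference_panel(seed: int, n_lines: int = 324, n_chrom: int = 10,
                    n_markers_per_chrom: int = 200):
    """The study-scale panel: 324 DH lines, 10 chromosomes, ~2,000 markers
    before MAF filtering."""
    return simulate_magic_genotypes(n_lines=n_lines, n_chrom=n_chrom,
                                    n_markers_per_chrom=n_markers_per_chrom,
                                    seed=seed)


# ---------------------------------------------------------------------------
# GWAS calibration


def uv_null_calibration(seed: int, n_reps: int = 200, h2: float = 0.5,
                        panel=None) -> dict:
    """Size and genomic inflation of the univariate scan under the null.

    Phenotypes are polygenic (heritability ``h2`` under the global
    kinship) with no causal marker; the scan uses the same global matrix,
    so the model is correctly specified and the test should reject at its
    nominal level with lambda_GC near 1.
    """
    if panel is None:
        panel = reference_panel(seed)
    kin = loco_kinships(panel)
    n = panel.n_samples
    L = np.linalg.cholesky(kin[0] + 1e-8 * np.eye(n))
    rng = np.random.default_rng(seed + 1)
    fracs = []
    chis = []
    for _ in range(n_reps):
        y = (L @ rng.standard_normal(n) * np.sqrt(h2)
             + rng.standard_normal(n) * np.sqrt(1 - h2))
        res = gwas_univariate(y, panel, kin, loco=False)
        p = res["p"].to_numpy()
        fracs.append(float((p < 0.05).mean()))
        chis.append(stats.chi2.isf(p, 1))
    chis = np.concatenate(chis)
    return {
        "size": float(np.mean(fracs)),
        "size_se": float(np.std(fracs, ddof=1) / np.sqrt(len(fracs))),
        "lambda_gc": float(np.median(chis) / stats.chi2.isf(0.5, 1)),
        "n_markers": int(panel.n_markers),
        "n_reps": n_reps,
    }


def mv_null_wald(seed: int, t: int = 8, h2: float = 0.5, panel=None) -> dict:
    """Mean joint Wald statistic of the multivariate scan under the null;
    chi2(t) implies a mean of t."""
    if panel is None:
        panel = reference_panel(seed)
    kin = loco_kinships(panel)
    n = panel.n_samples
    L = np.linalg.cholesky(kin[0] + 1e-8 * np.eye(n))
    rng = np.random.default_rng(seed + 2)
    Y = pd.DataFrame(
        L @ rng.standard_normal((n, t)) * np.sqrt(h2)
        + rng.standard_normal((n, t)) * np.sqrt(1 - h2),
        columns=[f"T{i}" for i in range(t)])
    res, _ = gwas_multivariate(Y, panel, kin, loco=False)
    ok = ~res["monomorphic"]
    return {"mean_wald": float(res.loc[ok, "stat"].mean()), "t": t,
            "n_markers": int(ok.sum())}


# ---------------------------------------------------------------------------
# multivariate power advantage


def _pleiotropic_study(panel, seed, shared_error: float = 0.5,
                       indep_error: float = 0.15):
    """One environment, three planted QTLs with pleiotropic reach through
    the curve architecture, eight analysis traits.

    On top of the genotype-level truth every trait receives a shared
    plot-level error component (all traits of a genotype come from the
    same plots, so their non-genetic errors are correlated) plus
    independent measurement noise.  The shared component is exactly what
    the multivariate model's residual covariance can exploit and the
    trait-by-trait scan cannot.
    """
    mk = panel.markers
    freqs = panel.b73_indicator().mean(axis=0)
    usable = np.flatnonzero((freqs > 0.3) & (freqs < 0.7))
    chroms = mk["chrom"].to_numpy()
    picks = []
    for c in (1, 4, 7):
        on_c = usable[chroms[usable] == c]
        picks.append(int(on_c[len(on_c) // 2]))
    qtls = [
        PlantedQtl(int(chroms[picks[0]]), int(mk["pos"].iloc[picks[0]]),
                   "glai_max", 0.16),
        PlantedQtl(int(chroms[picks[1]]), int(mk["pos"].iloc[picks[1]]),
                   "tau_s", 40.0),
        PlantedQtl(int(chroms[picks[2]]), int(mk["pos"].iloc[picks[2]]),
                   "t_M", 32.0),
    ]
    cfg = TruthConfig(qtls=qtls)
    envs = [Environment("WW", 2016, "WW", None)]
    design = make_trial_design(panel.sample_ids, envs, seed=seed)
    _, _, truth = simulate_trial_phenotypes(panel, design, cfg, seed=seed)
    tt = truth.true_traits.query("environment == 'WW'").set_index(
        "genotype").loc[panel.sample_ids]
    traits = ["D_V", "D_S", "GLAI_M", "AUC_V", "AUC_F", "AUC_S", "GY", "FF"]
    rng = np.random.default_rng(seed + 7)
    common = rng.standard_normal(len(tt))
    Y = pd.DataFrame({
        k: (tt[k] + shared_error * tt[k].std() * common
            + rng.normal(0, indep_error * tt[k].std(), len(tt)))
        for k in traits})
    return Y, picks, traits


def mv_vs_uv_power(seed: int, n_seeds: int = 20, panel=None) -> dict:
    """Planted-QTL detection counts of the multivariate versus univariate
    scans over replicate phenotype draws (a qualitative check of the
    multivariate power advantage on correlated traits)."""
    if panel is None:
        panel = reference_panel(seed)
    kin = loco_kinships(panel)
    seeds = _seed_stream(seed + 3, n_seeds)
    wins = 0
    mv_counts, uv_counts = [], []
    for s in seeds:
        Y, picks, traits = _pleiotropic_study(panel, s)
        mv, _ = gwas_multivariate(Y, panel, kin, loco=False)
        q_mv, _ = storey_qvalues(mv["p"].to_numpy())
        mv_hits = sum(q_mv[m] <= 0.05 for m in picks)
        uv_sig = np.zeros(panel.n_markers, dtype=bool)
        for tr in traits:
            res = gwas_univariate(Y[tr].to_numpy(), panel, kin, loco=False)
            q_uv, _ = storey_qvalues(res["p"].to_numpy())
            uv_sig |= q_uv <= 0.05
        uv_hits = sum(bool(uv_sig[m]) for m in picks)
        mv_counts.append(mv_hits)
        uv_counts.append(uv_hits)
        wins += mv_hits >= uv_hits
    return {
        "win_fraction": wins / n_seeds,
        "mean_mv_detected": float(np.mean(mv_counts)),
        "mean_uv_detected": float(np.mean(uv_counts)),
        "n_planted": 3, "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# backward selection operating characteristics


def qtl_retention(seed: int, n_seeds: int = 50, effect_in_sd: float = 0.5,
                  n_decoys: int = 5, alpha: float = 0.01,
                  panel=None) -> dict:
    """Retention of a planted QTL (effect stated in phenotypic SD of the
    genotype-by-environment means) and spurious retention of null decoy
    clusters, across replicate simulations."""
    if panel is None:
        panel = reference_panel(seed)
    freqs = panel.b73_indicator().mean(axis=0)
    usable = np.flatnonzero((freqs > 0.3) & (freqs < 0.7))
    planted = int(usable[np.argmin(np.abs(freqs[usable] - 0.5))])
    x = panel.b73_indicator()
    mk = panel.markers
    g_sd = e_sd = 0.5
    pheno_sd = np.sqrt(g_sd ** 2 + e_sd ** 2)
    effect = effect_in_sd * pheno_sd
    rng = np.random.default_rng(seed + 4)
    retained = 0
    decoys_kept = 0

    def cluster_for(m, p):
        return SnpCluster(trait="T", environment="net",
                          chrom=int(mk["chrom"].iloc[m]), members=[m],
                          peak=int(m), peak_p=p,
                          start=int(mk["pos"].iloc[m]),
                          end=int(mk["pos"].iloc[m]) + 1)

    for _ in range(n_seeds):
        g = rng.normal(0, g_sd, panel.n_samples)
        rows = []
        for e in range(4):
            y = g + effect * x[:, planted] + rng.normal(0, e_sd,
                                                        panel.n_samples)
            rows.extend({"genotype": s, "environment": f"E{e}", "value": v}
                        for s, v in zip(panel.sample_ids, y))
        means = pd.DataFrame(rows)
        pool = usable[usable != planted]
        decoy_m = rng.choice(pool, n_decoys, replace=False)
        cands = [cluster_for(planted, 1e-9)]
        cands += [cluster_for(int(m), 1e-4) for m in decoy_m]
        qtls = backward_select_qtls(cands, means, panel, alpha=alpha)
        peaks = {q.peak for q in qtls}
        retained += planted in peaks
        decoys_kept += len(peaks - {planted})
    return {
        "retention_rate": retained / n_seeds,
        "mean_decoys_per_run": decoys_kept / n_seeds,
        "decoy_bound": 2 * alpha * n_decoys,
        "n_seeds": n_seeds, "effect_in_sd": effect_in_sd,
    }


# ---------------------------------------------------------------------------
# grain-yield network recovery


def gy_network_recovery(seed: int, n_seeds: int = 20, qtl_r2: float = 0.18,
                        n_qtls: int = 6, n_envs: int = 11,
                        panel=None) -> dict:
    """Recovery of a planted GLAI-QTL -> grain-yield architecture whose
    combined direct effect explains ``qtl_r2`` of the network variance."""
    if panel is None:
        panel = reference_panel(seed)
    freqs = panel.b73_indicator().mean(axis=0)
    usable = np.flatnonzero((freqs > 0.3) & (freqs < 0.7))
    mk = panel.markers
    chroms = mk["chrom"].to_numpy()
    picks = []
    for c in np.unique(chroms):
        on_c = usable[chroms[usable] == c]
        if on_c.size:
            picks.append(int(on_c[len(on_c) // 2]))
        if len(picks) == n_qtls:
            break
    markers = [(int(chroms[m]), int(mk["pos"].iloc[m])) for m in picks]
    seeds = _seed_stream(seed + 5, n_seeds)
    r2s = []
    n_selected = []
    from .qtl import Qtl

    def fake_qtl(m):
        pos = int(mk["pos"].iloc[m])
        eff = pd.DataFrame({"beta": [0.0], "se": [1.0], "p": [1e-4],
                            "significant": [True]}, index=["E0"])
        return Qtl(trait="GLAI", chrom=int(chroms[m]), peak=int(m),
                   peak_pos=pos, start=pos - 1000, end=pos + 1000,
                   joint_p=1e-6, effects=eff)

    rng = np.random.default_rng(seed + 6)
    decoy_pool = np.array([m for m in usable if m not in picks])
    for s in seeds:
        gy, truth = simulate_gy_network(panel, markers, n_envs=n_envs,
                                        qtl_r2=qtl_r2, seed=s)
        gy = gy.rename(columns={"GY": "value"})
        decoys = rng.choice(decoy_pool, 4, replace=False)
        qtls = [fake_qtl(m) for m in picks]
        qtls += [fake_qtl(int(m)) for m in decoys]
        res = predict_gy_from_glai_qtls(qtls, gy, panel)
        r2s.append(res.network_r2)
        n_selected.append(len(res.selected))
    return {
        "mean_network_r2": float(np.mean(r2s)),
        "sd_network_r2": float(np.std(r2s, ddof=1)),
        "planted_r2": qtl_r2,
        "mean_n_selected": float(np.mean(n_selected)),
        "n_envs": n_envs, "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# heritability closed form


def h2_balanced_recovery(seed: int, n_seeds: int = 20, n_geno: int = 300,
                         n_reps: int = 2, sg2: float = 1.0,
                         se2: float = 1.0) -> dict:
    """Cullis H2 on a balanced iid design against the closed form
    1 / (1 + se2 / (r * sg2))."""
    seeds = _seed_stream(seed + 8, n_seeds)
    vals = []
    n_cols = 20
    for s in seeds:
        rng = np.random.default_rng(s)
        g = rng.normal(0, np.sqrt(sg2), n_geno)
        rows = []
        n_rows = int(np.ceil(n_geno / n_cols))
        for b in (1, 2):
            order = rng.permutation(n_geno)
            for k, gi in enumerate(order):
                r, c = divmod(k, n_cols)
                rows.append({"genotype": f"g{gi:03d}", "block": b,
                             "row": r + (b - 1) * n_rows, "col": c,
                             "y": g[gi] + rng.normal(0, np.sqrt(se2))})
        vals.append(generalized_heritability(pd.DataFrame(rows), "y"))
    theory = 1.0 / (1.0 + se2 / (n_reps * sg2))
    return {"mean_h2": float(np.mean(vals)), "closed_form": theory,
            "n_seeds": n_seeds, "n_genotypes": n_geno}


# ---------------------------------------------------------------------------
# bent-cable oracle


def bentcable_oracle_check(seed: int, n_curves: int = 100,
                           noise_sd: float = 0.1) -> dict:
    """Fraction of noisy curves where the production fit lands within one
    observation-grid step of the exhaustive (tau, gamma) lattice minimiser,
    and never with a worse residual sum of squares."""
    rng = np.random.default_rng(seed + 9)
    step = 10.0
    t = np.arange(0.0, 1000.0 + step, step)
    within = 0
    rss_ok = 0
    for _ in range(n_curves):
        tau = rng.uniform(250, 750)
        s1 = rng.uniform(0.005, 0.03)
        s2 = s1 * rng.uniform(-0.8, 0.8)
        v = np.where(t < tau, s1 * t, s1 * tau + s2 * (t - tau))
        v = v + rng.normal(0, noise_sd, t.size)
        fit = fit_bent_cable(t, v)
        taus = t[1:-1]
        gammas = np.geomspace(1.0, (t[-1] - t[0]) / 2.0, 12)
        tau_o, gamma_o, rss_o = brute_force_bent_cable(t, v, taus, gammas)
        within += abs(fit.tau - tau_o) <= step + 1e-9
        # the production search thins the tau grid before refining, so allow
        # a 0.1% relative slack on the residual comparison
        rss_ok += fit.rss <= rss_o * 1.001 + 1e-12
    return {"within_one_step_fraction": within / n_curves,
            "rss_never_worse_fraction": rss_ok / n_curves,
            "grid_step": step, "n_curves": n_curves}
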