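"""End-to-end driver: simulate -> extract -> adjust -> GWAS -> cluster ->
QTL -> colocalization -> yield prediction.

Every stage writes its artifact into the run directory and the manifest
records the configuration, derived seeds, package versions and a content
hash per output, so a rerun with an identical configuration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_snps, extend_interval
from .coloc import colocalize
from .config import PipelineConfig
from .io import (clusters_to_frame, qtls_to_frame, write_dosage_tsv,
                 write_marker_map, write_truth_json, write_vcf)
from .kinship import loco_kinships
from .lmm import gwas_univariate
from .mvlmm import gwas_multivariate
from .pheno import adjusted_means_table, pivot_means, trait_pca, variance_decomposition
from .qtl import backward_select_qtls, variance_explained
from .qvalues import assign_mv_traits, storey_qvalues
from .synthetic import (Environment, PlantedQtl, TruthConfig,
                        make_trial_design, simulate_gy_network,
                        simulate_magic_genotypes, simulate_trial_phenotypes)
from .traits import trait_table_from_long
from .yieldpred import predict_gy_from_glai_qtls


def resolve_planted_qtls(panel, specs):
    """Turn (chrom, pos_frac, param, effect) specs into PlantedQtl objects
    anchored on the nearest retained marker."""
    out = []
    for s in specs:
        chrom = int(s["chrom"])
        sub = panel.markers[panel.markers["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no retained markers on chromosome {chrom}")
        target = s["pos_frac"] * panel.chrom_lengths[chrom]
        row = sub.iloc[(sub["pos"] - target).abs().argmin()]
        out.append(PlantedQtl(chrom=chrom, pos=int(row["pos"]),
                              param=s["param"], effect=s["effect"]))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_panel, seed_design, seed_pheno, seed_network = (
        int(s.generate_state(1)[0] % 2**31) for s in rng_seeds)

    # 1. genotypes -----------------------------------------------------------
    panel = simulate_magic_genotypes(
        n_lines=config.n_lines, n_chrom=config.n_chrom,
        n_markers_per_chrom=config.n_markers_per_chrom,
        chrom_length_bp=config.chrom_length_bp,
        recomb_rate=config.recomb_rate,
        maf_threshold=config.maf_threshold, seed=seed_panel)
    write_dosage_tsv(panel, outdir / "dosage.tsv")
    write_marker_map(panel, outdir / "markers.tsv")
    write_vcf(panel, outdir / "genotypes.vcf")

    # 2. design + phenotypes -------------------------------------------------
    environments = [Environment(name, int(year), treat,
                                (900, 1600) if treat == "WD" else None)
                    for name, year, treat in config.environments]
    design = make_trial_design(panel.sample_ids, environments,
                               seed=seed_design)
    design.plots.to_csv(outdir / "design.csv", index=False)

    truth_cfg = TruthConfig(**config.truth) if config.truth else TruthConfig()
    truth_cfg.qtls = resolve_planted_qtls(panel, config.planted_qtls)
    obs, agro, truth = simulate_trial_phenotypes(panel, design, truth_cfg,
                                                 seed=seed_pheno)
    obs.to_csv(outdir / "glai_observations.csv", index=False)
    agro.to_csv(outdir / "agronomic.csv", index=False)
    truth.true_traits.to_csv(outdir / "true_traits.csv", index=False)
    write_truth_json(truth, outdir / "truth.json")

    # 3. trait extraction ----------------------------------------------------
    traits_plot = trait_table_from_long(obs)
    meta = design.plots.rename(columns={"plot": "plot_id"})
    traits_plot = traits_plot.merge(meta, on="plot_id")
    traits_plot.to_csv(outdir / "traits_plot.csv", index=False)

    # 4. adjusted means, variance decomposition, PCA -------------------------
    all_traits = config.glai_traits + config.agro_traits
    rho_grid = np.arange(0.0, 0.91, config.rho_step)
    glai_means = adjusted_means_table(traits_plot, config.glai_traits,
                                      rho_grid=rho_grid)
    agro_means = adjusted_means_table(agro, config.agro_traits,
                                      rho_grid=rho_grid)
    means = pd.concat([glai_means, agro_means], ignore_index=True)
    means.to_csv(outdir / "adjusted_means.csv", index=False)

    vc_rows = []
    plot_long = {t: traits_plot for t in config.glai_traits}
    plot_long.update({t: agro for t in config.agro_traits})
    for t in all_traits:
        vc = variance_decomposition(
            plot_long[t].rename(columns={t: "value"}), "value")
        vc_rows.append({"trait": t, "sigma_g2": vc.sigma_g2,
                        "sigma_ge2": vc.sigma_ge2, "sigma_e2": vc.sigma_e2,
                        "cv_g": vc.cv_g, "h2_network": vc.h2_network,
                        "p_genotype": vc.p_genotype, "p_gxe": vc.p_gxe})
    pd.DataFrame(vc_rows).to_csv(outdir / "variance_components.csv",
                                 index=False)

    wide = means.pivot_table(index="genotype",
                             columns=["trait", "environment"],
                             values="value")
    wide.columns = [f"{t}__{e}" for t, e in wide.columns]
    pca = trait_pca(wide)
    pca["explained_variance_ratio"].rename("evr").to_csv(outdir / "pca_evr.csv")
    pca["loadings"].to_csv(outdir / "pca_loadings.csv")

    # 5. GWAS ----------------------------------------------------------------
    kinships = loco_kinships(panel)
    env_names = [e.name for e in environments]
    assoc_frames = []
    sig_by_trait_env = {}
    for env in env_names:
        for t in all_traits:
            y = pivot_means(means, t).reindex(panel.sample_ids)[env]
            res = gwas_univariate(y.to_numpy(), panel, kinships, trait=t,
                                  environment=env)
            q, pi0 = storey_qvalues(res["p"].to_numpy())
            res["q"] = q
            res["significant"] = res["q"] <= config.significance_q
            assoc_frames.append(res)
            sig_by_trait_env[(t, env, "UV")] = res[res["significant"]]

        Y = pd.DataFrame({t: pivot_means(means, t).reindex(
            panel.sample_ids)[env] for t in config.mv_traits})
        mv, _ = gwas_multivariate(Y, panel, kinships, environment=env)
        q, pi0 = storey_qvalues(mv["p"].to_numpy())
        mv["q"] = q
        mv["significant"] = mv["q"] <= config.significance_q
        sig = mv[mv["significant"]]
        beta = sig[[f"beta_{t}" for t in config.mv_traits]].to_numpy()
        se = sig[[f"se_{t}" for t in config.mv_traits]].to_numpy()
        assigned, unassigned = assign_mv_traits(beta, se)
        names = [";".join(config.mv_traits[i] for i in a) for a in assigned]
        mv["assigned_traits"] = ""
        mv.loc[sig.index, "assigned_traits"] = names
        mv["trait"] = "joint"
        assoc_frames.append(mv)
        for t in config.mv_traits:
            ti = config.mv_traits.index(t)
            mask = [ti in a for a in assigned]
            sig_by_trait_env[(t, env, "MV")] = sig[mask]
    assoc = pd.concat(assoc_frames, ignore_index=True)
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)

    # 6. clustering ----------------------------------------------------------
    clusters_all = []
    cluster_lists = {}
    for env in env_names:
        for t in all_traits:
            frames = []
            for method in ("UV", "MV"):
                sub = sig_by_trait_env.get((t, env, method))
                if sub is not None and not sub.empty:
                    frames.append(sub[["chrom", "pos", "p"]])
            if not frames:
                continue
            merged = (pd.concat(frames).sort_values("p")
                      .drop_duplicates(["chrom", "pos"]))
            cls = cluster_snps(merged, panel, trait=t, environment=env,
                               source="M_ALL",
                               r2_threshold=config.r2_threshold,
                               max_span_frac=config.max_span_frac)
            clusters_all.extend(cls)
            cluster_lists.setdefault(t, []).extend(
                c for c in cls if not c.discarded)
    clusters_to_frame(clusters_all).to_csv(outdir / "clusters.tsv", sep="\t",
                                           index=False)

    # 7. QTL selection, intervals, colocalization ----------------------------
    qtls_all = []
    r2_report = {}
    for t, cls in sorted(cluster_lists.items()):
        ext = {c.peak: extend_interval(c, panel,
                                       r2_threshold=config.r2_threshold,
                                       window=config.ld_window)
               for c in cls}
        sub = means[means["trait"] == t].rename(columns={"value": "value"})
        qtls = backward_select_qtls(cls, sub[["genotype", "environment",
                                              "value"]], panel, trait=t,
                                    alpha=config.qtl_alpha,
                                    extended_intervals=ext)
        if qtls:
            net = variance_explained(qtls, sub, panel, scope="network")
            per_env = variance_explained(qtls, sub, panel,
                                         scope="per-environment")
            r2_report[t] = {
                "network_r2": net["r2"],
                "per_environment": {e: v["r2"] for e, v in per_env.items()},
            }
        qtls_all.extend(qtls)
    qtls_to_frame(qtls_all).to_csv(outdir / "qtls.tsv", sep="\t", index=False)
    coloc = colocalize(qtls_all, alpha=config.qtl_alpha)
    coloc.to_csv(outdir / "colocalizations.tsv", sep="\t", index=False)
    (outdir / "r2_report.json").write_text(
        json.dumps(r2_report, indent=2, sort_keys=True))

    # 8. grain-yield network -------------------------------------------------
    glai_qtls = [q for q in qtls_all if q.trait in config.glai_traits]
    net_cfg = dict(config.gy_network)
    qtl_markers = [(q.chrom, q.pos) for q in truth_cfg.qtls
                   if q.param != "FF"]
    gy_net, net_truth = simulate_gy_network(
        panel, qtl_markers or [(int(panel.markers["chrom"].iloc[0]),
                                int(panel.markers["pos"].iloc[0]))],
        n_envs=int(net_cfg.get("n_envs", 11)),
        qtl_r2=float(net_cfg.get("qtl_r2", 0.18)),
        seed=seed_network)
    gy_net = gy_net.rename(columns={"GY": "value"})
    gy_net.to_csv(outdir / "gy_network_means.csv", index=False)
    if glai_qtls:
        result = predict_gy_from_glai_qtls(glai_qtls, gy_net, panel,
                                           alpha=config.gy_alpha)
        gy_payload = {
            "n_candidate_regions": len(result.candidate_regions),
            "n_selected": len(result.selected),
            "network_r2": result.network_r2,
            "per_env_r2": result.per_env_r2,
            "per_env_significant": result.per_env_significant,
        }
    else:
        gy_payload = {"n_candidate_regions": 0, "n_selected": 0,
                      "network_r2": 0.0, "per_env_r2": {},
                      "per_env_significant": {}}
    (outdir / "gy_network.json").write_text(
        json.dumps(gy_payload, indent=2, sort_keys=True))

    # manifest ---------------------------------------------------------------
    outputs = sorted(p.name for p in outdir.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "glaidyn",
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {"panel": seed_panel, "design": seed_design,
                        "phenotypes": seed_pheno, "network": seed_network},
        "outputs": {name: _sha256(outdir / name) for name in outputs},
        "n_markers_retained": int(panel.n_markers),
        "n_qtls": len(qtls_all),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
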