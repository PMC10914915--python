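"""File formats: genotypes (TSV dosage matrix + marker map, minimal VCF),
GLAI observations, trial designs and result tables.

Conventions: genomic positions are 1-based; intervals half-open
[start, end); thermal time in integer GDD6; all tables UTF-8 CSV/TSV with
headers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GenotypePanel


def marker_ids(markers: pd.DataFrame) -> list:
    return [f"C{c}_{p}" for c, p in zip(markers["chrom"], markers["pos"])]


def write_dosage_tsv(panel: GenotypePanel, path):
    df = pd.DataFrame(panel.dosage, index=panel.sample_ids,
                      columns=marker_ids(panel.markers))
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def write_marker_map(panel: GenotypePanel, path):
    out = panel.markers[["chrom", "pos", "ref", "alt", "is_b73_allele"]].copy()
    out.insert(0, "marker", marker_ids(panel.markers))
    out.to_csv(path, sep="\t", index=False)


def read_panel_tsv(dosage_path, map_path) -> GenotypePanel:
    """Panel from a dosage TSV + marker map TSV (no founder truth)."""
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    mp = pd.read_csv(map_path, sep="\t")
    if list(dos.columns) != list(mp["marker"]):
        raise ValueError("dosage columns do not match the marker map")
    markers = mp[["chrom", "pos", "ref", "alt", "is_b73_allele"]].copy()
    return GenotypePanel(
        sample_ids=list(dos.index),
        markers=markers.reset_index(drop=True),
        dosage=dos.to_numpy(dtype=np.int8),
    )


def write_vcf(panel: GenotypePanel, path):
    """Minimal VCF 4.2 with homozygous GT calls (0/0 or 1/1)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, ln in sorted((panel.chrom_lengths or {}).items()):
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        ids = marker_ids(panel.markers)
        for j, (c, p, ref, alt) in enumerate(zip(
                panel.markers["chrom"], panel.markers["pos"],
                panel.markers["ref"], panel.markers["alt"])):
            gts = "\t".join("1/1" if d == 2 else "0/0"
                            for d in panel.dosage[:, j])
            fh.write(f"{c}\t{p}\t{ids[j]}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypePanel:
    """Read the minimal GT-only VCF written by :func:`write_vcf`."""
    samples = None
    chroms, poss, refs, alts = [], [], [], []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chroms.append(int(parts[0]))
            poss.append(int(parts[1]))
            refs.append(parts[3])
            alts.append(parts[4])
            calls = parts[9:]
            rows.append([2 if c.startswith("1") else 0 for c in calls])
    if samples is None:
        raise ValueError("no #CHROM header line found")
    dosage = np.asarray(rows, dtype=np.int8).T
    markers = pd.DataFrame({"chrom": chroms, "pos": poss,
                            "ref": refs, "alt": alts,
                            "is_b73_allele": False})
    return GenotypePanel(sample_ids=samples, markers=markers, dosage=dosage)


def write_truth_json(truth, path):
    """Planted QTLs, seeds and generator settings (trait truth goes to its
    own CSV)."""
    payload = {
        "qtls": [dataclasses.asdict(q) for q in truth.qtls],
        "child_seeds": {k: int(v) for k, v in truth.child_seeds.items()},
        "config": _jsonable(dataclasses.asdict(truth.config)),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def qtls_to_frame(qtls) -> pd.DataFrame:
    """Flatten a list of Qtl objects to a long table (one row per QTL and
    environment)."""
    rows = []
    for q in qtls:
        for env, rec in q.effects.iterrows():
            rows.append({
                "trait": q.trait, "chrom": q.chrom, "peak_pos": q.peak_pos,
                "start": q.start, "end": q.end, "joint_p": q.joint_p,
                "environment": env, "beta": rec["beta"], "se": rec["se"],
                "p": rec["p"], "significant": bool(rec["significant"]),
            })
    return pd.DataFrame(rows)


def clusters_to_frame(clusters) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        rows.append({
            "trait": cl.trait, "environment": cl.environment,
            "chrom": cl.chrom, "start": cl.start, "end": cl.end,
            "n_members": len(cl.members), "peak": cl.peak,
            "peak_p": cl.peak_p, "source": cl.source,
            "discarded": cl.discarded, "reason": cl.reason or "",
        })
    return pd.DataFrame(rows)
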