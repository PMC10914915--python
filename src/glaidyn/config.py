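"""Pipeline configuration.

A single dataclass with every stage parameter, loadable from YAML; unknown
keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

GLAI_TRAITS_6 = ["D_V", "D_S", "GLAI_M", "AUC_V", "AUC_F", "AUC_S"]
AGRO_TRAITS = ["GY", "FF", "KN", "TKW", "ASI"]
MV_TRAITS_8 = GLAI_TRAITS_6 + ["GY", "FF"]  # joint model: t = 8 traits


@dataclass
class PipelineConfig:
    seed: int = 1

    # panel
    n_lines: int = 120
    n_chrom: int = 3
    n_markers_per_chrom: int = 200
    chrom_length_bp: int = 200_000_000
    recomb_rate: float = 6.0
    maf_threshold: float = 0.035

    # trial network: (name, year, treatment)
    environments: list = field(default_factory=lambda: [
        ["16WW", 2016, "WW"], ["16WD", 2016, "WD"],
    ])

    # generator overrides (TruthConfig field name -> value) and planted QTLs
    # (each: chrom, pos_frac in [0,1], param, effect)
    truth: dict = field(default_factory=dict)
    planted_qtls: list = field(default_factory=lambda: [
        {"chrom": 1, "pos_frac": 0.3, "param": "glai_max", "effect": 0.3},
        {"chrom": 2, "pos_frac": 0.5, "param": "tau_s", "effect": 60.0},
        {"chrom": 1, "pos_frac": 0.3, "param": "GY", "effect": 3.0},
    ])

    # analysis
    glai_traits: list = field(default_factory=lambda: list(GLAI_TRAITS_6))
    agro_traits: list = field(default_factory=lambda: list(AGRO_TRAITS))
    mv_traits: list = field(default_factory=lambda: list(MV_TRAITS_8))
    rho_step: float = 0.3           # AR1 profile grid step for adjusted means
    significance_q: float = 0.05
    r2_threshold: float = 0.6
    max_span_frac: float = 0.30
    qtl_alpha: float = 0.01
    gy_alpha: float = 0.05
    ld_window: int = 1_000_000

    # yield network
    gy_network: dict = field(default_factory=lambda: {
        "n_envs": 11, "qtl_r2": 0.18,
    })

    def __post_init__(self):
        checks = [
            (0 < self.maf_threshold < 0.5, "maf_threshold in (0, 0.5)"),
            (0 < self.significance_q <= 1, "significance_q in (0, 1]"),
            (0 < self.r2_threshold <= 1, "r2_threshold in (0, 1]"),
            (0 < self.max_span_frac <= 1, "max_span_frac in (0, 1]"),
            (0 < self.qtl_alpha < 1, "qtl_alpha in (0, 1)"),
            (0 < self.gy_alpha < 1, "gy_alpha in (0, 1)"),
            (0 < self.rho_step <= 0.9, "rho_step in (0, 0.9]"),
            (self.n_lines >= 2, "n_lines >= 2"),
            (self.recomb_rate >= 0, "recomb_rate >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: require {msg}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
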