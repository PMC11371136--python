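"""End-to-end synthetic pipeline: simulation -> traits -> kinetics -> GWAS.

Chains every stage on synthetic data with known ground truth: a
structured genotype panel with one planted causal SNP sets each
accession's salt-response setpoint; per-accession root time-lapse pairs
(control / NaCl) are simulated, geometric traits extracted, re-bending
kinetics fitted, and the derived salt-response trait scanned with the
kinship-corrected mixed model, ending in haplotype grouping of the top
hits.  A JSON manifest records the config, seed and per-stage row
counts so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import (bonferroni_threshold, fit_null_lmm, haplotype_groups,
                    compare_haplotypes, kinship, maf_filter, pca_structure,
                    scan_snps, significant_hits)
from .io import write_dosage_csv, write_long_csv, write_rsml, write_vcf
from .kinetics import fit_decay, response_traits
from .simgen import (PanelSimConfig, RootSimConfig, simulate_panel,
                     simulate_root)
from .traits import trait_timeseries

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic run."""

    out_dir: str = "sita_run"
    seed: int = 0
    log_level: str = "INFO"
    roots: RootSimConfig = field(default_factory=RootSimConfig)
    panel: PanelSimConfig = field(default_factory=PanelSimConfig)
    # how strongly the simulated genetic value shifts the salt setpoint (deg
    # per phenotype SD); the measurement chain adds the heading noise on top
    pheno_scale_deg: float = 15.0
    tip_fraction: float = 0.10
    variant: str = "EXP"
    t_eval_rtd_h: float = 5.0
    t_eval_rva_h: float = 23.0
    maf_threshold: float = 0.05
    alpha: float = 0.05
    kinship_method: str = "vanraden"
    n_pc: int = 0
    min_haplotype_size: int = 10
    n_top_snps_haplotype: int = 3
    write_traces: bool = False

    def validate(self) -> None:
        self.roots.validate()
        self.panel.validate()
        if not (0.0 < self.tip_fraction <= 1.0):
            raise ValueError("tip_fraction must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.maf_threshold < 0:
            raise ValueError("maf_threshold must be >= 0")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    roots = RootSimConfig(**raw.pop("roots", {}))
    panel_kwargs = raw.pop("panel", {})
    if "maf_range" in panel_kwargs:
        panel_kwargs["maf_range"] = tuple(panel_kwargs["maf_range"])
    panel = PanelSimConfig(**panel_kwargs)
    cfg = RunConfig(roots=roots, panel=panel, **raw)
    cfg.validate()
    return cfg


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["roots"] = dataclasses.asdict(cfg.roots)
    d["panel"] = dataclasses.asdict(cfg.panel)
    d["panel"]["maf_range"] = list(cfg.panel.maf_range)
    return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and return the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    logger.info("pipeline seed=%d out=%s", cfg.seed, out)

    # --- stage 1: genotype panel with planted causal SNP -------------------
    panel_cfg = dataclasses.replace(cfg.panel, seed=int(rng.integers(2**31)))
    panel, genetic_value, truth = simulate_panel(panel_cfg)
    write_vcf(panel, out / "genotypes.vcf")
    write_dosage_csv(panel, out / "dosages.csv", out / "markers.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump({k: v for k, v in truth.items() if k != "subpop"}, fh,
                  indent=2, default=float)

    # --- stage 2: per-accession root pairs ---------------------------------
    z = (genetic_value - genetic_value.mean()) / max(genetic_value.std(), 1e-12)
    rows = []
    traces = []
    for i, acc in enumerate(panel.accession_ids):
        setpoint = cfg.roots.theta_set_salt_deg + cfg.pheno_scale_deg * z[i]
        acc_cfg = dataclasses.replace(cfg.roots, theta_set_salt_deg=setpoint)
        pair = {}
        for treatment in ("control", "NaCl"):
            series = simulate_root(acc_cfg, treatment,
                                   seed=int(rng.integers(2**31)))
            table = trait_timeseries(series, cfg.tip_fraction)
            table.insert(0, "accession_id", acc)
            pair[treatment] = table
            if cfg.write_traces:
                traces.append(series)
        fit_c = fit_decay(pair["control"]["time_h"],
                          pair["control"]["rtd_deg"], cfg.variant)
        fit_s = fit_decay(pair["NaCl"]["time_h"],
                          pair["NaCl"]["rtd_deg"], cfg.variant)
        rt = response_traits(fit_s, fit_c, pair["NaCl"], pair["control"],
                             cfg.t_eval_rtd_h, cfg.t_eval_rva_h)
        rows.append({
            "accession_id": acc,
            "k_ctrl": fit_c.k, "k_salt": fit_s.k,
            "K_ratio": rt.K_ratio, "k_diff": rt.k_diff,
            "rtd_diff_5h": rt.rtd_diff_deg,
            "rva_diff_23h": rt.rva_diff_deg,
        })
    traits_df = pd.DataFrame(rows)
    traits_df.to_csv(out / "response_traits.csv", index=False)
    if cfg.write_traces:
        write_rsml(traces, out / "traces.rsml")
        write_long_csv(traces, out / "traces.csv")

    # --- stage 3: association scan -----------------------------------------
    y = traits_df["rva_diff_23h"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise RuntimeError("gwas stage: non-finite derived trait values")
    pd.DataFrame({"accession_id": panel.accession_ids, "value": y}).to_csv(
        out / "phenotype.csv", index=False)

    filtered, m = maf_filter(panel, cfg.maf_threshold)
    K = kinship(filtered, cfg.kinship_method)
    covariates = pca_structure(K, cfg.n_pc) if cfg.n_pc > 0 else None
    null = fit_null_lmm(y, K, covariates)
    result = scan_snps(filtered, y, null, covariates, cfg.alpha)
    result.table.to_csv(out / "association.csv", index=False)
    hits = significant_hits(result)

    # --- stage 4: haplotype follow-up --------------------------------------
    top_ids = (hits["id"].head(cfg.n_top_snps_haplotype).tolist()
               or result.table.nsmallest(cfg.n_top_snps_haplotype,
                                         "p")["id"].tolist())
    grouping = haplotype_groups(filtered, top_ids, cfg.min_haplotype_size)
    trait_series = pd.Series(y, index=panel.accession_ids)
    n_major = len(grouping.group_sizes) - len(grouping.minor_groups)
    hap_stats = {}
    if n_major >= 2:
        grouping = compare_haplotypes(trait_series, grouping)
        hap_stats = {"statistic": grouping.statistic,
                     "p_value": grouping.p_value,
                     "group_means": grouping.group_means}
    grouping.assignments.rename_axis("accession_id").to_frame().to_csv(
        out / "haplotypes.csv")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "stages": {
            "panel": {"n_acc": panel.n_acc, "n_snp": panel.n_snp},
            "traits": {"n_accessions": len(traits_df)},
            "gwas": {"m_after_maf": m,
                     "bonferroni_threshold": result.threshold,
                     "n_significant": len(hits)},
            "haplotypes": {"groups": grouping.group_sizes,
                           "minor": grouping.minor_groups,
                           **hap_stats},
        },
        "truth": {k: v for k, v in truth.items() if k != "subpop"},
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    logger.info("pipeline complete: %d/%d SNPs retained, %d significant",
                m, panel.n_snp, len(hits))
    return manifest
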