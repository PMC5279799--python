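"""End-to-end orchestration: QC -> impute -> LD -> blocks -> Q/K -> scans.

A single :class:`PipelineConfig` (optionally loaded from YAML) drives the
run; every stage writes plain-text outputs under the chosen directory and
a manifest records input checksums, seeds, and package versions so a
rerun with the same config reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import haplotype_loci, scan, snp_loci
from .blocks import build_blocks, call_block_alleles, deduplicate
from .effects import compare_loci
from .errors import ParameterError
from .genotypes import (
    read_genotypes,
    read_map,
    read_phenotypes,
    qc_filter,
    write_genotypes,
)
from .impute import ImputeConfig, impute_missing
from .ld import critical_r2, fit_decay, ld_table
from .structure import dapc_structure, kinship_matrix

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str
    map: str
    phenotypes: str
    out_dir: str = "hapgwas_out"
    max_missing: float = 0.25
    min_maf: float = 0.05
    window_source: str = "fitted"  # "fitted" | "fixed"
    window_cM: float | None = None  # used when window_source == "fixed"
    models: list[str] = field(default_factory=lambda: ["mlm-qk"])
    n_groups: int | str = 4
    kinship_method: str = "scaled-ibs"
    fdr_alpha: float = 0.05
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    ld_subsample: int | None = 100000
    seed: int = 0

    def validate(self) -> None:
        for p in (self.genotypes, self.map, self.phenotypes):
            if not Path(p).exists():
                raise ParameterError(f"input file not found: {p}")
        if not (0 < self.fdr_alpha < 1):
            raise ParameterError("fdr alpha must lie in (0, 1)")
        if self.window_source not in ("fitted", "fixed"):
            raise ParameterError("window_source must be 'fitted' or 'fixed'")
        if self.window_source == "fixed" and (self.window_cM is None or self.window_cM <= 0):
            raise ParameterError("fixed window requires window_cM > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "impute" in raw and isinstance(raw["impute"], dict):
            raw["impute"] = ImputeConfig(**raw["impute"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a manifest dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: dict[str, float] = {}

    def tick(name):
        stages[name] = round(time.time() - t0, 3)
        log.info("stage %s done at %.2fs", name, stages[name])

    g = read_genotypes(cfg.genotypes)
    gmap = read_map(cfg.map)
    pheno = read_phenotypes(cfg.phenotypes)
    tick("load")

    g, qc = qc_filter(g, cfg.max_missing, cfg.min_maf)
    unmapped = gmap.unmapped(g.marker_ids)
    if unmapped:
        log.warning("%d markers not on the map were dropped", len(unmapped))
        g = g.subset_markers([i for i, m in enumerate(g.marker_ids) if m in gmap])
    tick("qc")

    g = impute_missing(g, gmap, cfg.impute)
    write_genotypes(g, out / "genotypes_imputed.tsv", format="dose")
    tick("impute")

    inter = ld_table(g, gmap, scope="interchromosomal", subsample=cfg.ld_subsample, seed=cfg.seed)
    crit = critical_r2(inter)
    intra = ld_table(g, gmap, scope="genome", subsample=cfg.ld_subsample, seed=cfg.seed)
    decay = fit_decay(intra, n=g.n_lines, critical=crit)
    intra.df.to_csv(out / "ld_intra.csv", index=False)
    with open(out / "ld_decay.json", "w") as fh:
        json.dump(decay.to_dict(), fh, indent=1)
    tick("ld")

    g_dedup, dedup_report = deduplicate(g, gmap)
    if cfg.window_source == "fixed":
        window = float(cfg.window_cM)
    else:
        if decay.decay_distance is None:
            raise ParameterError("decay curve never crosses the critical r2; set a fixed window")
        window = decay.decay_distance
    structure_blocks = build_blocks(gmap, window, marker_ids=g_dedup.marker_ids)
    blockset = call_block_alleles(g_dedup, structure_blocks, min_haf=cfg.min_maf)
    blockset.summary().to_csv(out / "blocks.csv", index=False)
    blockset.calls.to_csv(out / "block_calls.tsv", sep="\t")
    tick("blocks")

    structure = dapc_structure(g, n_groups=cfg.n_groups, seed=cfg.seed)
    pd.DataFrame(
        structure.Q,
        index=g.line_ids,
        columns=[f"Q{i + 1}" for i in range(structure.n_groups)],
    ).to_csv(out / "structure_Q.csv")
    K = kinship_matrix(g, method=cfg.kinship_method)
    pd.DataFrame(K.values, index=K.line_ids, columns=K.line_ids).to_csv(out / "kinship.csv")
    tick("structure_kinship")

    # Align phenotype rows with panel lines.
    pheno_df = pheno.df.reindex(g.line_ids)
    snps = snp_loci(g_dedup, gmap)
    haps = haplotype_loci(blockset)
    comparisons = {}
    for trait in pheno_df.columns:
        y = pheno_df[trait].to_numpy()
        for model in cfg.models:
            snp_res = scan(
                y, snps, model=model, Q=structure.Q, K=K, fdr_alpha=cfg.fdr_alpha, trait=trait
            )
            hap_res = scan(
                y, haps, model=model, Q=structure.Q, K=K, fdr_alpha=cfg.fdr_alpha, trait=trait
            )
            tag = f"{trait}_{model}".replace("*", "star").replace(" ", "_")
            snp_res.df.to_csv(out / f"assoc_snp_{tag}.csv", index=False)
            hap_res.df.to_csv(out / f"assoc_hap_{tag}.csv", index=False)
            comp = compare_loci(
                hap_res, snp_res, blockset, gmap, y=y, g=g_dedup, alpha=cfg.fdr_alpha
            )
            comp.df.to_csv(out / f"comparison_{tag}.csv", index=False)
            comparisons[tag] = {"mean_ive": comp.mean_ive, "mean_iae": comp.mean_iae}
    tick("assoc")

    manifest = {
        "package_version": __version__,
        "inputs": {p: _sha256(getattr(cfg, p)) for p in ("genotypes", "map", "phenotypes")},
        "seed": cfg.seed,
        "qc": {"n_input": qc.n_input, "n_retained": qc.n_retained},
        "n_dedup_markers": g_dedup.n_markers,
        "critical_r2": crit,
        "decay": decay.to_dict(),
        "window_cM": window,
        "n_blocks": len(blockset.blocks),
        "n_dropped_blocks": len(blockset.dropped),
        "comparisons": comparisons,
        "stage_seconds": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
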