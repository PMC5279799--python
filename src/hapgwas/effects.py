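"""Allelic effects, haplotype-vs-SNP comparisons, and trait utilities.

The allelic effect of an allele is the mean trait value of its carrier
lines minus the whole-panel mean; the reported locus effect is the
largest allele effect in absolute value (the pooled rare class is
excluded). A significant haplotype locus is matched to the significant
SNP with the smallest p-value whose map position falls inside the block
interval, and the per-pair improvements are

    IVE% = 100 * (R2_hap - R2_snp) / R2_snp
    IAE% = 100 * (|effect_hap| - |effect_snp|) / |effect_snp|
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult
from .blocks import RARE, HaplotypeBlockSet
from .errors import EmptyResultError, MonomorphicError, ParameterError
from .genotypes import GeneticMap, GenotypeMatrix, PhenotypeTable
from .ld import pairwise_r2


def allelic_effect(y, carriers) -> float:
    """Mean trait value of carrier lines minus the whole-panel mean.

    `carriers` is a boolean mask or an index array into `y`.
    """
    y = np.asarray(y, dtype=float)
    carriers = np.asarray(carriers)
    sub = y[carriers]
    if sub.size == 0:
        raise EmptyResultError("empty carrier set")
    return float(np.nanmean(sub) - np.nanmean(y))


def snp_locus_effect(y, dose: np.ndarray) -> float:
    """Max-|effect| allele effect of a biallelic SNP (signed)."""
    effects = []
    for target in (0, 2):
        mask = dose == target
        if mask.any():
            effects.append(allelic_effect(y, mask))
    if not effects:
        raise EmptyResultError("SNP has no homozygous carriers")
    return max(effects, key=abs)


def haplotype_locus_effect(y, calls: pd.Series) -> float:
    """Max-|effect| allele effect over a block's non-rare allele classes."""
    effects = []
    y = np.asarray(y, dtype=float)
    for allele in calls.dropna().unique():
        if allele == RARE:
            continue
        effects.append(allelic_effect(y, (calls == allele).to_numpy()))
    if not effects:
        raise EmptyResultError("block has no non-rare alleles")
    return max(effects, key=abs)


def ive(r2_hap: float, r2_snp: float) -> float:
    """Percent increase in variance explained by the haplotype locus."""
    if r2_snp <= 0:
        raise ParameterError("SNP R2 must be positive")
    return 100.0 * (r2_hap - r2_snp) / r2_snp


def iae(effect_hap: float, effect_snp: float) -> float:
    """Percent increase in (absolute) allelic effect."""
    if effect_snp == 0:
        raise ParameterError("SNP effect must be non-zero")
    return 100.0 * (abs(effect_hap) - abs(effect_snp)) / abs(effect_snp)


@dataclass
class ComparisonTable:
    df: pd.DataFrame
    mean_ive: float
    mean_iae: float


def compare_loci(
    hap_results: AssocResult,
    snp_results: AssocResult,
    blocks: HaplotypeBlockSet,
    gmap: GeneticMap,
    y=None,
    g: GenotypeMatrix | None = None,
    alpha: float = 0.05,
) -> ComparisonTable:
    """Pair significant haplotype loci with in-interval significant SNPs.

    When several significant SNPs fall inside one block interval the one
    with the smallest p-value is matched. Unmatched haplotype loci keep
    empty SNP fields. Effects are filled when `y` (trait vector aligned
    with the panel) and `g` are given.
    """
    hap_sig = hap_results.significant(alpha)
    snp_sig = snp_results.significant(alpha)
    rows = []
    for _, hrow in hap_sig.iterrows():
        block = blocks.block(hrow["locus"])
        candidates = []
        for _, srow in snp_sig.iterrows():
            sid = srow["locus"]
            if sid in gmap and gmap.chrom[sid] == block.chrom and (
                block.start <= gmap.pos[sid] <= block.end
            ):
                candidates.append(srow)
        row = {
            "trait": hap_results.trait,
            "haplotype": hrow["locus"],
            "hap_interval": f"{block.chrom} ({block.start:g}-{block.end:g})",
            "nbM": block.n_snps,
            "hap_p": hrow["p"],
            "hap_adj_p": hrow["adj_p"],
            "hap_r2_pct": hrow["r2_pct"],
            "hap_effect": np.nan,
            "snp": None,
            "snp_pos": np.nan,
            "snp_p": np.nan,
            "snp_adj_p": np.nan,
            "snp_r2_pct": np.nan,
            "snp_effect": np.nan,
            "ive_pct": np.nan,
            "iae_pct": np.nan,
        }
        if y is not None and blocks.calls is not None:
            row["hap_effect"] = haplotype_locus_effect(y, blocks.calls[hrow["locus"]])
        if candidates:
            best = min(candidates, key=lambda r: r["p"])
            row["snp"] = best["locus"]
            row["snp_pos"] = gmap.pos[best["locus"]]
            row["snp_p"] = best["p"]
            row["snp_adj_p"] = best["adj_p"]
            row["snp_r2_pct"] = best["r2_pct"]
            row["ive_pct"] = ive(hrow["r2_pct"], best["r2_pct"])
            if y is not None and g is not None:
                row["snp_effect"] = snp_locus_effect(y, g.dose_of(best["locus"]))
                if row["snp_effect"] != 0 and np.isfinite(row["hap_effect"]):
                    row["iae_pct"] = iae(row["hap_effect"], row["snp_effect"])
        rows.append(row)
    df = pd.DataFrame(rows)
    matched_ive = df["ive_pct"].dropna() if len(df) else pd.Series(dtype=float)
    matched_iae = df["iae_pct"].dropna() if len(df) else pd.Series(dtype=float)
    return ComparisonTable(
        df=df,
        mean_ive=float(matched_ive.mean()) if len(matched_ive) else np.nan,
        mean_iae=float(matched_iae.mean()) if len(matched_iae) else np.nan,
    )


def colour_loss_residuals(pasta_b, semolina_b) -> np.ndarray:
    """Residuals of OLS pasta-b* on semolina-b*: observed minus predicted.

    Positive values mean less pigment loss than the panel average.
    """
    x = np.asarray(semolina_b, dtype=float)
    y = np.asarray(pasta_b, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ParameterError("need at least 3 complete line pairs")
    if np.ptp(x[ok]) == 0:
        raise ParameterError("semolina b* has zero variance; regression undefined")
    slope, intercept, *_ = stats.linregress(x[ok], y[ok])
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - (intercept + slope * x[ok])
    return resid


def trait_correlations(pheno: PhenotypeTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among traits with two-sided p-values.

    Constant traits yield NaN entries (flagged by the caller via isna).
    """
    traits = pheno.traits
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            a = pheno.df[traits[i]]
            b = pheno.df[traits[j]]
            ok = a.notna() & b.notna()
            if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(a[ok], b[ok])
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def candidate_gene_ld(
    g: GenotypeMatrix, signal_markers: list[str], gene_markers: list[str]
) -> pd.DataFrame:
    """Pairwise r2 between association signals and candidate-gene markers."""
    for m in list(signal_markers) + list(gene_markers):
        if m not in g.marker_ids:
            raise KeyError(f"unknown marker id {m!r}")
    rows = []
    for s in signal_markers:
        for c in gene_markers:
            try:
                r2 = pairwise_r2(g.dose_of(s), g.dose_of(c))
            except MonomorphicError:
                r2 = np.nan
            rows.append({"signal": s, "gene_marker": c, "r2": r2})
    return pd.DataFrame(rows)
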