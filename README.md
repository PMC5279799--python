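# hapgwas

Haplotype-block association mapping for inbred crop panels. The package
implements a full pipeline from a QC'd SNP matrix on a genetic (cM) map to
matched haplotype-vs-single-SNP association results:

1. **genotype I/O + QC** — HapMap-like TSV, numeric-dose TSV and VCF readers
   and writers; marker filters for missingness (> 25% by default) and minor
   allele frequency (< 0.05 by default).
2. **imputation** — per-marker random-forest classifiers trained on the
   nearest mapped markers, sweeping from a mode-fill start; observed calls
   are never altered.
3. **LD analysis** — pairwise dose-correlation r², a background ("critical")
   r² from inter-chromosomal pairs (parametric 95th percentile on the
   sqrt scale, or empirical quantile), and a nonlinear fit of the
   drift-sampling expectation of r² against map distance whose crossing
   point with the critical r² gives the haplotype window width.
4. **haplotype blocks** — same-chromosome duplicate-column collapse, fixed
   cM windows anchored at each chromosome's first marker, per-line
   multi-allelic block alleles with rare-allele (< 5%) pooling, and PIC.
5. **structure + kinship** — PCA (≤ N/3 components) + k-means (group count
   fixed or chosen by Gaussian-mixture BIC) + LDA membership probabilities
   Q; scaled-IBS or VanRaden-centered kinship K.
6. **association** — GLM (naive, +Q) and MLM (K, Q+K) scans for single-SNP
   and multi-allelic haplotype loci, REML variance components via the
   eigendecomposition of K with P3D reuse across loci, adaptive step-up FDR
   with estimated null proportion, QQ diagnostics.
7. **effects + comparison** — carrier-mean allelic effects, matching of
   significant haplotype loci to in-interval significant SNPs, percent
   increases in variance explained (IVE) and allelic effect (IAE), colour
   loss as pasta-b*-on-semolina-b* regression residuals, trait
   correlations, and candidate-gene LD.
8. **synthetic panels** — a Balding–Nichols + copying-process generator for
   structured inbred panels with controllable LD decay, missing data, and
   single-SNP or allelic-series (multi-SNP, non-additive) QTL with full
   ground truth.

## CLI

Every stage is exposed as a subcommand of `hapgwas`:

```bash
hapgwas simulate --lines 169 --subpops 4 --seed 1 --out panel
hapgwas qc --genotypes panel.genotypes.tsv --out qc.tsv
hapgwas impute --genotypes qc.tsv --map panel.map.csv --seed 1 --out imputed.tsv
hapgwas ld --genotypes imputed.tsv --map panel.map.csv --scope genome --out ld.csv
hapgwas blocks --genotypes imputed.tsv --map panel.map.csv --window 5.3 --out hap
hapgwas structure --genotypes imputed.tsv --groups 4 --seed 1 --out Q.csv
hapgwas kinship --genotypes imputed.tsv --out K.csv
hapgwas assoc --genotypes imputed.tsv --map panel.map.csv \
    --phenotypes panel.phenotypes.csv --trait trait --model mlm-qk --out assoc.csv
```

or end to end from a YAML config:

```bash
hapgwas run --config cfg.yaml
```

where `cfg.yaml` names the three input files plus thresholds, model list,
window source (`fitted` from the LD decay or `fixed`), FDR alpha and seeds.
Outputs (CSV/TSV/JSON, including a manifest with input checksums) land in
the configured output directory; reruns with the same config are
byte-identical.

## File formats

- genotype TSV: `marker<TAB>alleles<TAB><line>...`, one marker per row,
  single IUPAC bases per call (`N` missing); numeric-dose dialect uses
  `0/1/2` with `NA`.
- map CSV: `marker,chrom,cM`.
- phenotype CSV: first column line id, one column per trait.
- VCF: sites + GT only; `./.` is missing.

All coordinates are genetic (cM).
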