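"""Genotype, map, and phenotype containers plus file I/O and marker QC.

Dose coding: lines x markers, ``0`` and ``2`` for the two homozygotes,
``1`` for a heterozygote (tolerated on input, treated as missing by the
LD/haplotype stages), ``-1`` for a missing call.

Supported on-disk dialects
--------------------------
``hapmap``  markers as rows; columns ``marker<TAB>alleles<TAB><line>...``
            with single IUPAC bases per call (``N`` missing, ambiguity
            code for a het).
``dose``    same shape but numeric calls ``0/1/2`` with ``NA`` missing.
``vcf``     sites + GT only; ``./.`` maps to missing (read via cyvcf2
            when available, otherwise a minimal text parser).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError, ParameterError

# IUPAC ambiguity codes used to encode heterozygous calls in hapmap TSV.
_IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_IUPAC_HET_REV = {v: k for k, v in _IUPAC_HET.items()}


@dataclass
class GenotypeMatrix:
    """Allele-dose matrix of inbred lines by biallelic markers.

    Parameters
    ----------
    line_ids : list of str
        Unique line identifiers (rows of `dose`).
    marker_ids : list of str
        Unique marker identifiers (columns of `dose`).
    dose : ndarray of int8, shape (n_lines, n_markers)
        Allele doses in {0, 1, 2} with -1 for missing.
    alleles : ndarray of str, shape (n_markers, 2), optional
        Reference/alternate base letters per marker; defaults to A/B.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dose: np.ndarray
    alleles: np.ndarray | None = None

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.int8)
        if self.dose.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ParameterError(
                f"dose shape {self.dose.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ParameterError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ParameterError("duplicate marker ids")
        bad = ~np.isin(self.dose, (-1, 0, 1, 2))
        if bad.any():
            raise ParameterError(f"invalid dose values: {np.unique(self.dose[bad])}")
        if self.alleles is None:
            self.alleles = np.array([("A", "B")] * self.n_markers, dtype=object)
        else:
            self.alleles = np.asarray(self.alleles, dtype=object)
            if self.alleles.shape != (self.n_markers, 2):
                raise ParameterError("alleles must have shape (n_markers, 2)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dose == -1

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return self.missing_mask.mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing calls.

        Markers with no observed calls get NaN.
        """
        d = self.dose.astype(float)
        d[self.missing_mask] = np.nan
        with np.errstate(invalid="ignore"):
            f = np.nanmean(d, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def dose_of(self, marker_id: str) -> np.ndarray:
        return self.dose[:, self.marker_index(marker_id)]

    def subset_markers(self, index: np.ndarray | list) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            dose=self.dose[:, idx].copy(),
            alleles=self.alleles[idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.line_ids), list(self.marker_ids), self.dose.copy(), self.alleles.copy()
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.dose, other.dose)
        )


@dataclass
class GeneticMap:
    """Marker positions on a genetic (cM) map."""

    chrom: dict[str, str]
    pos: dict[str, float]

    def __post_init__(self):
        for m, p in self.pos.items():
            if not np.isfinite(p):
                raise ParameterError(f"non-finite position for marker {m!r}")

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.pos

    def __len__(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(self.chrom.values())
        return list(seen)

    def markers_on(self, chrom: str) -> list[str]:
        """Marker ids on `chrom`, sorted by position (ties by id)."""
        ms = [m for m, c in self.chrom.items() if c == chrom]
        return sorted(ms, key=lambda m: (self.pos[m], m))

    def unmapped(self, marker_ids) -> list[str]:
        return [m for m in marker_ids if m not in self.pos]

    def distance(self, a: str, b: str) -> float:
        """|cM difference|; inf for markers on different chromosomes."""
        if self.chrom[a] != self.chrom[b]:
            return float("inf")
        return abs(self.pos[a] - self.pos[b])


class PhenotypeTable:
    """Line-mean trait values, wrapped around a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise ParameterError("duplicate line ids in phenotype table")
        self.df = df.astype(float)

    @property
    def line_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def traits(self) -> list[str]:
        return list(self.df.columns)

    def trait(self, name: str) -> pd.Series:
        return self.df[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, PhenotypeTable) and self.df.equals(other.df)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _dose_from_base(base: str, ref: str, alt: str, marker: str, line_no: int) -> int:
    if base == "N":
        return -1
    if base == ref:
        return 0
    if base == alt:
        return 2
    pair = _IUPAC_HET_REV.get(base)
    if pair is not None and pair == frozenset((ref, alt)):
        return 1
    raise FormatError(f"call {base!r} not consistent with alleles {ref}/{alt} at {marker}", line_no)


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from `hapmap`/`dose` TSV or a VCF."""
    path = Path(path)
    if format == "auto":
        if path.suffix.lower() == ".vcf":
            format = "vcf"
        else:
            with open(path) as fh:
                header = fh.readline()
            format = "vcf" if header.startswith("##fileformat=VCF") else "hapmap"
    if format == "vcf":
        return _read_vcf(path)
    if format not in ("hapmap", "dose"):
        raise ParameterError(f"unknown genotype format {format!r}")

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError("empty genotype file", 1)
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "marker":
        raise FormatError("expected header 'marker<TAB>alleles<TAB><line ids...>'", 1)
    line_ids = header[2:]
    n = len(line_ids)
    marker_ids, allele_rows, dose_rows = [], [], []
    for ln, row in enumerate(lines[1:], start=2):
        fields = row.split("\t")
        if len(fields) != n + 2:
            raise FormatError(f"expected {n + 2} fields, found {len(fields)}", ln)
        marker, alleles = fields[0], fields[1]
        try:
            ref, alt = alleles.split("/")
        except ValueError:
            raise FormatError(f"bad alleles field {alleles!r}", ln) from None
        if format == "hapmap":
            doses = [_dose_from_base(b, ref, alt, marker, ln) for b in fields[2:]]
        else:
            doses = []
            for v in fields[2:]:
                if v in ("NA", "N", "."):
                    doses.append(-1)
                elif v in ("0", "1", "2"):
                    doses.append(int(v))
                else:
                    raise FormatError(f"bad dose value {v!r}", ln)
        marker_ids.append(marker)
        allele_rows.append((ref, alt))
        dose_rows.append(doses)
    dose = np.array(dose_rows, dtype=np.int8).T if dose_rows else np.empty((n, 0), np.int8)
    return GenotypeMatrix(line_ids, marker_ids, dose, np.array(allele_rows, dtype=object))


def write_genotypes(g: GenotypeMatrix, path, format: str = "hapmap") -> None:
    path = Path(path)
    if format == "vcf":
        _write_vcf(g, path)
        return
    if format not in ("hapmap", "dose"):
        raise ParameterError(f"unknown genotype format {format!r}")
    with open(path, "w") as fh:
        fh.write("marker\talleles\t" + "\t".join(g.line_ids) + "\n")
        for j, marker in enumerate(g.marker_ids):
            ref, alt = g.alleles[j]
            if format == "hapmap":
                het = _IUPAC_HET.get(frozenset((ref, alt)), "H")
                lut = {-1: "N", 0: ref, 1: het, 2: alt}
            else:
                lut = {-1: "NA", 0: "0", 1: "1", 2: "2"}
            calls = "\t".join(lut[int(d)] for d in g.dose[:, j])
            fh.write(f"{marker}\t{ref}/{alt}\t{calls}\n")


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path), gts012=True)
    line_ids = list(vcf.samples)
    marker_ids, allele_rows, dose_cols = [], [], []
    for var in vcf:
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        alt = var.ALT[0] if var.ALT else "B"
        allele_rows.append((var.REF, alt))
        gts = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2 doses; 3 unknown
        gts[gts == 3] = -1
        dose_cols.append(gts)
    dose = (
        np.column_stack(dose_cols) if dose_cols else np.empty((len(line_ids), 0), np.int8)
    )
    return GenotypeMatrix(line_ids, marker_ids, dose, np.array(allele_rows, dtype=object))


def _read_vcf_text(path: Path) -> GenotypeMatrix:
    """Fallback plain-text VCF reader (sites + GT only)."""
    line_ids: list[str] = []
    marker_ids, allele_rows, dose_rows = [], [], []
    with open(path) as fh:
        for ln, row in enumerate(fh, start=1):
            row = row.rstrip("\n")
            if row.startswith("##") or not row:
                continue
            if row.startswith("#CHROM"):
                line_ids = row.split("\t")[9:]
                continue
            f = row.split("\t")
            if len(f) < 10:
                raise FormatError("VCF record with no genotype columns", ln)
            marker_ids.append(f[2] if f[2] != "." else f"{f[0]}_{f[1]}")
            allele_rows.append((f[3], f[4] if f[4] != "." else "B"))
            doses = []
            for call in f[9:]:
                gt = call.split(":")[0].replace("|", "/")
                if gt in ("./.", "."):
                    doses.append(-1)
                else:
                    doses.append(sum(int(a) for a in gt.split("/")))
            dose_rows.append(doses)
    dose = np.array(dose_rows, np.int8).T if dose_rows else np.empty((len(line_ids), 0), np.int8)
    return GenotypeMatrix(line_ids, marker_ids, dose, np.array(allele_rows, dtype=object))


def _write_vcf(g: GenotypeMatrix, path: Path, gmap: GeneticMap | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.line_ids) + "\n")
        gt_lut = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for j, marker in enumerate(g.marker_ids):
            if gmap is not None and marker in gmap:
                chrom = gmap.chrom[marker]
                pos = int(round(gmap.pos[marker] * 10000)) + 1  # cM scaled to int
            else:
                chrom, pos = "0", j + 1
            ref, alt = g.alleles[j]
            calls = "\t".join(gt_lut[int(d)] for d in g.dose[:, j])
            fh.write(f"{chrom}\t{pos}\t{marker}\t{ref}\t{alt}\t.\t.\t.\tGT\t{calls}\n")


def read_map(path) -> GeneticMap:
    """Read a genetic map CSV with columns marker, chrom, cM."""
    df = pd.read_csv(path)
    required = {"marker", "chrom", "cM"}
    if not required.issubset(df.columns):
        raise FormatError(f"map CSV must have columns {sorted(required)}; found {list(df.columns)}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise FormatError(f"duplicate marker id in map: {dup!r}")
    return GeneticMap(
        chrom=dict(zip(df["marker"], df["chrom"].astype(str))),
        pos=dict(zip(df["marker"], df["cM"].astype(float))),
    )


def write_map(gmap: GeneticMap, path) -> None:
    rows = [(m, gmap.chrom[m], gmap.pos[m]) for m in gmap.pos]
    pd.DataFrame(rows, columns=["marker", "chrom", "cM"]).to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype CSV: first column line ids, remaining columns traits."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("phenotype CSV needs a line column and at least one trait")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df.rename_axis("line").to_csv(path)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Counts of markers removed by each QC rule (a marker can hit both)."""

    n_input: int
    n_retained: int
    n_failed_missing: int
    n_failed_maf: int
    removed_missing: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    maf_basis: str = "non-missing calls, pre-imputation"


def qc_filter(
    g: GenotypeMatrix, max_missing: float = 0.25, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers with missing fraction > `max_missing` or MAF < `min_maf`.

    MAF is computed on non-missing calls. Raises
    :class:`~hapgwas.errors.EmptyResultError` if nothing survives.
    """
    if not (0 <= max_missing <= 1) or not (0 <= min_maf <= 1):
        raise ParameterError("thresholds must lie in [0, 1]")
    miss = g.missing_fraction()
    maf = g.maf()
    fail_missing = miss > max_missing
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf >= min_maf)  # NaN MAF (all missing) also fails
    keep = ~(fail_missing | fail_maf)
    report = QcReport(
        n_input=g.n_markers,
        n_retained=int(keep.sum()),
        n_failed_missing=int(fail_missing.sum()),
        n_failed_maf=int(fail_maf.sum()),
        removed_missing=[m for m, f in zip(g.marker_ids, fail_missing) if f],
        removed_maf=[m for m, f in zip(g.marker_ids, fail_maf) if f],
    )
    if not keep.any():
        raise EmptyResultError("no markers pass QC")
    return g.subset_markers(keep), report
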