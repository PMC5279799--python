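"""Haplotype-block construction: dedup, LD windows, allele calls, PIC.

Each chromosome is partitioned into consecutive half-open windows of a
fixed cM width anchored at the chromosome's first marker; windows holding
at least two markers become multi-allelic haplotype loci named
``hap_{chrom}_{index}`` with indices counting emitted blocks in map
order. A line's block allele is the concatenation of its member-SNP base
letters; alleles rarer than ``min_haf`` are pooled into a single "rare"
class, and a block is dropped when fewer than two classes survive
pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genotypes import GeneticMap, GenotypeMatrix

RARE = "rare"


@dataclass
class DedupReport:
    """Maps each retained representative marker to its duplicate group."""

    groups: dict[str, list[str]]

    @property
    def n_removed(self) -> int:
        return sum(len(v) - 1 for v in self.groups.values())


def deduplicate(g: GenotypeMatrix, gmap: GeneticMap) -> tuple[GenotypeMatrix, DedupReport]:
    """Collapse same-chromosome markers with identical dose columns.

    Columns identical after a global allele flip (dose -> 2 - dose) also
    collapse. The representative is the member with the smallest cM
    position (ties broken by marker id).
    """
    if g.missing_mask.any():
        raise ParameterError("deduplicate requires an imputed matrix")
    groups: dict[tuple, list[str]] = {}
    for m in g.marker_ids:
        if m not in gmap:
            raise ParameterError(f"marker {m!r} not on the map")
        col = g.dose_of(m)
        flipped = (2 - col).astype(np.int8)
        key = (gmap.chrom[m], min(col.tobytes(), flipped.tobytes()))
        groups.setdefault(key, []).append(m)

    keep: list[str] = []
    report: dict[str, list[str]] = {}
    for members in groups.values():
        members = sorted(members, key=lambda m: (gmap.pos[m], m))
        keep.append(members[0])
        report[members[0]] = members
    keep_idx = [g.marker_index(m) for m in sorted(keep, key=g.marker_index)]
    out = g.subset_markers(keep_idx)
    return out, DedupReport(groups=report)


@dataclass
class HaplotypeBlock:
    locus_id: str
    chrom: str
    start: float  # cM of first member
    end: float  # cM of last member
    members: list[str]  # marker ids sorted by cM

    @property
    def n_snps(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeBlockSet:
    blocks: list[HaplotypeBlock]
    singletons: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    window_cM: float | None = None
    # filled by call_block_alleles:
    calls: pd.DataFrame | None = None  # lines x locus_id, strings (or RARE)
    frequencies: dict[str, dict[str, float]] = field(default_factory=dict)

    def block(self, locus_id: str) -> HaplotypeBlock:
        for b in self.blocks:
            if b.locus_id == locus_id:
                return b
        raise KeyError(locus_id)

    def summary(self) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            freqs = self.frequencies.get(b.locus_id)
            rows.append(
                {
                    "locus": b.locus_id,
                    "chrom": b.chrom,
                    "start_cM": b.start,
                    "end_cM": b.end,
                    "nbM": b.n_snps,
                    "n_alleles": len(freqs) if freqs else np.nan,
                    "PIC": pic(list(freqs.values())) if freqs else np.nan,
                }
            )
        return pd.DataFrame(rows)


def build_blocks(
    gmap: GeneticMap, window_cM: float, marker_ids: list[str] | None = None
) -> HaplotypeBlockSet:
    """Partition each chromosome into fixed-width windows of markers.

    Windows are half-open ``[s + k*w, s + (k+1)*w)`` anchored at the
    chromosome's first marker position ``s``; only windows with >= 2
    markers are emitted as blocks.
    """
    if window_cM <= 0:
        raise ParameterError("window_cM must be > 0")
    universe = set(marker_ids) if marker_ids is not None else None
    if universe is not None:
        missing = [m for m in universe if m not in gmap]
        if missing:
            raise ParameterError(f"unmapped marker {missing[0]!r}")

    blocks: list[HaplotypeBlock] = []
    singletons: list[str] = []
    for chrom in gmap.chromosomes():
        ms = [m for m in gmap.markers_on(chrom) if universe is None or m in universe]
        if not ms:
            continue
        anchor = gmap.pos[ms[0]]
        windows: dict[int, list[str]] = {}
        for m in ms:
            k = int(np.floor((gmap.pos[m] - anchor) / window_cM))
            windows.setdefault(k, []).append(m)
        index = 0
        for k in sorted(windows):
            members = windows[k]
            if len(members) < 2:
                singletons.extend(members)
                continue
            index += 1
            blocks.append(
                HaplotypeBlock(
                    locus_id=f"hap_{chrom}_{index}",
                    chrom=chrom,
                    start=gmap.pos[members[0]],
                    end=gmap.pos[members[-1]],
                    members=list(members),
                )
            )
    return HaplotypeBlockSet(blocks=blocks, singletons=singletons, window_cM=window_cM)


def call_block_alleles(
    g: GenotypeMatrix, blockset: HaplotypeBlockSet, min_haf: float = 0.05
) -> HaplotypeBlockSet:
    """Call per-line block alleles and pool rare ones.

    A line's allele at a block is the ordered concatenation of its member
    SNP base letters. Alleles with frequency < `min_haf` are pooled into
    the ``"rare"`` class; blocks left with fewer than two >=`min_haf`
    classes are dropped (listed in ``dropped``).
    """
    if g.missing_mask.any():
        raise ParameterError("call_block_alleles requires an imputed matrix")
    kept: list[HaplotypeBlock] = []
    dropped: list[str] = []
    freqs_out: dict[str, dict[str, float]] = {}
    calls = {}
    n = g.n_lines
    for b in blockset.blocks:
        cols = [g.marker_index(m) for m in b.members]
        letters = np.empty((n, len(cols)), dtype=object)
        for k, j in enumerate(cols):
            ref, alt = g.alleles[j]
            d = g.dose[:, j]
            letters[:, k] = np.where(d == 0, ref, np.where(d == 2, alt, "?"))
        allele = np.array(["".join(row) for row in letters])
        valid = np.array(["?" not in a for a in allele])  # het members invalidate a call
        counts = pd.Series(allele[valid]).value_counts()
        freq = counts / counts.sum()
        common = freq[freq >= min_haf]
        if len(common) < 2:
            dropped.append(b.locus_id)
            continue
        pooled = np.where(np.isin(allele, common.index.to_numpy()), allele, RARE)
        pooled = np.where(valid, pooled, None)
        kept.append(b)
        calls[b.locus_id] = pooled
        f = {a: float(v) for a, v in common.items()}
        rare_mass = float(freq[freq < min_haf].sum())
        if rare_mass > 0:
            f[RARE] = rare_mass
        freqs_out[b.locus_id] = f
    df = pd.DataFrame(calls, index=pd.Index(g.line_ids, name="line"))
    return HaplotypeBlockSet(
        blocks=kept,
        singletons=list(blockset.singletons),
        dropped=dropped,
        window_cM=blockset.window_cM,
        calls=df,
        frequencies=freqs_out,
    )


def pic(freqs) -> float:
    """Polymorphism information content of an allele-frequency vector.

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0):
        raise ParameterError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ParameterError(f"frequencies sum to {p.sum()}, not 1")
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2 * s2 - s4)
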