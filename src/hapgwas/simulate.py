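"""Synthetic structured inbred panels with block-wise LD and known QTL.

The generator produces fully homozygous lines (doses {0, 2}) from a
Balding–Nichols-style divergence model: each subpopulation's allele
frequencies are Beta-distributed around a shared ancestral frequency with
spread controlled by ``fst``. Along each chromosome, alleles are drawn
through a first-order copying process on a shared latent uniform so that
the dose correlation between markers at map distance ``d`` decays roughly
as ``exp(-ld_rho * d)`` — the decay rate is the directly controlled
quantity.

Trait values are the sum of QTL effects (single-SNP or allelic-series),
a polygenic background scaled against the residual noise, and Gaussian
noise. The full generating state is returned as a :class:`TruthRecord`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ParameterError
from .genotypes import GeneticMap, GenotypeMatrix, PhenotypeTable

import pandas as pd


@dataclass
class QTLSpec:
    """One simulated QTL.

    For ``kind="single"`` the trait gains ``effects["1"]`` per line that is
    homozygous for the alternate allele at one marker inside the interval.
    For ``kind="series"`` a set of ``n_snps`` nearby markers is chosen and
    ``effects`` maps joint allele strings (e.g. ``"010"``, one 0/1 digit
    per member SNP) to trait shifts; unlisted combinations contribute 0.
    A series whose effects are not additive in the digits cannot be
    captured by any single constituent SNP.
    """

    chrom: str
    start: float
    end: float
    kind: Literal["single", "series"] = "single"
    n_snps: int = 1
    effects: dict[str, float] = field(default_factory=lambda: {"1": 1.0})

    def validate(self, chrom_lengths: dict[str, float]) -> None:
        if self.chrom not in chrom_lengths:
            raise ParameterError(f"QTL chromosome {self.chrom!r} not simulated")
        if not (0 <= self.start <= self.end <= chrom_lengths[self.chrom]):
            raise ParameterError(
                f"QTL interval [{self.start}, {self.end}] outside chromosome {self.chrom}"
            )
        if self.kind == "single" and self.n_snps != 1:
            raise ParameterError("single-SNP QTL must have n_snps=1")
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")
        for combo, eff in self.effects.items():
            if len(combo) != self.n_snps or set(combo) - set("01"):
                raise ParameterError(f"bad allele combination key {combo!r}")
            if not np.isfinite(eff):
                raise ParameterError("QTL effects must be finite")


@dataclass
class SimConfig:
    n_lines: int = 169
    n_subpops: int = 4
    fst: float = 0.15
    chromosomes: list[tuple[str, float]] = field(
        default_factory=lambda: [("1A", 100.0), ("1B", 100.0)]
    )
    markers_per_chrom: int = 200
    ld_rho: float = 0.3
    missing_rate: float = 0.0
    qtl_spec: list[QTLSpec] = field(default_factory=list)
    h2_polygenic: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2 or self.n_subpops < 1 or self.markers_per_chrom < 1:
            raise ParameterError("n_lines, n_subpops and markers_per_chrom must be positive")
        if self.n_subpops > self.n_lines:
            raise ParameterError("more subpopulations than lines")
        for frac, name in ((self.fst, "fst"), (self.missing_rate, "missing_rate"),
                           (self.h2_polygenic, "h2_polygenic")):
            if not (0 <= frac < 1):
                raise ParameterError(f"{name} must lie in [0, 1)")
        if self.ld_rho <= 0:
            raise ParameterError("ld_rho must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ParameterError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ParameterError(f"chromosome {name!r} has non-positive length")
        for q in self.qtl_spec:
            q.validate(lengths)


@dataclass
class TruthRecord:
    """Ground truth of a simulated panel, JSON-serializable."""

    subpop_labels: list[int]
    qtl_markers: list[list[str]]
    qtl_effects: list[dict[str, float]]
    polygenic_values: list[float]
    ancestral_freqs: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def _copying_haplotypes(rng, freqs, positions, n_lines, ld_rho):
    """Draw inbred haplotypes with distance-decaying LD.

    freqs: (n_lines, m) per-line target allele frequencies (the line's
    subpopulation frequencies). A shared latent uniform is copied from the
    previous marker with probability exp(-ld_rho * gap), preserving
    marginal frequencies while correlating nearby markers.
    """
    m = freqs.shape[1]
    u = np.empty((n_lines, m))
    u[:, 0] = rng.random(n_lines)
    gaps = np.diff(positions)
    copy_p = np.exp(-ld_rho * gaps)
    for j in range(1, m):
        fresh = rng.random(n_lines)
        keep = rng.random(n_lines) < copy_p[j - 1]
        u[:, j] = np.where(keep, u[:, j - 1], fresh)
    return (u < freqs).astype(np.int8)  # 0/1 haplotype alleles


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeMatrix, GeneticMap, PhenotypeTable, TruthRecord]:
    """Simulate genotypes, a map, one trait, and the generating truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_lines

    # Deterministic near-equal split into subpopulations.
    labels = np.array([1 + (i * config.n_subpops) // n for i in range(n)])

    line_ids = [f"L{i + 1:03d}" for i in range(n)]
    chrom_names, chrom_pos, marker_ids = [], [], []
    for name, length in config.chromosomes:
        pos = rng.uniform(0.0, length, size=config.markers_per_chrom)
        # guarantee every QTL interval holds enough markers: seed an even
        # grid of n_snps positions inside each interval on this chromosome
        for q in config.qtl_spec:
            if q.chrom == name:
                inner = np.linspace(q.start, q.end, q.n_snps + 2)[1:-1]
                pos = np.concatenate([pos, inner])
        pos = np.sort(pos)
        chrom_names.append(name)
        chrom_pos.append(pos)
        marker_ids.extend(f"M_{name}_{k + 1}" for k in range(len(pos)))

    # Ancestral and subpopulation allele frequencies (Balding–Nichols).
    m_total = sum(len(p) for p in chrom_pos)
    p_anc = rng.uniform(0.1, 0.9, size=m_total)
    if config.fst > 0:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        p_sub = np.clip(
            rng.beta(a, b, size=(config.n_subpops, m_total)), 1e-4, 1 - 1e-4
        )
    else:
        p_sub = np.tile(p_anc, (config.n_subpops, 1))

    dose_cols = []
    offset = 0
    for pos in chrom_pos:
        m = len(pos)
        freqs = p_sub[labels - 1, offset : offset + m]
        hap = _copying_haplotypes(rng, freqs, pos, n, config.ld_rho)
        dose_cols.append(2 * hap)
        offset += m
    dose = np.concatenate(dose_cols, axis=1)

    chrom_of = {}
    start = 0
    for name, pos in zip(chrom_names, chrom_pos):
        for mid in marker_ids[start : start + len(pos)]:
            chrom_of[mid] = name
        start += len(pos)
    gmap = GeneticMap(chrom=chrom_of, pos=dict(zip(marker_ids, np.concatenate(chrom_pos))))

    # QTL genetic values.
    genetic = np.zeros(n)
    qtl_markers: list[list[str]] = []
    for q in config.qtl_spec:
        members = _pick_qtl_markers(gmap, q)
        qtl_markers.append(members)
        member_idx = [marker_ids.index(m) for m in members]
        alleles = (dose[:, member_idx] // 2).astype(str)
        combos = np.array(["".join(row) for row in alleles])
        for combo, eff in q.effects.items():
            genetic += np.where(combos == combo, eff, 0.0)

    # Polygenic background: scaled so poly-variance / (poly + noise) = h2.
    beta = rng.normal(size=m_total)
    poly = (dose - dose.mean(axis=0)) @ beta
    sd = poly.std()
    if sd > 0 and config.h2_polygenic > 0:
        target_var = (
            config.h2_polygenic / (1 - config.h2_polygenic) * max(config.noise_sd, 1e-12) ** 2
        )
        poly = poly / sd * np.sqrt(target_var)
    else:
        poly = np.zeros(n)

    y = genetic + poly + rng.normal(0.0, config.noise_sd, size=n)
    pheno = PhenotypeTable(pd.DataFrame({"trait": y}, index=pd.Index(line_ids, name="line")))

    g = GenotypeMatrix(line_ids, marker_ids, dose)
    if config.missing_rate > 0:
        g = inject_missing(g, config.missing_rate, seed=int(rng.integers(2**31)))

    truth = TruthRecord(
        subpop_labels=[int(x) for x in labels],
        qtl_markers=qtl_markers,
        qtl_effects=[dict(q.effects) for q in config.qtl_spec],
        polygenic_values=[float(v) for v in poly],
        ancestral_freqs=dict(zip(marker_ids, map(float, p_anc))),
    )
    return g, gmap, pheno, truth


def _pick_qtl_markers(gmap: GeneticMap, q: QTLSpec) -> list[str]:
    inside = [
        m for m in gmap.markers_on(q.chrom) if q.start <= gmap.pos[m] <= q.end
    ]
    if len(inside) < q.n_snps:
        raise ParameterError(
            f"QTL interval [{q.start}, {q.end}] on {q.chrom} holds "
            f"{len(inside)} markers, needs {q.n_snps}"
        )
    centre = (q.start + q.end) / 2
    picked = sorted(inside, key=lambda m: (abs(gmap.pos[m] - centre), m))[: q.n_snps]
    return sorted(picked, key=lambda m: gmap.pos[m])


def inject_missing(genotypes: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each call to missing independently with probability `rate`."""
    if not (0 <= rate < 1):
        raise ParameterError("missing rate must lie in [0, 1)")
    out = genotypes.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.dose.shape) < rate
    out.dose[mask] = -1
    return out
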