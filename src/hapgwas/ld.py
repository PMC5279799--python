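"""Pairwise LD, background (critical) r-squared, and decay-curve fitting.

LD between two loci is the squared Pearson correlation of allele doses
across lines; for fully inbred material this equals D^2 / (pA pa pB pb).
The background level is estimated from pairs of loci on different
chromosomes, either as the squared 95th percentile on the sqrt(r2) scale
(parametric) or as a plain empirical quantile. The decay of expected r2
with genetic distance follows the drift-sampling expectation

    E[r2] = ((10+C)/((2+C)(11+C))) * (1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C)))

with C = rho * d, fitted by nonlinear least squares; the decay distance
is the map distance at which the fitted curve falls to the background
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EmptyResultError, FitError, MonomorphicError, ParameterError
from .genotypes import GeneticMap, GenotypeMatrix


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dose vectors across lines."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ParameterError("dose vectors must be 1-D, equal length, n >= 2")
    if np.any(x < 0) or np.any(y < 0):
        raise ParameterError("missing doses present; impute before LD analysis")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MonomorphicError("r2 undefined for a monomorphic locus")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class LDTable:
    """Long-format table of marker pairs with distance and r2."""

    df: pd.DataFrame  # columns: marker_i, marker_j, distance, r2
    n: int  # lines used
    scope: str

    def __len__(self) -> int:
        return len(self.df)


def _corr_sq(dose: np.ndarray) -> np.ndarray:
    """Pairwise r2 matrix over columns of a no-missing dose matrix."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(dose, rowvar=False)
    return c * c


def ld_table(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    scope: str = "genome",
    subsample: int | None = None,
    seed: int | None = None,
) -> LDTable:
    """Enumerate (or seeded-subsample) marker pairs and their r2.

    scope: a chromosome name for within-chromosome pairs, ``"genome"`` for
    all within-chromosome pairs genome-wide, or ``"interchromosomal"``
    for pairs of loci on different chromosomes (distance unset).
    """
    if g.missing_mask.any():
        raise ParameterError("genotypes must be imputed before LD analysis")
    mapped = [m for m in g.marker_ids if m in gmap]
    rows: list[tuple] = []

    if scope == "interchromosomal":
        idx = {m: g.marker_index(m) for m in mapped}
        pairs = [
            (a, b) for a, b in combinations(mapped, 2) if gmap.chrom[a] != gmap.chrom[b]
        ]
        if subsample is not None and subsample < len(pairs):
            rng = np.random.default_rng(seed)
            chosen = rng.choice(len(pairs), size=subsample, replace=False)
            pairs = [pairs[i] for i in sorted(chosen)]
        for a, b in pairs:
            rows.append((a, b, np.nan, pairwise_r2(g.dose[:, idx[a]], g.dose[:, idx[b]])))
    else:
        chroms = gmap.chromosomes() if scope == "genome" else [scope]
        for chrom in chroms:
            ms = [m for m in gmap.markers_on(chrom) if m in set(mapped)]
            if len(ms) < 2:
                warnings.warn(f"chromosome {chrom!r} has <2 markers; empty LD table")
                continue
            cols = [g.marker_index(m) for m in ms]
            r2 = _corr_sq(g.dose[:, cols].astype(float))
            pos = np.array([gmap.pos[m] for m in ms])
            for i, j in combinations(range(len(ms)), 2):
                rows.append((ms[i], ms[j], abs(pos[i] - pos[j]), r2[i, j]))
        if subsample is not None and subsample < len(rows):
            rng = np.random.default_rng(seed)
            chosen = rng.choice(len(rows), size=subsample, replace=False)
            rows = [rows[i] for i in sorted(chosen)]

    df = pd.DataFrame(rows, columns=["marker_i", "marker_j", "distance", "r2"])
    return LDTable(df=df, n=g.n_lines, scope=scope)


Z_95 = 1.6449  # standard normal 95th percentile


def critical_r2(unlinked: LDTable, method: str = "parametric-sqrt", q: float = 0.95) -> float:
    """Background LD threshold from the unlinked (inter-chromosomal) r2."""
    r2 = unlinked.df["r2"].to_numpy()
    if r2.size < 2:
        raise EmptyResultError("need at least 2 unlinked pairs for a threshold")
    if r2.size < 30:
        warnings.warn(f"only {r2.size} unlinked pairs; threshold is unstable")
    if method == "parametric-sqrt":
        root = np.sqrt(r2)
        z = Z_95 if q == 0.95 else stats.norm.ppf(q)
        thr = (root.mean() + z * root.std(ddof=1)) ** 2
    elif method == "empirical":
        thr = float(np.quantile(r2, q))
    else:
        raise ParameterError(f"unknown critical-r2 method {method!r}")
    return float(np.clip(thr, 0.0, 1.0))


def expected_r2(d: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Drift-sampling expectation of r2 at map distance d (cM), C = rho*d."""
    C = rho * np.asarray(d, dtype=float)
    t1 = (10 + C) / ((2 + C) * (11 + C))
    t2 = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    return t1 * t2


@dataclass
class DecayFit:
    rho: float
    n: int
    critical_r2: float
    decay_distance: float | None  # None when the curve never crosses

    def to_dict(self) -> dict:
        return asdict(self)


def fit_decay(intra: LDTable, n: int | None = None, critical: float = 0.2) -> DecayFit:
    """Fit the decay rate rho and locate the distance where E[r2] = critical."""
    if len(intra) == 0:
        raise EmptyResultError("empty intra-chromosomal LD table")
    d = intra.df["distance"].to_numpy(dtype=float)
    r2 = intra.df["r2"].to_numpy(dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ParameterError("intra-chromosomal distances must be finite and >= 0")
    n = int(n if n is not None else intra.n)

    try:
        (rho_hat,), pcov = optimize.curve_fit(
            lambda dd, rho: expected_r2(dd, rho, n),
            d,
            r2,
            p0=[0.5],
            bounds=(1e-9, np.inf),
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"decay fit did not converge: {exc}") from exc
    if not np.isfinite(rho_hat):
        raise FitError(f"decay fit returned rho={rho_hat}; cov={pcov}")

    return DecayFit(
        rho=float(rho_hat),
        n=n,
        critical_r2=float(critical),
        decay_distance=decay_distance(float(rho_hat), n, float(critical), d.max()),
    )


def decay_distance(rho: float, n: int, critical: float, d_max: float) -> float | None:
    """Smallest d > 0 with E[r2](d) <= critical, by bracketed root search."""
    lo = 1e-6
    f = lambda dd: expected_r2(dd, rho, n) - critical
    if f(lo) <= 0:
        return lo
    hi = max(d_max, 1.0)
    # expand the bracket: the curve is monotone decreasing toward ~1/n
    for _ in range(60):
        if f(hi) <= 0:
            break
        hi *= 2
    else:
        return None  # never crosses (critical below the asymptote)
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


def per_chromosome_decay(
    g: GenotypeMatrix, gmap: GeneticMap, critical: float
) -> dict[str, DecayFit]:
    """Independent decay fits per chromosome (skipping <2-marker ones)."""
    out = {}
    for chrom in gmap.chromosomes():
        table = ld_table(g, gmap, scope=chrom)
        if len(table) == 0:
            continue
        out[chrom] = fit_decay(table, n=g.n_lines, critical=critical)
    return out
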