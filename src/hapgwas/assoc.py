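"""Single-SNP and multi-allelic haplotype association scans.

Models
------
``glm-naive``  OLS F-test of the locus term given an intercept.
``glm-q``      as above plus structure covariates Q.
``mlm-k``      mixed model y = Xb + locus + u + e with Var(u) = sg2*K,
               variance components by REML through the eigendecomposition
               of K; the locus F-test is run on the whitened
               (generalized-least-squares) scale.
``mlm-qk``     mixed model with Q covariates as well.

With ``p3d=True`` (default) the variance components are estimated once
under the no-locus null and reused for every locus; ``p3d=False``
re-estimates them per locus.

A SNP locus contributes a single dose regressor; a haplotype locus
contributes h-1 indicator columns with the most frequent allele as the
reference and the pooled "rare" class kept as an ordinary level (levels
carried by fewer than `min_level_count` lines are merged into the
reference).

Marker R2 is reported as the percent reduction in residual sum of
squares attributable to the locus term after the covariates, computed on
the whitened scale for mixed models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .blocks import RARE, HaplotypeBlockSet
from .errors import ParameterError
from .genotypes import GeneticMap, GenotypeMatrix
from .structure import KinshipMatrix, q_covariates

log = logging.getLogger(__name__)

MODELS = ("glm-naive", "glm-q", "mlm-k", "mlm-qk")


@dataclass
class Locus:
    """A testable locus: design columns plus descriptive metadata."""

    locus_id: str
    design: np.ndarray  # n x p columns for the locus term
    chrom: str | None = None
    start: float | None = None
    end: float | None = None
    n_snps: int = 1
    kind: str = "snp"  # "snp" | "haplotype"


def snp_loci(g: GenotypeMatrix, gmap: GeneticMap | None = None) -> list[Locus]:
    """One 1-df dose regressor per marker (hets enter as dose 1)."""
    loci = []
    for j, m in enumerate(g.marker_ids):
        chrom = gmap.chrom.get(m) if gmap else None
        pos = gmap.pos.get(m) if gmap else None
        loci.append(
            Locus(
                locus_id=m,
                design=g.dose[:, j].astype(float)[:, None],
                chrom=chrom,
                start=pos,
                end=pos,
                kind="snp",
            )
        )
    return loci


def haplotype_loci(blockset: HaplotypeBlockSet, min_level_count: int = 3) -> list[Locus]:
    """Indicator design per block: reference = most frequent allele.

    Levels with fewer than `min_level_count` carriers are merged into the
    reference. Blocks left with a single level are skipped (logged).
    """
    if blockset.calls is None:
        raise ParameterError("blockset has no allele calls; run call_block_alleles")
    loci = []
    for b in blockset.blocks:
        calls = blockset.calls[b.locus_id]
        counts = calls.value_counts(dropna=True)
        if counts.empty:
            continue
        reference = counts.index[0]
        levels = []
        for lev, cnt in counts.items():
            if lev == reference:
                continue
            if cnt < min_level_count:
                log.info("block %s: level %r (%d lines) merged into reference", b.locus_id, lev, cnt)
                continue
            levels.append(lev)
        if not levels:
            log.info("block %s skipped: single usable level", b.locus_id)
            continue
        design = np.column_stack([(calls == lev).to_numpy(dtype=float) for lev in levels])
        loci.append(
            Locus(
                locus_id=b.locus_id,
                design=design,
                chrom=b.chrom,
                start=b.start,
                end=b.end,
                n_snps=b.n_snps,
                kind="haplotype",
            )
        )
    return loci


# ---------------------------------------------------------------------------
# REML via eigendecomposition of K (EMMA-style)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float

    @property
    def delta(self) -> float:
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf


def _check_psd(K: np.ndarray) -> np.ndarray:
    """Eigendecompose K; shift tiny negative eigenvalues, error on real ones."""
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6 * max(1.0, lam.max()):
        raise ParameterError(f"kinship not PSD (min eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)
    return lam, U


def _reml_delta(y_r: np.ndarray, X_r: np.ndarray, lam: np.ndarray) -> float:
    """Maximize the restricted likelihood over delta = se2/sg2.

    y_r, X_r are already rotated into the eigenbasis of K (lam = eigenvalues).
    """
    n, q = X_r.shape

    def neg_restricted_ll(log_delta: float) -> float:
        w = lam + np.exp(log_delta)
        Xw = X_r / w[:, None]
        XtWX = X_r.T @ Xw
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ y_r)
        except np.linalg.LinAlgError:
            return np.inf
        resid = y_r - X_r @ beta
        rss = float(resid @ (resid / w))
        sg2 = rss / (n - q)
        sign, logdet_xtwx = np.linalg.slogdet(XtWX)
        if sign <= 0 or sg2 <= 0:
            return np.inf
        ll = -0.5 * (
            (n - q) * (np.log(2 * np.pi * sg2) + 1)
            + float(np.log(w).sum())
            + logdet_xtwx
        )
        return -ll

    grid = np.linspace(-10.0, 10.0, 41)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
    best = res.x if res.fun <= vals[i] else grid[i]
    return float(np.exp(best))


def reml_variance_components(
    y: np.ndarray, X: np.ndarray, K: np.ndarray
) -> tuple[VarianceComponents, np.ndarray, np.ndarray]:
    """REML sg2/se2 for y = Xb + u + e, Var(u)=sg2*K. Returns (vc, lam, U)."""
    lam, U = _check_psd(K)
    y_r = U.T @ y
    X_r = U.T @ X
    delta = _reml_delta(y_r, X_r, lam)
    w = lam + delta
    Xw = X_r / w[:, None]
    beta = np.linalg.solve(X_r.T @ Xw, Xw.T @ y_r)
    resid = y_r - X_r @ beta
    n, q = X_r.shape
    sg2 = float(resid @ (resid / w)) / (n - q)
    return VarianceComponents(sigma_g2=sg2, sigma_e2=delta * sg2), lam, U


# ---------------------------------------------------------------------------
# F-tests
# ---------------------------------------------------------------------------

def _rss_rank(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _f_test(y: np.ndarray, X0: np.ndarray, locus_cols: np.ndarray):
    """F-test of the locus columns given covariates X0 (both pre-whitened)."""
    rss0, rank0 = _rss_rank(y, X0)
    X1 = np.column_stack([X0, locus_cols])
    rss1, rank1 = _rss_rank(y, X1)
    df1 = rank1 - rank0
    df2 = len(y) - rank1
    if df1 < 1 or df2 < 1:
        return None
    num = max(rss0 - rss1, 0.0)
    if rss1 <= 0:
        p = 0.0 if num > 0 else 1.0
        return np.inf, df1, df2, p, 100.0
    F = (num / df1) / (rss1 / df2)
    p = float(stats.f.sf(F, df1, df2))
    r2_pct = 100.0 * num / rss0 if rss0 > 0 else 0.0
    return float(F), df1, df2, max(p, np.finfo(float).tiny), r2_pct


@dataclass
class AssocResult:
    """Per-locus association statistics for one trait under one model."""

    df: pd.DataFrame
    model: str
    trait: str = "trait"
    n_lines: int = 0
    metadata: dict = field(default_factory=dict)

    def pvalues(self) -> np.ndarray:
        return self.df["p"].to_numpy()

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        if "adj_p" not in self.df:
            raise ParameterError("run adjust_fdr first (adj_p column missing)")
        return self.df[self.df["adj_p"] < alpha]


def scan(
    y,
    loci: list[Locus],
    model: str = "mlm-qk",
    Q: np.ndarray | None = None,
    K: KinshipMatrix | np.ndarray | None = None,
    p3d: bool = True,
    fdr_alpha: float | None = 0.05,
    var_components: VarianceComponents | None = None,
    trait: str = "trait",
) -> AssocResult:
    """Run an association scan of `loci` against trait vector `y`.

    `y` may contain NaN; those lines are dropped from every design.
    `var_components`, when given, fixes sg2/se2 (skips REML) — used for
    oracle comparisons and degenerate cases.
    """
    if model not in MODELS:
        raise ParameterError(f"model must be one of {MODELS}")
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    yk = y[keep]
    n = int(keep.sum())
    if n < 3:
        raise ParameterError("fewer than 3 phenotyped lines")

    covs = [np.ones((n, 1))]
    if model in ("glm-q", "mlm-qk"):
        if Q is None:
            raise ParameterError(f"model {model} requires Q")
        covs.append(q_covariates(np.asarray(Q)[keep]))
    X0 = np.column_stack(covs)

    whiten = None
    if model.startswith("mlm"):
        if K is None:
            raise ParameterError(f"model {model} requires K")
        Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        Kv = Kv[np.ix_(keep, keep)]
        if var_components is None and p3d:
            vc, lam, U = reml_variance_components(yk, X0, Kv)
        elif var_components is not None:
            vc = var_components
            lam, U = _check_psd(Kv)
        else:
            vc, lam, U = None, *_check_psd(Kv)

        def make_whitener(vc_local):
            d = vc_local.delta
            if np.isinf(d):  # sg2 == 0 -> plain OLS
                w = np.ones_like(lam)
            else:
                w = lam + d
            scale = 1.0 / np.sqrt(w)
            return lambda A: (U.T @ A) * (scale[:, None] if A.ndim == 2 else scale)

        whiten = make_whitener(vc) if vc is not None else None

    rows = []
    for locus in loci:
        L = locus.design[keep]
        if model.startswith("mlm") and not p3d and var_components is None:
            vc_l, lam_l, U_l = reml_variance_components(
                yk, np.column_stack([X0, L]), Kv
            )
            scale = 1.0 / np.sqrt(lam_l + vc_l.delta)
            wfun = lambda A: (U_l.T @ A) * (scale[:, None] if A.ndim == 2 else scale)
            res = _f_test(wfun(yk), wfun(X0), wfun(L))
        elif whiten is not None:
            res = _f_test(whiten(yk), whiten(X0), whiten(L))
        else:
            res = _f_test(yk, X0, L)
        if res is None:
            log.info("locus %s skipped: no testable degrees of freedom", locus.locus_id)
            continue
        F, df1, df2, p, r2 = res
        rows.append(
            {
                "locus": locus.locus_id,
                "kind": locus.kind,
                "chrom": locus.chrom,
                "start_cM": locus.start,
                "end_cM": locus.end,
                "nbM": locus.n_snps,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "r2_pct": r2,
            }
        )
    df = pd.DataFrame(rows)
    meta = {"p3d": p3d, "r2_definition": "percent RSS reduction after covariates (whitened for MLM)"}
    if model.startswith("mlm") and "vc" in locals() and vc is not None:
        meta["sigma_g2"] = vc.sigma_g2
        meta["sigma_e2"] = vc.sigma_e2
    result = AssocResult(df=df, model=model, trait=trait, n_lines=n, metadata=meta)
    if fdr_alpha is not None and len(df):
        adj, sig, pi0 = adjust_fdr(df["p"].to_numpy(), alpha=fdr_alpha)
        result.df["adj_p"] = adj
        result.df["significant"] = sig
        result.metadata["pi0"] = pi0
    return result


# ---------------------------------------------------------------------------
# Adaptive FDR and QQ
# ---------------------------------------------------------------------------

def adjust_fdr(
    pvals, alpha: float = 0.05, lam: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Adaptive step-up FDR adjustment with estimated null proportion.

    pi0 = (#{p_i > lam} + 1) / (m * (1 - lam)), capped at 1, with
    lam = alpha / (1 + alpha) by default; adjusted p-values follow the
    step-up rule with m replaced by m * pi0. Returns (adjusted, significant,
    pi0-hat).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in (0, 1]")
    if lam is None:
        lam = alpha / (1 + alpha)
    m = p.size
    pi0 = min(1.0, (float((p > lam).sum()) + 1.0) / (m * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted, adjusted < alpha, pi0


def qq_points(pvals) -> pd.DataFrame:
    """Expected vs observed -log10(p) for a QQ plot."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value vector")
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)  # descending
    observed = -np.log10(np.sort(p))  # descending (smallest p first)
    return pd.DataFrame({"expected": expected, "observed": observed})
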