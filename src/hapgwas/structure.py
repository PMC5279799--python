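"""Population structure (PCA + k-means + LDA membership) and kinship.

The structure routine mirrors the discriminant-analysis-of-principal-
components workflow: centred doses are reduced to at most floor(N/3)
principal components, groups are found by k-means on the scores (k fixed
or chosen by BIC over 1..10), and a linear discriminant fit on the
scores yields per-line membership probabilities Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.mixture import GaussianMixture

from .errors import ParameterError
from .genotypes import GenotypeMatrix


def max_retained_pcs(n_lines: int) -> int:
    """Retention rule: at most N/3 principal components."""
    return n_lines // 3


@dataclass
class StructureResult:
    n_pcs: int
    assignments: np.ndarray  # group label per line, 1-based
    Q: np.ndarray  # lines x groups membership probabilities
    variance_explained: float  # fraction captured by the retained PCs
    bic: dict[int, float] | None = None  # k -> BIC when k was chosen automatically

    @property
    def n_groups(self) -> int:
        return self.Q.shape[1]


def _pc_scores(g: GenotypeMatrix, n_pcs: int) -> tuple[np.ndarray, float]:
    X = g.dose.astype(float)
    X -= X.mean(axis=0)
    # SVD is deterministic and exact; avoids randomized-solver seed issues.
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    n_pcs = min(n_pcs, int((var > 1e-10 * var[0]).sum()))
    scores = U[:, :n_pcs] * s[:n_pcs]
    explained = float(var[:n_pcs].sum() / total) if total > 0 else 0.0
    return scores, explained


def _kmeans_labels(scores: np.ndarray, k: int, seed: int | None) -> np.ndarray:
    if k == 1:
        return np.zeros(scores.shape[0], dtype=int)
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores).labels_


def _auto_k(scores: np.ndarray, seed: int | None, k_max: int = 10) -> tuple[int, dict[int, float]]:
    """Choose the group number by spherical Gaussian-mixture BIC.

    A raw k-means within-cluster-SS criterion over-splits in high
    dimension (the split always shaves some variance off a null cloud);
    the mixture BIC with a proper likelihood stays at k=1 on
    unstructured panels.
    """
    bics: dict[int, float] = {}
    for k in range(1, min(k_max, scores.shape[0]) + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="spherical", n_init=3, random_state=seed
        ).fit(scores)
        bics[k] = float(gm.bic(scores))
    best = min(bics, key=bics.get)
    return best, bics


def dapc_structure(
    g: GenotypeMatrix,
    n_groups: int | str = "auto",
    n_pcs: int | None = None,
    seed: int | None = None,
) -> StructureResult:
    """Infer group membership probabilities from genotype principal components."""
    if g.missing_mask.any():
        raise ParameterError("structure analysis requires an imputed matrix")
    n = g.n_lines
    cap = max_retained_pcs(n)
    requested = cap if n_pcs is None else n_pcs
    if requested < 1:
        raise ParameterError("need at least one principal component")
    scores, explained = _pc_scores(g, min(requested, cap))

    bic_table = None
    if n_groups == "auto":
        k, bic_table = _auto_k(scores, seed)
    else:
        k = int(n_groups)
        if k < 1 or k > n:
            raise ParameterError(f"n_groups={k} outside 1..{n}")
    labels = _kmeans_labels(scores, k, seed)

    if k == 1:
        Q = np.ones((n, 1))
    else:
        lda = LinearDiscriminantAnalysis()
        lda.fit(scores, labels)
        Q = lda.predict_proba(scores)
        labels = np.asarray(lda.predict(scores))
        # map arbitrary k-means labels to 1..k in order of first appearance
    order = {lab: i for i, lab in enumerate(dict.fromkeys(labels.tolist()))}
    assignments = np.array([order[lab] + 1 for lab in labels])
    Q = Q[:, [lab for lab in dict.fromkeys(labels.tolist())]] if k > 1 else Q
    return StructureResult(
        n_pcs=scores.shape[1],
        assignments=assignments,
        Q=Q,
        variance_explained=explained,
        bic=bic_table,
    )


@dataclass
class KinshipMatrix:
    values: np.ndarray  # lines x lines
    line_ids: list[str]
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.line_ids), len(self.line_ids)):
            raise ParameterError("kinship matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ParameterError("kinship matrix must be symmetric")
        self.values = v


def kinship_matrix(g: GenotypeMatrix, method: str = "scaled-ibs") -> KinshipMatrix:
    """Line-by-line similarity: scaled allele sharing or VanRaden cross-product."""
    if g.n_lines < 2:
        raise ParameterError("kinship needs at least two lines")
    if g.missing_mask.any():
        raise ParameterError("kinship requires an imputed matrix")
    D = g.dose.astype(float)
    if method == "scaled-ibs":
        # mean per-marker allele sharing: 1 - |di - dj| / 2
        n, m = D.shape
        diff = np.abs(D[:, None, :] - D[None, :, :]).sum(axis=2)
        s = 1.0 - diff / (2.0 * m)
        mn = s.min()
        K = (s - mn) / (1.0 - mn) if mn < 1.0 else np.ones_like(s)
    elif method == "centered":
        p = D.mean(axis=0) / 2.0
        Z = D - 2.0 * p
        denom = float(np.sum(4.0 * p * (1.0 - p)))  # inbred dose variance 4pq
        if denom <= 0:
            raise ParameterError("all markers monomorphic; kinship undefined")
        K = Z @ Z.T / denom
    else:
        raise ParameterError(f"unknown kinship method {method!r}")
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, line_ids=list(g.line_ids), method=method)


def q_covariates(Q: np.ndarray) -> np.ndarray:
    """Full-rank covariate block from membership probabilities (drop last column)."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2:
        raise ParameterError("Q must be 2-D")
    return Q[:, :-1] if Q.shape[1] > 1 else np.empty((Q.shape[0], 0))
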