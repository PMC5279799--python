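"""Random-forest genotype imputation from flanking mapped markers.

Each marker with missing calls gets its own random-forest classifier
trained on the nearest mapped markers (map distance, same chromosome,
falling back to the rest of the genome when the chromosome is short).
The working matrix starts from a per-marker mode fill and is swept
``max_iter`` times, so later markers see the previous sweep's
predictions. Observed calls are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ImputationError, ParameterError
from .genotypes import GeneticMap, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class ImputeConfig:
    n_trees: int = 100
    n_neighbors: int = 30
    max_iter: int = 2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_trees, self.n_neighbors, self.max_iter) < 1:
            raise ParameterError("n_trees, n_neighbors and max_iter must be >= 1")


def _mode_fill_value(col: np.ndarray) -> int:
    """Most frequent observed homozygote; ties go to the major allele (dose 2
    when counts tie exactly, the larger observed class otherwise)."""
    obs = col[(col == 0) | (col == 2)]
    if obs.size == 0:
        raise ImputationError("marker has no observed homozygous calls")
    n2 = int((obs == 2).sum())
    n0 = obs.size - n2
    return 2 if n2 >= n0 else 0


def _neighbor_indices(gmap: GeneticMap, marker_ids: list[str], j: int, k: int) -> np.ndarray:
    """Indices of the k markers nearest to marker j by map distance.

    Same-chromosome markers rank first (by |cM| gap); if fewer than k
    exist, the remainder is taken from other chromosomes in input order.
    """
    target = marker_ids[j]
    dists = []
    for i, m in enumerate(marker_ids):
        if i == j:
            continue
        d = gmap.distance(target, m)
        dists.append((d, i))
    dists.sort()
    return np.array([i for _, i in dists[:k]], dtype=int)


def impute_missing(
    g: GenotypeMatrix, gmap: GeneticMap, cfg: ImputeConfig
) -> GenotypeMatrix:
    """Return a copy of `g` with every missing call imputed to 0 or 2."""
    cfg.validate()
    unmapped = gmap.unmapped(g.marker_ids)
    if unmapped:
        raise ParameterError(f"{len(unmapped)} markers missing from map, e.g. {unmapped[0]!r}")

    out = g.copy()
    missing = out.missing_mask
    if not missing.any():
        return out

    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = out.marker_ids[int(np.flatnonzero(all_missing)[0])]
        raise ImputationError(f"marker {bad!r} has no observed calls; cannot train")

    # Working matrix: mode fill as the starting point.
    work = out.dose.copy()
    targets = np.flatnonzero(missing.any(axis=0))
    for j in targets:
        work[missing[:, j], j] = _mode_fill_value(out.dose[:, j])

    seeds = np.random.SeedSequence(cfg.seed).spawn(len(targets) * cfg.max_iter)
    si = 0
    for _sweep in range(cfg.max_iter):
        for j in targets:
            col = out.dose[:, j]
            miss_rows = missing[:, j]
            train_rows = (col == 0) | (col == 2)  # hets never train
            y_train = col[train_rows]
            if len(np.unique(y_train)) < 2:
                work[miss_rows, j] = int(y_train[0])
                si += 1
                continue
            nb = _neighbor_indices(gmap, out.marker_ids, j, cfg.n_neighbors)
            if nb.size == 0:
                work[miss_rows, j] = _mode_fill_value(col)
                si += 1
                continue
            rf = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                random_state=int(seeds[si].generate_state(1)[0] % (2**31)),
                n_jobs=1,
            )
            rf.fit(work[np.ix_(train_rows, nb)], y_train)
            work[miss_rows, j] = rf.predict(work[np.ix_(miss_rows, nb)]).astype(np.int8)
            si += 1

    # Only ever replace the originally-missing cells.
    out.dose[missing] = work[missing]
    assert not out.missing_mask.any()
    return out


def mode_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Baseline: fill every missing call with the marker's modal homozygote."""
    out = g.copy()
    for j in np.flatnonzero(out.missing_mask.any(axis=0)):
        out.dose[out.missing_mask[:, j], j] = _mode_fill_value(out.dose[:, j])
    return out
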