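import numpy as np
import pandas as pd
import pytest

from hapgwas.errors import EmptyResultError, MonomorphicError, ParameterError
from hapgwas.genotypes import GeneticMap, GenotypeMatrix
from hapgwas.ld import (
    DecayFit,
    LDTable,
    critical_r2,
    decay_distance,
    expected_r2,
    fit_decay,
    ld_table,
    pairwise_r2,
    per_chromosome_decay,
)


def r2_from_haplotype_counts(x, y):
    """Independent oracle: D^2 / (pA pa pB pb) from 2x2 haplotype counts
    (valid for inbred lines where each line is one haplotype)."""
    a = (np.asarray(x) // 2).astype(float)
    b = (np.asarray(y) // 2).astype(float)
    pA, pB = a.mean(), b.mean()
    pAB = np.mean(a * b)
    D = pAB - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


class TestPairwiseR2:
    def test_identical_vectors(self):
        x = np.array([0, 2, 2, 0, 2])
        assert pairwise_r2(x, x) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert pairwise_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_matches_frequency_count_oracle(self):
        x = np.array([0, 0, 2, 2, 2, 0, 2, 0])
        y = np.array([0, 2, 2, 2, 0, 0, 2, 2])
        assert pairwise_r2(x, y) == pytest.approx(r2_from_haplotype_counts(x, y), abs=1e-12)

    def test_symmetric_and_label_invariant(self, rng):
        x = rng.choice([0, 2], size=30)
        y = rng.choice([0, 2], size=30)
        base = pairwise_r2(x, y)
        assert pairwise_r2(y, x) == pytest.approx(base)
        assert pairwise_r2(2 - x, y) == pytest.approx(base)
        assert pairwise_r2(x, 2 - y) == pytest.approx(base)
        perm = rng.permutation(30)
        assert pairwise_r2(x[perm], y[perm]) == pytest.approx(base)

    def test_monomorphic_rejected(self):
        with pytest.raises(MonomorphicError):
            pairwise_r2([2, 2, 2, 2], [0, 2, 0, 2])

    def test_missing_rejected(self):
        with pytest.raises(ParameterError):
            pairwise_r2([-1, 2, 0], [0, 2, 0])


def _grid_panel(markers_per_chrom, chroms=("1A",), n=40, seed=0):
    rng = np.random.default_rng(seed)
    ids, chrom, pos = [], {}, {}
    for c in chroms:
        for i in range(markers_per_chrom):
            m = f"{c}_m{i}"
            ids.append(m)
            chrom[m] = c
            pos[m] = float(i)
    dose = rng.choice([0, 2], size=(n, len(ids))).astype(np.int8)
    # guard against monomorphic columns
    dose[0] = 0
    dose[1] = 2
    return GenotypeMatrix([f"L{i}" for i in range(n)], ids, dose), GeneticMap(chrom, pos)


class TestLdTable:
    def test_three_markers_three_rows(self):
        g, gmap = _grid_panel(3)
        assert len(ld_table(g, gmap, scope="genome")) == 3

    def test_interchromosomal_cardinality(self):
        g, gmap = _grid_panel(2, chroms=("1A", "2B"))
        t = ld_table(g, gmap, scope="interchromosomal")
        assert len(t) == 4
        assert t.df["distance"].isna().all()

    def test_subsample_deterministic(self):
        g, gmap = _grid_panel(30, chroms=("1A", "2B"))
        a = ld_table(g, gmap, scope="interchromosomal", subsample=100, seed=9)
        b = ld_table(g, gmap, scope="interchromosomal", subsample=100, seed=9)
        assert a.df.equals(b.df)

    def test_single_marker_chromosome_warns(self):
        g, gmap = _grid_panel(1)
        with pytest.warns(UserWarning):
            t = ld_table(g, gmap, scope="1A")
        assert len(t) == 0


class TestCriticalR2:
    def test_degenerate_empirical(self):
        df = pd.DataFrame({"marker_i": "a", "marker_j": "b", "distance": np.nan,
                           "r2": [0.3] * 50})
        t = LDTable(df=df, n=100, scope="interchromosomal")
        assert critical_r2(t, method="empirical") == pytest.approx(0.3)

    def test_parametric_closed_form(self, rng):
        # sqrt(r2) ~ N(0.3, 0.1): threshold -> (0.3 + 1.6449*0.1)^2 = 0.21556
        root = rng.normal(0.3, 0.1, size=10**5)
        df = pd.DataFrame({"marker_i": "a", "marker_j": "b", "distance": np.nan,
                           "r2": root**2})
        t = LDTable(df=df, n=100, scope="interchromosomal")
        assert critical_r2(t) == pytest.approx((0.3 + 1.6449 * 0.1) ** 2, abs=0.005)

    def test_null_panel_threshold_small(self):
        # independent markers, 169 lines: E[r2] ~ 1/n, threshold < 0.1
        g, gmap = _grid_panel(40, chroms=("1A", "2B"), n=169, seed=3)
        t = ld_table(g, gmap, scope="interchromosomal")
        assert critical_r2(t) < 0.1

    def test_too_few_pairs(self):
        df = pd.DataFrame({"marker_i": ["a"], "marker_j": ["b"], "distance": [np.nan],
                           "r2": [0.2]})
        with pytest.raises(EmptyResultError):
            critical_r2(LDTable(df=df, n=10, scope="interchromosomal"))


class TestExpectedR2:
    def test_analytic_limits(self):
        # d=0 and n -> infinity: 10/22
        assert expected_r2(0.0, rho=1.0, n=10**9) == pytest.approx(10 / 22, abs=1e-6)
        # C -> infinity tends to the sampling floor ~1/n -> 0 for huge n
        assert expected_r2(1e9, rho=1.0, n=10**9) < 1e-6

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0.0, 200.0, 500)
        vals = expected_r2(d, rho=0.4, n=169)
        assert np.all(np.diff(vals) < 0)


class TestFitDecay:
    def _exact_table(self, rho, n, n_points=200, d_max=50.0):
        d = np.linspace(0.05, d_max, n_points)
        df = pd.DataFrame({"marker_i": "a", "marker_j": "b", "distance": d,
                           "r2": expected_r2(d, rho, n)})
        return LDTable(df=df, n=n, scope="genome")

    def test_self_consistent_recovery(self):
        t = self._exact_table(rho=0.5, n=169)
        fit = fit_decay(t, n=169, critical=0.2)
        assert fit.rho == pytest.approx(0.5, rel=0.01)

    def test_noisy_decay_distance_within_10pct(self, rng):
        rho, n = 0.3, 169
        d = rng.uniform(0.05, 50.0, size=10**4)
        r2 = np.clip(expected_r2(d, rho, n) + rng.normal(0, 0.05, size=d.size), 0, 1)
        t = LDTable(df=pd.DataFrame({"marker_i": "a", "marker_j": "b",
                                     "distance": d, "r2": r2}), n=n, scope="genome")
        fit = fit_decay(t, n=n, critical=0.2)
        exact = decay_distance(rho, n, 0.2, 50.0)
        assert fit.decay_distance == pytest.approx(exact, rel=0.10)

    def test_never_crossing_flagged(self):
        # critical below the large-C sampling floor (~1/n): no crossing
        t = self._exact_table(rho=0.5, n=169)
        fit = fit_decay(t, n=169, critical=1e-5)
        assert fit.decay_distance is None

    def test_empty_table_rejected(self):
        t = LDTable(df=pd.DataFrame(columns=["marker_i", "marker_j", "distance", "r2"]),
                    n=10, scope="genome")
        with pytest.raises(EmptyResultError):
            fit_decay(t, n=10, critical=0.2)


class TestPerChromosomeDecay:
    def test_genome_fit_within_per_chromosome_range(self):
        from hapgwas.simulate import SimConfig, simulate_panel

        cfg = SimConfig(n_lines=150, n_subpops=1, fst=0.0,
                        chromosomes=[("1A", 100.0), ("2A", 100.0), ("3A", 100.0)],
                        markers_per_chrom=100, ld_rho=0.4, seed=12)
        g, gmap, *_ = simulate_panel(cfg)
        genome = fit_decay(ld_table(g, gmap, scope="genome"), n=g.n_lines, critical=0.1)
        per = per_chromosome_decay(g, gmap, critical=0.1)
        dists = [f.decay_distance for f in per.values()]
        assert len(dists) == 3
        assert min(dists) <= genome.decay_distance <= max(dists)
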