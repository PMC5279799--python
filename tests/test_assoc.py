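import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapgwas.assoc import (
    Locus,
    VarianceComponents,
    adjust_fdr,
    haplotype_loci,
    qq_points,
    scan,
    snp_loci,
)
from hapgwas.blocks import build_blocks, call_block_alleles, deduplicate
from hapgwas.errors import ParameterError
from hapgwas.structure import dapc_structure, kinship_matrix


def ols_f_oracle(y, X0, X1_extra):
    """Brute-force normal-equations F-test of extra columns."""
    X1 = np.column_stack([X0, X1_extra])
    b0 = np.linalg.solve(X0.T @ X0, X0.T @ y)
    b1 = np.linalg.solve(X1.T @ X1, X1.T @ y)
    rss0 = float(((y - X0 @ b0) ** 2).sum())
    rss1 = float(((y - X1 @ b1) ** 2).sum())
    df1 = X1.shape[1] - X0.shape[1]
    df2 = len(y) - X1.shape[1]
    F = ((rss0 - rss1) / df1) / (rss1 / df2)
    return F, stats.f.sf(F, df1, df2)


def gls_f_oracle(y, X0, X1_extra, V):
    """Closed-form GLS F-test with a fixed covariance V (Cholesky whitening)."""
    L = np.linalg.cholesky(V)
    w = lambda A: np.linalg.solve(L, A)
    return ols_f_oracle(w(y), w(X0), w(X1_extra))


class TestGlmOracle:
    def test_matches_normal_equations(self, rng):
        n = 18
        dose = rng.choice([0.0, 2.0], size=n)
        y = 0.5 * dose + rng.normal(size=n)
        res = scan(y, [Locus("snp", dose[:, None])], model="glm-naive", fdr_alpha=None)
        F_o, p_o = ols_f_oracle(y, np.ones((n, 1)), dose[:, None])
        assert res.df["F"][0] == pytest.approx(F_o, abs=1e-10)
        assert res.df["p"][0] == pytest.approx(p_o, abs=1e-10)

    def test_glm_q_matches_oracle(self, rng):
        n = 20
        Q = rng.dirichlet([1, 1, 1], size=n)
        dose = rng.choice([0.0, 2.0], size=n)
        y = rng.normal(size=n) + Q @ [1.0, -1.0, 0.0]
        res = scan(y, [Locus("snp", dose[:, None])], model="glm-q", Q=Q, fdr_alpha=None)
        X0 = np.column_stack([np.ones(n), Q[:, :2]])
        F_o, p_o = ols_f_oracle(y, X0, dose[:, None])
        assert res.df["p"][0] == pytest.approx(p_o, abs=1e-10)

    def test_multilevel_haplotype_design(self, rng):
        n = 30
        levels = rng.choice(["AA", "AB", "BB"], size=n)
        y = rng.normal(size=n) + (levels == "AB") * 2.0
        design = np.column_stack([(levels == l).astype(float) for l in ("AB", "BB")])
        res = scan(y, [Locus("hap", design, kind="haplotype")], model="glm-naive",
                   fdr_alpha=None)
        F_o, p_o = ols_f_oracle(y, np.ones((n, 1)), design)
        assert res.df["df1"][0] == 2
        assert res.df["p"][0] == pytest.approx(p_o, abs=1e-10)


class TestMlm:
    def test_fixed_vc_matches_gls_oracle(self, rng):
        n = 15
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        dose = rng.choice([0.0, 2.0], size=n)
        y = rng.normal(size=n)
        vc = VarianceComponents(sigma_g2=1.3, sigma_e2=0.7)
        res = scan(y, [Locus("snp", dose[:, None])], model="mlm-k", K=K,
                   var_components=vc, fdr_alpha=None)
        V = 1.3 * K + 0.7 * np.eye(n)
        F_o, p_o = gls_f_oracle(y, np.ones((n, 1)), dose[:, None], V)
        assert res.df["F"][0] == pytest.approx(F_o, rel=1e-8)
        assert res.df["p"][0] == pytest.approx(p_o, rel=1e-8)

    def test_identity_kinship_reduces_to_glm(self, rng):
        n = 40
        dose = rng.choice([0.0, 2.0], size=(n, 5))
        y = rng.normal(size=n) + dose[:, 0]
        loci = [Locus(f"m{j}", dose[:, j][:, None]) for j in range(5)]
        glm = scan(y, loci, model="glm-naive", fdr_alpha=None)
        mlm = scan(y, loci, model="mlm-k", K=np.eye(n), fdr_alpha=None)
        # with K = I the whitening is a scalar: p-values must coincide
        assert np.allclose(glm.df["p"], mlm.df["p"], atol=1e-6)

    def test_p3d_vs_exact_close(self, rng):
        n = 30
        A = rng.normal(size=(n, 60))
        K = A @ A.T / 60
        dose = rng.choice([0.0, 2.0], size=n)
        u = np.linalg.cholesky(K + 1e-6 * np.eye(n)) @ rng.normal(size=n)
        y = 0.8 * dose + u + rng.normal(size=n)
        loci = [Locus("snp", dose[:, None])]
        p3 = scan(y, loci, model="mlm-k", K=K, p3d=True, fdr_alpha=None)
        ex = scan(y, loci, model="mlm-k", K=K, p3d=False, fdr_alpha=None)
        assert np.log10(p3.df["p"][0]) == pytest.approx(np.log10(ex.df["p"][0]), abs=0.5)

    def test_missing_phenotypes_dropped(self, rng):
        n = 25
        dose = rng.choice([0.0, 2.0], size=n)
        y = rng.normal(size=n)
        y[:5] = np.nan
        res = scan(y, [Locus("snp", dose[:, None])], model="glm-naive", fdr_alpha=None)
        assert res.n_lines == 20

    def test_requires_k(self, rng):
        with pytest.raises(ParameterError):
            scan(rng.normal(size=10), [], model="mlm-k")


class TestPowerVsSingleSnp:
    def test_haplotype_beats_constituent_snps_on_series_qtl(self):
        """Allelic-series (parity) QTL: the block term sees what no single
        member SNP can (spot check at a handful of seeds; the 50-rep power
        comparison lives in the acceptance suite)."""
        from hapgwas.simulate import QTLSpec, SimConfig, simulate_panel

        wins = 0
        for seed in range(6):
            eff = {c: (1.8 if c.count("1") % 2 == 1 else 0.0)
                   for c in ["000", "001", "010", "011", "100", "101", "110", "111"]}
            cfg = SimConfig(
                n_lines=169, n_subpops=1, fst=0.0,
                chromosomes=[("1A", 60.0), ("2A", 60.0)], markers_per_chrom=20,
                ld_rho=1.5, h2_polygenic=0.2, noise_sd=1.0, seed=seed,
                qtl_spec=[QTLSpec(chrom="1A", start=1.0, end=4.0, kind="series",
                                  n_snps=3, effects=eff)],
            )
            g, gmap, pheno, truth = simulate_panel(cfg)
            y = pheno.df["trait"].to_numpy()
            gd, _ = deduplicate(g, gmap)
            bs = call_block_alleles(gd, build_blocks(gmap, 5.3, marker_ids=gd.marker_ids))
            hap = scan(y, haplotype_loci(bs), model="glm-naive").df.set_index("locus")
            snp = scan(y, snp_loci(gd, gmap), model="glm-naive").df.set_index("locus")
            qtl = set(truth.qtl_markers[0])
            hit = [b.locus_id for b in bs.blocks if qtl & set(b.members) and b.locus_id in hap.index]
            hap_adj = hap.loc[hit, "adj_p"].min() if hit else 1.1
            snp_adj = snp.loc[[m for m in qtl if m in snp.index], "adj_p"].min()
            wins += bool(hap_adj < snp_adj)
        assert wins >= 4


class TestAdjustFdr:
    def test_all_ones(self):
        adj, sig, pi0 = adjust_fdr(np.ones(10))
        assert np.all(adj == 1.0)
        assert not sig.any()

    def test_single_p_hand_computed(self):
        # m=1, p=0.01, lambda=0.05/1.05=0.047619: pi0 = (0+1)/(1*0.952381) -> capped 1
        adj, sig, pi0 = adjust_fdr([0.01], alpha=0.05)
        assert pi0 == 1.0
        assert adj[0] == pytest.approx(0.01)
        assert sig[0]

    def test_step_up_hand_example(self):
        # pi0 estimated from the data, then BH with m*pi0
        p = np.array([0.001, 0.01, 0.03, 0.5, 0.9])
        lam = 0.05 / 1.05
        pi0 = min(1.0, (2 + 1) / (5 * (1 - lam)))
        adj, _, pi0_got = adjust_fdr(p, alpha=0.05)
        assert pi0_got == pytest.approx(pi0)
        expected = p * pi0 * 5 / np.array([1, 2, 3, 4, 5])
        expected = np.minimum.accumulate(expected[::-1])[::-1]
        assert np.allclose(adj, np.minimum(expected, 1.0))

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=200)
        adj, *_ = adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ParameterError):
            adjust_fdr([])
        with pytest.raises(ParameterError):
            adjust_fdr([0.0, 0.5])


class TestQqPoints:
    def test_single_point(self):
        df = qq_points([0.5])
        assert len(df) == 1
        assert df["expected"][0] == pytest.approx(-np.log10(0.5 / 1))

    def test_strong_signal_top_point(self, rng):
        p = np.concatenate([[1e-8], rng.uniform(size=999)])
        df = qq_points(p)
        assert df["observed"].max() == pytest.approx(8.0, abs=0.01)

    def test_uniform_near_diagonal(self):
        ok = 0
        for seed in range(5):
            p = np.random.default_rng(seed).uniform(size=10**4)
            df = qq_points(p)
            ok += np.abs(df["expected"] - df["observed"]).max() < 0.5
        assert ok >= 4


class TestInflationReduction:
    def test_qk_model_reduces_inflation_on_structured_null(self, structured_panel):
        g, gmap, pheno, _ = structured_panel
        y = pheno.df["trait"].to_numpy()
        st = dapc_structure(g, n_groups=4, seed=0)
        K = kinship_matrix(g)
        loci = snp_loci(g, gmap)
        naive = scan(y, loci, model="glm-naive", fdr_alpha=None)
        qk = scan(y, loci, model="mlm-qk", Q=st.Q, K=K, fdr_alpha=None)
        lam = lambda p: np.median(stats.chi2.isf(p, df=1)) / stats.chi2.ppf(0.5, df=1)
        assert lam(qk.pvalues()) < lam(naive.pvalues())
        assert lam(qk.pvalues()) == pytest.approx(1.0, abs=0.25)
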