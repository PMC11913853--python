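"""Normalization and moderated-t differential expression."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tricross import expression as ex
from tricross import sim


def _nb_counts(rng, n_genes, n_samples, mean_log2=(4, 10), phi=0.05, lib=None):
    base = 2.0 ** rng.uniform(*mean_log2, size=n_genes)
    lib = np.ones(n_samples) if lib is None else lib
    mu = base[:, None] * lib[None, :]
    if phi == 0:
        return rng.poisson(mu)
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + mu))


class TestFilter:
    @pytest.mark.parametrize(
        "n_zero, kept",
        [(0, True), (5, True), (6, False), (8, False)],  # 8 samples; boundary 6/8 = 75%
    )
    def test_boundary_inclusive(self, n_zero, kept):
        counts = pd.DataFrame([[0] * n_zero + [5] * (8 - n_zero)], index=["g"])
        out = ex.filter_low_expression(counts)
        assert ("g" in out.index) == kept

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            ex.filter_low_expression(pd.DataFrame([[1]]), fraction=0.0)


class TestTmm:
    def test_identical_samples_unit_factors(self, rng):
        x = _nb_counts(rng, 500, 1, phi=0.0)[:, 0]
        counts = np.tile(x[:, None], (1, 4))
        assert np.allclose(ex.tmm_factors(counts), 1.0)

    def test_scaled_library_factors_equal(self, rng):
        x = _nb_counts(rng, 2000, 3, phi=0.1)
        counts = np.column_stack([x[:, 0], (2 * x[:, 0]), x[:, 1]])
        f = ex.tmm_factors(counts)
        # pure depth scaling is absorbed by library size, not the factor
        assert abs(f[0] / f[1] - 1.0) < 0.01

    def test_single_outlier_gene_trimmed(self, rng):
        x = _nb_counts(rng, 1000, 1, phi=0.0)[:, 0]
        y = x.copy()
        y[0] *= 2  # one doubled gene; trimming should discard it
        f = ex.tmm_factors(np.column_stack([x, y]))
        assert abs(f[1] / f[0] - 1.0) < 0.02

    def test_matches_edger_oracle(self, rng, tmp_path):
        """Independent cross-check against edgeR's calcNormFactors."""
        counts = _nb_counts(rng, 400, 4, phi=0.2,
                            lib=np.array([1.0, 2.0, 0.7, 1.5]))
        # perturb composition so factors differ from 1
        counts[:40, 0] = counts[:40, 0] * 6
        cpath = tmp_path / "counts.tsv"
        pd.DataFrame(counts).to_csv(cpath, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{cpath}"))
            f <- calcNormFactors(x, method="TMM")
            cat(paste(f, collapse=","))
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.skip(f"edgeR oracle unavailable: {exc}")
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        mine = ex.tmm_factors(counts)
        assert np.allclose(mine, ref, rtol=0.02)


class TestLog2Cpm:
    def test_zero_count_formula(self):
        counts = np.array([[0]])
        v = ex.log2_cpm(counts, factors=np.array([1.0]), lib_sizes=np.array([1e6]))
        assert v[0, 0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-9)
        assert v[0, 0] == pytest.approx(-1.0, abs=2e-6)

    def test_depth_scale_invariance(self, rng):
        x = _nb_counts(rng, 300, 2, mean_log2=(6, 10))  # away from the prior-count regime
        a = ex.log2_cpm(x)
        b = ex.log2_cpm(2 * x)
        assert np.allclose(a, b, atol=0.02)

    def test_equal_counts_equal_values(self):
        x = np.array([[10, 10], [90, 90]])
        v = ex.log2_cpm(x)
        assert np.allclose(v[:, 0], v[:, 1])


class TestVoom:
    def test_homoscedastic_weights_constant(self, rng):
        y = rng.normal(5.0, 1.0, size=(5000, 8))
        X = pd.DataFrame({"Intercept": np.ones(8)})
        w = ex.voom_weights(y, X, np.full(8, 1e6))
        assert w.std() / w.mean() < 0.10

    def test_nb_trend_weights_increase_with_abundance(self, rng):
        counts = _nb_counts(rng, 3000, 10, mean_log2=(2, 11), phi=0.05)
        f = ex.tmm_factors(counts)
        lib = counts.sum(axis=0) * f
        y = ex.log2_cpm(counts, f)
        X = pd.DataFrame({"Intercept": np.ones(10)})
        w = ex.voom_weights(y, X, lib)
        mean_count = y.mean(axis=1)
        lo = w[mean_count < np.quantile(mean_count, 0.25)].mean()
        hi = w[mean_count > np.quantile(mean_count, 0.75)].mean()
        assert hi > 2 * lo

    def test_too_few_genes_falls_back(self, rng):
        with pytest.warns(UserWarning):
            w = ex.voom_weights(rng.normal(size=(5, 6)),
                                pd.DataFrame({"i": np.ones(6)}), np.full(6, 1e6))
        assert np.all(w == 1.0)


class TestGeneModels:
    def test_known_slope_recovered(self, rng):
        n = 250
        x = rng.normal(size=n)
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
        y = (0.5 * x + rng.normal(scale=1.0, size=n))[None, :]
        fits = ex.fit_gene_models(y, X)
        se = np.sqrt(fits.sigma2[0]) * fits.stdev_unscaled[0, 1]
        assert abs(fits.coef[0, 1] - 0.5) < 3 * se

    def test_null_t_distribution(self, rng):
        from scipy import stats
        n, G = 12, 5000
        X = pd.DataFrame({"Intercept": np.ones(n), "x": rng.normal(size=n)})
        Y = rng.normal(size=(G, n))
        fits = ex.fit_gene_models(Y, X)
        t = fits.t_ordinary("x")
        ks = stats.kstest(t, stats.t(df=fits.df_residual).cdf)
        assert ks.pvalue > 0.01

    def test_rank_deficient_design_errors(self, rng):
        X = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
        with pytest.raises(ValueError, match="rank deficient"):
            ex.fit_gene_models(rng.normal(size=(3, 10)), X)

    def test_weighted_fit_matches_wls(self, rng):
        import statsmodels.api as sm
        n = 40
        X = pd.DataFrame({"Intercept": np.ones(n), "x": rng.normal(size=n)})
        y = rng.normal(size=(1, n))
        w = rng.uniform(0.5, 2.0, size=(1, n))
        fits = ex.fit_gene_models(y, X, weights=w)
        ref = sm.WLS(y[0], X.values, weights=w[0]).fit()
        assert np.allclose(fits.coef[0], ref.params, atol=1e-8)
        assert np.allclose(np.sqrt(fits.sigma2[0]) * fits.stdev_unscaled[0], ref.bse, atol=1e-8)


class TestEbayes:
    def test_d0_recovered_from_simulation(self, rng):
        # s2_g ~ s0^2 * F(df, d0) with d0 = 4, df = 10
        d0, df, s0_sq = 4.0, 10, 2.0
        s2 = s0_sq * rng.chisquare(df, 10000) / df / (rng.chisquare(d0, 10000) / d0)
        d0_hat, s0_hat = ex.fit_f_dist(s2, df)
        assert abs(d0_hat - d0) / d0 < 0.25
        assert abs(s0_hat - s0_sq) / s0_sq < 0.25

    def test_equal_variances_give_infinite_d0(self, rng):
        n = 8
        X = pd.DataFrame({"Intercept": np.ones(n), "x": rng.normal(size=n)})
        Y = rng.normal(size=(200, n))
        fits = ex.fit_gene_models(Y, X)
        fits.sigma2[:] = 1.5  # all genes share a variance
        mod_t, p, d0, s0_sq = ex.ebayes_moderate(fits, "x")
        assert np.isinf(d0)
        assert np.all(np.isfinite(mod_t))
        # every gene is shrunk onto the common prior variance
        t_pooled = fits.coef[:, 1] / (np.sqrt(s0_sq) * fits.stdev_unscaled[:, 1])
        assert np.allclose(mod_t, t_pooled)

    def test_matches_limma_oracle(self, rng, tmp_path):
        """Moderated t against limma's lmFit + eBayes on a small fixture."""
        n, G = 10, 150
        x = np.repeat([0.0, 1.0], n // 2)
        Y = rng.normal(size=(G, n)) * rng.uniform(0.5, 2.0, size=(G, 1))
        Y[:10] += 1.5 * x
        ypath = tmp_path / "y.tsv"
        pd.DataFrame(Y).to_csv(ypath, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("{ypath}"))
            design <- cbind(1, rep(c(0,1), each={n//2}))
            fit <- eBayes(lmFit(y, design))
            write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior,
                        s0=fit$s2.prior), stdout(), sep="\\t", row.names=FALSE)
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.skip(f"limma oracle unavailable: {exc}")
        from io import StringIO
        ref = pd.read_csv(StringIO(out.stdout), sep="\t")
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
        fits = ex.fit_gene_models(Y, X)
        mod_t, p, d0, s0_sq = ex.ebayes_moderate(fits, "x")
        assert np.allclose(mod_t, ref["t"].values, rtol=1e-3, atol=1e-6)
        assert d0 == pytest.approx(ref["d0"].iloc[0], rel=0.01)
        assert s0_sq == pytest.approx(ref["s0"].iloc[0], rel=0.01)


class TestBhFdr:
    def test_hand_worked_example(self):
        q = ex.bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_degenerate_inputs(self):
        assert np.allclose(ex.bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert ex.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_nan_propagates_without_affecting_ranking(self):
        q = ex.bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], ex.bh_fdr([0.01, 0.02]))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
    def test_monotone_in_p(self, ps):
        q = ex.bh_fdr(ps)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(q[order]) > -1e-12)
        assert np.all((q >= np.asarray(ps) - 1e-12) & (q <= 1.0))


@pytest.fixture(scope="module")
def f0(small_cohort):
    return ex.run_de(small_cohort.f0_counts, small_cohort.f0_pheno, "f0_lineage")


class TestRunDe:
    def test_blr_up_gene_positive_log2fc(self, small_cohort, f0):
        """Sign convention: genes planted up in bLR report positive Log2FC."""
        de = f0
        line_de = small_cohort.planted_line_de.set_index("gene_id")
        strong = de.index.intersection(line_de.index[line_de["log2fc"] > 0])
        assert (de.loc[strong, "log2fc"] > 0).mean() > 0.9

    def test_result_contract(self, f0):
        assert {"log2fc", "t", "mod_t", "p", "q", "ave_expr"} <= set(f0.columns)
        assert np.all(np.sign(f0["log2fc"]) == np.sign(f0["mod_t"]))
        # q monotone in p
        srt = f0.sort_values("p")
        assert np.all(np.diff(srt["q"]) > -1e-12)

    def test_invariant_to_sample_order(self, small_cohort, f0):
        perm = np.random.default_rng(0).permutation(small_cohort.f0_counts.shape[1])
        counts = small_cohort.f0_counts.iloc[:, perm]
        de2 = ex.run_de(counts, small_cohort.f0_pheno, "f0_lineage")
        assert np.allclose(f0["mod_t"].values, de2["mod_t"].values, atol=1e-8)

    def test_missing_covariates_named(self, small_cohort):
        pheno = small_cohort.f0_pheno.drop(columns=["pct_rRNA"])
        with pytest.raises(ValueError, match="pct_rRNA"):
            ex.run_de(small_cohort.f0_counts, pheno, "f0_lineage")

    def test_f2_behavior_model_runs(self, small_cohort):
        de = ex.run_de(small_cohort.f2_counts, small_cohort.f2_pheno, "f2_behavior",
                       behavior="LocoScore")
        assert de.attrs["term"] == "LocoScore"
        assert len(de) > 0

    def test_interaction_term_optional(self, small_cohort):
        de = ex.run_de(small_cohort.f2_counts, small_cohort.f2_pheno, "f2_behavior",
                       behavior="LocoScore", interaction_sex=True)
        assert len(de) > 0


class TestPcaDiagnostics:
    def test_planted_batch_effect_tracks_top_pc(self, rng):
        n, G = 40, 800
        batch = np.repeat(["B1", "B2"], n // 2)
        y = rng.normal(size=(G, n))
        y[: G // 2] += 1.5 * (batch == "B2")  # strong batch effect on half the genes
        pheno = pd.DataFrame({"SequencingBatch": batch, "x": rng.normal(size=n)})
        diag = ex.pca_diagnostics(pd.DataFrame(y), pheno)
        assert diag.loc["SequencingBatch"].max() > 0.5
        assert diag.loc["x"].max() < 0.5
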