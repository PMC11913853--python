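"""cis-eQTL mapping: transforms, scans, permutation beta approximation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tricross import eqtl


def _hwe_dosages(rng, n, m, maf=0.3):
    return rng.binomial(2, maf, size=(n, m)).astype(float)


class TestRint:
    def test_blom_values_n3(self):
        out = eqtl.rint([5.0, 1.0, 9.0])
        # Phi^-1((rank - 3/8)/(n + 1/4)) for ranks (2, 1, 3) of n = 3
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(-0.8694, abs=1e-4)
        assert out[2] == pytest.approx(+0.8694, abs=1e-4)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=51)
        assert np.allclose(eqtl.rint(x), eqtl.rint(np.exp(3 * x)))

    def test_mean_zero_odd_n(self, rng):
        x = rng.normal(size=101)
        assert abs(eqtl.rint(x).mean()) < 1e-6

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            eqtl.rint(np.ones(10))


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        Y = rng.normal(size=(5, 30))
        R = eqtl.residualize(Y, np.ones((30, 1)))
        assert np.allclose(R, Y - Y.mean(axis=1, keepdims=True))

    def test_exact_linear_signal_removed(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x])
        Y = (2.0 + 3.0 * x)[None, :]
        assert np.abs(eqtl.residualize(Y, X)).max() < 1e-10

    def test_orthogonality(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        R = eqtl.residualize(rng.normal(size=(10, 40)), X)
        assert np.abs(R @ X).max() < 1e-8

    def test_rank_deficiency_errors(self, rng):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError):
            eqtl.residualize(rng.normal(size=(2, 20)), X)


class TestLdPrune:
    def test_duplicate_column_removed(self, rng):
        D = _hwe_dosages(rng, 100, 3)
        D = np.column_stack([D, D[:, 0]])
        kept = eqtl.ld_prune(D)
        assert 0 in kept and 3 not in kept

    def test_independent_snps_all_kept(self, rng):
        D = _hwe_dosages(rng, 500, 20)
        assert len(eqtl.ld_prune(D)) == 20

    def test_hand_built_instance_matches_exhaustive_check(self, rng):
        """Retained set never contains a pair with r^2 > threshold, and the
        greedy earlier-index-wins rule is respected."""
        n = 200
        base = _hwe_dosages(rng, n, 2, maf=0.5)
        noise = lambda s: np.clip(base[:, 0] + rng.normal(0, s, n), 0, 2)
        D = np.column_stack([base[:, 0], noise(0.3), base[:, 1], noise(0.4), base[:, 0]])
        kept = eqtl.ld_prune(D, r2_threshold=0.5)
        C = np.corrcoef(D.T) ** 2
        for a in kept:
            for b in kept:
                if a < b:
                    assert C[a, b] <= 0.5
        assert 0 in kept  # first column always survives greedy pruning


class TestPcCovariates:
    def test_spiked_direction_recovered(self, rng):
        n, g = 80, 60
        spike = rng.normal(size=n)
        E = 3.0 * np.outer(rng.normal(size=g), spike) + rng.normal(size=(g, n)) * 0.3
        D = _hwe_dosages(rng, n, 40)
        pcs = eqtl.compute_pc_covariates(E, D, n_pcs=5)
        cos = np.corrcoef(pcs[:, 0], spike)[0, 1]
        assert abs(cos) > 0.95

    def test_orthonormal(self, rng):
        pcs = eqtl.compute_pc_covariates(rng.normal(size=(30, 50)),
                                         _hwe_dosages(rng, 50, 30), n_pcs=5)
        expr, geno = pcs[:, :5], pcs[:, 5:]
        assert np.allclose(expr.T @ expr, np.eye(5), atol=1e-8)
        assert np.allclose(geno.T @ geno, np.eye(5), atol=1e-8)

    def test_sample_permutation_equivariance(self, rng):
        E = rng.normal(size=(30, 50))
        D = _hwe_dosages(rng, 50, 30)
        pcs = eqtl.compute_pc_covariates(E, D)
        perm = rng.permutation(50)
        pcs_p = eqtl.compute_pc_covariates(E[:, perm], D[perm])
        # PCs unique up to sign
        for k in range(pcs.shape[1]):
            assert min(np.abs(pcs_p[:, k] - pcs[perm, k]).max(),
                       np.abs(pcs_p[:, k] + pcs[perm, k]).max()) < 1e-8

    def test_too_few_dimensions(self, rng):
        with pytest.raises(ValueError):
            eqtl.compute_pc_covariates(rng.normal(size=(3, 50)),
                                       _hwe_dosages(rng, 50, 10), n_pcs=5)


class TestNominalScan:
    def test_planted_evariant_power(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 245
            D = _hwe_dosages(rng, n, 30)
            y = eqtl.rint(D[:, 7] * 0.8 + rng.normal(size=n))
            res = eqtl.nominal_scan(y, D, np.ones((n, 1)))
            hits += res["p"][7] < 1e-6
        assert hits >= 19

    def test_null_beta_near_zero(self, rng):
        n = 4000
        D = _hwe_dosages(rng, n, 5)
        y = eqtl.rint(rng.normal(size=n))
        res = eqtl.nominal_scan(y, D, np.ones((n, 1)))
        assert np.abs(res["beta"]).max() < 5 / np.sqrt(n)

    def test_min_p_order_statistic(self):
        """Median of min-p over 100 independent SNPs under the null matches
        the order-statistic expectation 1 - 0.5^(1/100)."""
        min_ps = []
        for s in range(60):
            rng = np.random.default_rng(s)
            n = 200
            D = _hwe_dosages(rng, n, 100)
            y = eqtl.rint(rng.normal(size=n))
            min_ps.append(eqtl.nominal_scan(y, D, np.ones((n, 1)))["p"].min())
        expected_median = 1 - 0.5 ** (1 / 100)
        # binomial CI on the empirical median at 60 draws is generous
        assert 0.2 * expected_median < np.median(min_ps) < 3.0 * expected_median

    def test_empty_window_errors(self, rng):
        with pytest.raises(ValueError):
            eqtl.nominal_scan(rng.normal(size=10), np.empty((10, 0)), np.ones((10, 1)))


class TestPermutationPass:
    def test_single_snp_window_beta_near_uniform(self):
        rng = np.random.default_rng(0)
        n = 150
        D = _hwe_dosages(rng, n, 1)
        y = eqtl.rint(rng.normal(size=n))
        rec = eqtl.permutation_pass(y, D, np.ones((n, 1)), n_perm=2000, seed=1)
        # a single-SNP window has Uniform(0,1) minima: Beta(1,1) within 20%
        assert abs(rec.beta_a - 1.0) < 0.2
        assert abs(rec.beta_b - 1.0) < 0.2

    def test_observed_extreme_matches_direct(self, rng):
        n = 150
        D = _hwe_dosages(rng, n, 20)
        y = eqtl.rint(D[:, 3] + rng.normal(size=n))
        rec = eqtl.permutation_pass(y, D, np.ones((n, 1)), n_perm=300, seed=2)
        assert rec.top_idx == 3
        assert rec.p_empirical < 0.05 and rec.p_perm_direct <= 1 / 300 + 1e-9

    def test_weak_signal_cdf_endpoint(self, rng):
        # observed min p near 1 (constant-ish dosage effect absent, 1 SNP)
        n = 100
        D = _hwe_dosages(rng, n, 1)
        y = eqtl.rint(rng.normal(size=n))
        rec = eqtl.permutation_pass(y, D, np.ones((n, 1)), n_perm=200, seed=3)
        if rec.p_nominal > 0.9:
            assert rec.p_empirical > 0.8

    def test_beta_vs_direct_agreement(self):
        """Beta-approximated empirical p within +/-0.02 (mean absolute) of
        the direct rank-based permutation p across simulated genes."""
        diffs = []
        for s in range(50):
            rng = np.random.default_rng(100 + s)
            n = 150
            D = _hwe_dosages(rng, n, 25)
            strength = [0.0, 0.1, 0.2, 0.3][s % 4]
            y = eqtl.rint(strength * D[:, 0] + rng.normal(size=n))
            rec = eqtl.permutation_pass(y, D, np.ones((n, 1)), n_perm=1000, seed=s)
            diffs.append(abs(rec.p_empirical - rec.p_perm_direct))
        assert np.mean(diffs) < 0.02

    def test_monotone_in_nominal_p(self):
        from scipy.stats import beta as beta_dist
        a, b = 1.3, 18.0
        ps = np.linspace(1e-6, 1, 50)
        emp = beta_dist.cdf(ps, a, b)
        assert np.all(np.diff(emp) >= 0)


class TestEgeneFdr:
    def test_empty_input(self):
        out = eqtl.egene_fdr(pd.DataFrame({"pval_beta": []}))
        assert len(out) == 0

    def test_strong_signals_all_called(self):
        df = pd.DataFrame({"pval_beta": np.full(50, 1e-8)})
        out = eqtl.egene_fdr(df)
        assert out["is_egene"].all()


class TestConditionalScan:
    def _gene_with_two_evariants(self, rng, n=245):
        D = _hwe_dosages(rng, n, 40)
        # two unlinked planted signals
        y = eqtl.rint(0.6 * D[:, 5] + 0.6 * D[:, 30] + rng.normal(size=n))
        return y, D

    def test_two_independent_signals_recovered(self):
        found = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            y, D = self._gene_with_two_evariants(rng)
            covs = np.ones((len(y), 1))
            rec = eqtl.permutation_pass(y, D, covs, n_perm=300, seed=s)
            thr = stats.beta.ppf(0.05, rec.beta_a, rec.beta_b)
            extra = eqtl.conditional_scan(y, D, covs, rec.top_idx, thr, seed=s)
            idx = {rec.top_idx} | {r["snp_idx"] for r in extra}
            found += {5, 30} <= idx and extra[0]["rank"] == 1 if extra else False
        assert found >= 8

    def test_single_signal_no_extra(self):
        none_found = 0
        for s in range(10):
            rng = np.random.default_rng(50 + s)
            n = 245
            D = _hwe_dosages(rng, n, 40)
            y = eqtl.rint(0.8 * D[:, 5] + rng.normal(size=n))
            covs = np.ones((n, 1))
            rec = eqtl.permutation_pass(y, D, covs, n_perm=300, seed=s)
            thr = stats.beta.ppf(0.05, rec.beta_a, rec.beta_b)
            extra = eqtl.conditional_scan(y, D, covs, rec.top_idx, thr, seed=s)
            none_found += len(extra) == 0
        assert none_found >= 9

    def test_perfect_ld_copy_never_second_signal(self, rng):
        n = 245
        D = _hwe_dosages(rng, n, 10)
        D[:, 9] = D[:, 5]  # perfect proxy of the causal SNP
        y = eqtl.rint(0.8 * D[:, 5] + rng.normal(size=n))
        covs = np.ones((n, 1))
        rec = eqtl.permutation_pass(y, D, covs, n_perm=300, seed=0)
        thr = stats.beta.ppf(0.05, rec.beta_a, rec.beta_b)
        extra = eqtl.conditional_scan(y, D, covs, rec.top_idx, thr, seed=0)
        assert {rec.top_idx} <= {5, 9}
        assert all(r["snp_idx"] not in (5, 9) for r in extra)


class TestResolvePerfectLd:
    def test_single_snp(self, rng):
        assert eqtl.resolve_perfect_ld([4], rng) == 4

    def test_uniform_choice(self):
        picks = [eqtl.resolve_perfect_ld([0, 1], np.random.default_rng(s))
                 for s in range(1000)]
        k = sum(picks)
        se = np.sqrt(1000 * 0.25)
        assert abs(k - 500) < 3 * se

    def test_stable_for_fixed_seed(self):
        a = eqtl.resolve_perfect_ld([3, 7, 9], np.random.default_rng(5))
        b = eqtl.resolve_perfect_ld([3, 7, 9], np.random.default_rng(5))
        assert a == b

    def test_empty_errors(self, rng):
        with pytest.raises(ValueError):
            eqtl.resolve_perfect_ld([], rng)


class TestFullMapping:
    def test_sample_permutation_invariance(self, small_cohort):
        """eGene calls are invariant to a consistent permutation of samples
        across genotypes, expression, and covariates."""
        from tricross.expression import F2_COVARIATES, build_design, filter_low_expression, log2_cpm, tmm_factors

        c = small_cohort
        kept = filter_low_expression(c.f2_counts)
        y = log2_cpm(kept, tmm_factors(kept))
        tech = build_design(c.f2_pheno, None, F2_COVARIATES)
        D = c.cross.f2_dosages

        def calls(y, tech, D):
            res = eqtl.map_cis_eqtls(y, tech, D, c.snp_table, c.gene_table,
                                     n_perm=150, seed=11, conditional=False)
            return set(res[res["is_egene"]]["phenotype_id"])

        perm = np.random.default_rng(1).permutation(D.shape[0])
        base = calls(y, tech, D)
        permuted = calls(y.iloc[:, perm], tech.iloc[perm], D[perm])
        assert base == permuted

    def test_planted_egenes_recovered(self, default_run):
        """At |aFC| >= 1 and fixed-divergent eVariants (F2 MAF 0.5), planted
        eGenes are recalled at >= 0.9."""
        res = default_run
        top = res.eqtl[res.eqtl["rank"] == 0]
        egenes = set(top[top["is_egene"]]["phenotype_id"])
        planted = set(res.cohort.truth_eqtls["gene_id"])
        pleio = set(res.cohort.pleiotropic_genes)
        assert len(egenes & pleio) / len(pleio) >= 0.9
        # tested windows respect the cis contract
        assert (top["maf"] > 0.01).all()
        assert (top["tss_distance"].abs() <= 1_000_000).all()
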