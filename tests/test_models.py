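"""Logistic engine and haplotype association tests: closed-form checks,
agreement with an independent optimizer, separation/collinearity handling,
and the global and SNP-adjusted likelihood-ratio tests."""

import numpy as np
import pytest
from scipy.stats import kstest

import hapscan as hs
from hapscan.em import GenotypeWindow, em_fit
from hapscan.models import (
    CollinearityError,
    design_from_covariates,
    fit_logistic,
    global_haplotype_test,
    haplotype_specific_test,
    snp_adjusted_lr_test,
)


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        fit = fit_logistic(y, np.ones((100, 1)), ["intercept"])
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(100 * np.log(0.5), abs=1e-8)

    def test_two_by_two_closed_form(self):
        """Exposure table (30,20) cases / (15,35) controls gives the
        saturated-model MLE beta = log((30*35)/(20*15)) = log 3.5."""
        y = np.r_[np.ones(50), np.zeros(50)]
        x = np.r_[np.ones(30), np.zeros(20), np.ones(15), np.zeros(35)]
        fit = fit_logistic(y, np.column_stack([np.ones(100), x]))
        assert fit.coefficients[1] == pytest.approx(np.log(3.5), abs=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20), np.zeros(20)]
        fit = fit_logistic(y, np.column_stack([np.ones(40), x]))
        assert not fit.converged

    def test_rank_deficient_design_names_term(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.arange(20.0)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(CollinearityError):
            fit_logistic(y, X, ["intercept", "a", "b"])

    def test_matches_statsmodels_on_random_designs(self, rng):
        """|Δβ| < 1e-5 against an independent optimizer on 20 small designs."""
        import statsmodels.api as sm

        for _ in range(20):
            n = 200
            X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
            beta = rng.normal(scale=0.7, size=4)
            p = 1 / (1 + np.exp(-(X @ beta)))
            y = (rng.random(n) < p).astype(float)
            if y.sum() < 2 or y.sum() > n - 2:
                continue
            ours = fit_logistic(y, X)
            ref = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10)
            np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-5)
            assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)


class TestDesignBuilder:
    def test_categorical_expansion(self, small_covariates):
        X, names = design_from_covariates(small_covariates, len(small_covariates))
        assert names[0] == "intercept"
        assert sum(n.startswith("study_") for n in names) == small_covariates["study"].nunique() - 1
        assert X.shape[0] == len(small_covariates)

    def test_misaligned_table_rejected(self, small_covariates):
        with pytest.raises(ValueError):
            design_from_covariates(small_covariates, 7)


@pytest.fixture(scope="module")
def effect_cohort():
    """Cohort with a planted moderate per-copy effect on a common haplotype."""
    pool = hs.generate_haplotype_pool(5, 8, 1.0, seed=7)
    risk = pool.haplotypes[int(np.argmax(pool.pool_freqs))]
    model = hs.DiseaseModel(risk_haplotype=risk, risk_start=0, beta_h=np.log(1.5))
    cohort = hs.generate_cohort(pool, 1200, 1200, model, seed=19)
    return pool, risk, cohort


def _em_dosage(cohort, haplotype):
    gm = cohort.genotypes
    fit = em_fit(GenotypeWindow(
        gm.calls, alleles=list(zip(gm.snps["allele1"], gm.snps["allele2"]))))
    return fit, fit.dosages[:, fit.haplotypes.index(haplotype)]


class TestHaplotypeSpecific:
    def test_constant_dosage_is_collinear(self, small_covariates, null_cohort):
        with pytest.raises(CollinearityError):
            haplotype_specific_test(np.zeros(500), small_covariates, null_cohort.labels)

    def test_recovers_planted_effect(self, effect_cohort):
        _, risk, cohort = effect_cohort
        _, dosage = _em_dosage(cohort, risk)
        cov = cohort.covariates[["age", "study", "pc1", "pc2"]]
        res = haplotype_specific_test(dosage, cov, cohort.labels)
        assert res.ci_low < 1.5 < res.ci_high
        assert res.p < 0.05

    def test_null_p_uniform_under_label_permutation(self, null_cohort, rng):
        gm = null_cohort.genotypes
        fit = em_fit(GenotypeWindow(gm.calls))
        j = int(np.argmax(fit.freqs))
        dosage = fit.dosages[:, j]
        cov = null_cohort.covariates[["age", "pc1"]]
        y = null_cohort.labels.copy()
        pvals = []
        for _ in range(500):
            yp = y[rng.permutation(len(y))]
            res = haplotype_specific_test(dosage, cov, yp)
            pvals.append(res.p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestGlobalTest:
    def test_k2_reduces_to_one_df_lr(self):
        """With two common haplotypes the global test equals the 1-df LR test
        of the non-reference dosage."""
        pool = hs.generate_haplotype_pool(3, 2, 1.0, seed=23)
        cohort = hs.generate_cohort(pool, 300, 300, hs.DiseaseModel(), seed=24)
        gm = cohort.genotypes
        fit = em_fit(GenotypeWindow(
            gm.calls, alleles=list(zip(gm.snps["allele1"], gm.snps["allele2"]))))
        cov = cohort.covariates[["age"]]
        res = global_haplotype_test(fit, cov, cohort.labels)
        assert res.df == 1
        non_ref = int(np.argmin(fit.freqs))
        single = haplotype_specific_test(fit.dosages[:, non_ref], cov,
                                         cohort.labels, test="lr")
        assert res.statistic == pytest.approx(single.statistic, abs=1e-9)
        assert res.p == pytest.approx(single.p, rel=1e-9)

    def test_df_is_k_minus_one(self, null_cohort):
        fit = em_fit(GenotypeWindow(null_cohort.genotypes.calls))
        k = int((fit.freqs > 0.01).sum())
        res = global_haplotype_test(fit, null_cohort.covariates[["age"]],
                                    null_cohort.labels)
        assert res.df == k - 1

    def test_single_common_haplotype_yields_no_test(self):
        pool = hs.HaplotypePool(
            2, [("A", "G"), ("C", "T")], ["AC", "GT"], np.array([0.995, 0.005]))
        cohort = hs.generate_cohort(pool, 200, 200, hs.DiseaseModel(), seed=31)
        fit = em_fit(GenotypeWindow(cohort.genotypes.calls))
        assert global_haplotype_test(fit, None, cohort.labels) is None


class TestSnpAdjustedLr:
    def test_dosage_identical_to_snp_is_collinear(self, null_cohort):
        g = null_cohort.genotypes.calls[:, 0].astype(float)
        res = snp_adjusted_lr_test(g, [g.copy()], None, null_cohort.labels)
        assert res.collinear
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_empty_adjustment_equals_lr_haplotype_test(self, effect_cohort):
        _, risk, cohort = effect_cohort
        _, dosage = _em_dosage(cohort, risk)
        cov = cohort.covariates[["age", "pc1"]]
        adj = snp_adjusted_lr_test(dosage, [], cov, cohort.labels)
        plain = haplotype_specific_test(dosage, cov, cohort.labels, test="lr")
        assert adj.statistic == pytest.approx(plain.statistic, abs=1e-9)

    def test_null_snp_adjustment_leaves_test_roughly_unchanged(self, effect_cohort, rng):
        """Conditioning on an independent null SNP barely moves the statistic."""
        _, risk, cohort = effect_cohort
        _, dosage = _em_dosage(cohort, risk)
        cov = cohort.covariates[["age", "pc1"]]
        noise_snp = rng.binomial(2, 0.3, size=len(dosage)).astype(float)
        adj = snp_adjusted_lr_test(dosage, [noise_snp], cov, cohort.labels)
        plain = haplotype_specific_test(dosage, cov, cohort.labels, test="lr")
        assert adj.statistic == pytest.approx(plain.statistic, rel=0.2)

    def test_lr_statistic_nonnegative_and_affine_invariant(self, effect_cohort):
        _, risk, cohort = effect_cohort
        _, dosage = _em_dosage(cohort, risk)
        cov1 = cohort.covariates[["age", "pc1"]]
        cov2 = cov1.assign(age=cov1["age"] * 10 - 400)
        g = cohort.genotypes.calls[:, 2].astype(float)
        r1 = snp_adjusted_lr_test(dosage, [g], cov1, cohort.labels)
        r2 = snp_adjusted_lr_test(dosage, [g], cov2, cohort.labels)
        assert r1.statistic >= 0.0
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-6)


def test_wald_and_lr_agree_under_moderate_effects(effect_cohort):
    """1-df Wald and LR p-values agree within 20% relative error at n >= 2000."""
    _, risk, cohort = effect_cohort
    _, dosage = _em_dosage(cohort, risk)
    cov = cohort.covariates[["age", "pc1"]]
    wald = haplotype_specific_test(dosage, cov, cohort.labels, test="wald")
    lr = haplotype_specific_test(dosage, cov, cohort.labels, test="lr")
    assert np.log(wald.p) == pytest.approx(np.log(lr.p), rel=0.2)
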