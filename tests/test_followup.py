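"""Region extension arithmetic, exhaustive variable-length search,
SNP-adjusted verification and local-ancestry adjustment."""

import numpy as np
import pytest

import hapscan as hs
from hapscan.followup import (
    Region,
    candidate_runs,
    exhaustive_haplotype_search,
    extend_region,
    known_region_scan,
    local_ancestry_covariate,
    merge_overlapping_regions,
    verify_top_hit,
)
from hapscan.simulate import LocalAncestryTrack


class TestExtendRegion:
    def test_half_width_extension_doubles_the_region(self):
        r = extend_region(Region("1", 8_309_317, 8_318_147))
        assert (r.bp_start, r.bp_end) == (8_304_902, 8_322_562)

    def test_zero_factor_is_identity(self):
        r = Region("4", 100, 200)
        assert extend_region(r, factor=0.0) == r

    def test_start_clamped_at_one(self):
        r = extend_region(Region("2", 100, 1100))
        assert r.bp_start == 1
        assert r.bp_end == 1600

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            Region("1", 10, 5)


class TestCandidateRuns:
    @pytest.mark.parametrize("R,len_max,expected", [
        (5, 10, 10),     # 4 + 3 + 2 + 1
        (12, 10, 63),    # sum_{L=2..10} (13 - L)
        (2, 10, 1),
    ])
    def test_run_counts(self, R, len_max, expected):
        assert len(candidate_runs(R, 2, len_max)) == expected

    def test_runs_are_contiguous_and_bounded(self):
        for s, L in candidate_runs(8, 2, 10):
            assert 2 <= L <= 8 and 0 <= s and s + L <= 8


@pytest.fixture(scope="module")
def region_cohort():
    """12-SNP region with a planted 4-SNP haplotype effect on SNPs 4-7."""
    pools = [hs.generate_haplotype_pool(4, 5, 1.0, seed=600 + b) for b in range(3)]
    rp = pools[1]
    risk = rp.haplotypes[int(np.argmin(np.abs(rp.pool_freqs - 0.3)))]
    model = hs.DiseaseModel(risk_haplotype=risk, risk_start=4, beta_h=np.log(1.8))
    cohort = hs.generate_cohort(pools, 900, 900, model, seed=601)
    region = Region("1", int(cohort.genotypes.snps["pos"].min()),
                    int(cohort.genotypes.snps["pos"].max()))
    return cohort, region, risk


class TestExhaustiveSearch:
    def test_ranking_is_total_and_deterministic(self, region_cohort):
        cohort, region, _ = region_cohort
        cov = cohort.covariates[["age", "pc1"]]
        h1 = exhaustive_haplotype_search(cohort.genotypes, region, cov,
                                         cohort.labels, len_max=5)
        h2 = exhaustive_haplotype_search(cohort.genotypes, region, cov,
                                         cohort.labels, len_max=5)
        key = [(h.snp_ids, h.allele_string) for h in h1]
        assert key == [(h.snp_ids, h.allele_string) for h in h2]
        ps = [h.unadjusted.p for h in h1]
        assert ps == sorted(ps)

    def test_top_hit_overlaps_the_planted_run(self, region_cohort):
        cohort, region, _ = region_cohort
        cov = cohort.covariates[["age", "pc1"]]
        hits = exhaustive_haplotype_search(cohort.genotypes, region, cov,
                                           cohort.labels, len_max=6)
        top = hits[0]
        planted = set(cohort.genotypes.snps["snp_id"].iloc[4:8])
        assert planted & set(top.snp_ids)

    def test_all_hits_are_common_and_within_length_bounds(self, region_cohort):
        cohort, region, _ = region_cohort
        hits = exhaustive_haplotype_search(
            cohort.genotypes, region, cohort.covariates[["age"]],
            cohort.labels, len_max=5)
        for h in hits:
            assert 2 <= h.length <= 5
            assert h.frequency > 0.01

    def test_window_scan_haplotypes_are_a_subset_of_candidates(self, region_cohort):
        """Every 5-SNP-window haplotype reappears among the exhaustive
        search's length-5 candidates on the same region."""
        from hapscan.em import GenotypeWindow, em_fit

        cohort, region, _ = region_cohort
        gm = cohort.genotypes
        hits = exhaustive_haplotype_search(gm, region, cohort.covariates[["age"]],
                                           cohort.labels, len_max=5,
                                           freq_threshold=0.01)
        candidates = {(h.snp_ids, h.allele_string) for h in hits}
        alleles = list(zip(gm.snps["allele1"], gm.snps["allele2"]))
        for s in range(gm.n_snps - 4):
            fit = em_fit(GenotypeWindow(gm.calls[:, s:s + 5], alleles=alleles[s:s + 5]))
            ids = tuple(gm.snps["snp_id"].iloc[s:s + 5])
            for hap, f in zip(fit.haplotypes, fit.freqs):
                if f > 0.01:
                    assert (ids, hap) in candidates

    def test_too_small_region_rejected(self, region_cohort):
        cohort, _, _ = region_cohort
        with pytest.raises(ValueError):
            exhaustive_haplotype_search(cohort.genotypes, Region("1", 1, 2),
                                        None, cohort.labels)


class TestVerifyTopHit:
    def test_two_snp_haplotype_collinear_with_its_snp(self):
        """With only two complementary haplotypes, the haplotype dosage equals
        a constituent SNP genotype and the adjusted test degenerates."""
        pool = hs.HaplotypePool(2, [("A", "G"), ("C", "T")], ["AC", "GT"],
                                np.array([0.6, 0.4]))
        cohort = hs.generate_cohort(pool, 400, 400, hs.DiseaseModel(), seed=71)
        gm = cohort.genotypes
        region = Region("1", int(gm.snps["pos"].min()), int(gm.snps["pos"].max()))
        cov = cohort.covariates[["age"]]
        hits = exhaustive_haplotype_search(gm, region, cov, cohort.labels)
        top = verify_top_hit(hits[0], gm, cov, cohort.labels)
        assert top.adjusted.collinear
        assert top.adjusted.statistic == 0.0

    def test_planted_effect_survives_best_snp_adjustment(self, region_cohort):
        cohort, region, _ = region_cohort
        gm = cohort.genotypes
        cov = cohort.covariates[["age", "pc1"]]
        hits = exhaustive_haplotype_search(gm, region, cov, cohort.labels, len_max=6)
        top = verify_top_hit(hits[0], gm, cov, cohort.labels)
        assert top.best_snp in top.snp_ids
        assert top.adjusted.p < 0.01
        assert not top.adjusted.collinear

    def test_independent_null_index_snp_changes_little(self, region_cohort):
        cohort, region, _ = region_cohort
        gm = cohort.genotypes
        cov = cohort.covariates[["age", "pc1"]]
        hits = exhaustive_haplotype_search(gm, region, cov, cohort.labels, len_max=6)
        # SNP in a different, effect-free block
        null_snp = gm.snps["snp_id"].iloc[0]
        plain = verify_top_hit(hits[0], gm, cov, cohort.labels)
        extra = verify_top_hit(hits[0], gm, cov, cohort.labels, index_snps=[null_snp])
        assert extra.adjusted.statistic == pytest.approx(plain.adjusted.statistic, rel=0.25)
        assert null_snp in extra.adjusting_snps


class TestLocalAncestry:
    def _track(self, post, snp_ids):
        n = post.shape[0]
        return LocalAncestryTrack([f"S{i}" for i in range(n)], snp_ids, post)

    def test_symmetric_posteriors_give_dosage_one(self):
        post = np.tile([0.25, 0.5, 0.25], (4, 3, 1))
        cov = local_ancestry_covariate(self._track(post, ["a", "b", "c"]), ["a", "b"])
        np.testing.assert_allclose(cov, 1.0)

    def test_certain_zero_copies_gives_zero(self):
        post = np.tile([1.0, 0.0, 0.0], (4, 2, 1))
        cov = local_ancestry_covariate(self._track(post, ["a", "b"]), ["a", "b"])
        np.testing.assert_allclose(cov, 0.0)

    def test_mean_over_constituent_snps(self):
        post = np.zeros((1, 3, 3))
        post[0, 0] = [1, 0, 0]     # dosage 0
        post[0, 1] = [0, 1, 0]     # dosage 1
        post[0, 2] = [0, 0, 1]     # dosage 2
        cov = local_ancestry_covariate(self._track(post, ["a", "b", "c"]),
                                       ["a", "b", "c"])
        assert cov[0] == pytest.approx(1.0)

    def test_missing_snp_raises_lookup_error(self):
        post = np.tile([1.0, 0.0, 0.0], (2, 2, 1))
        with pytest.raises(KeyError):
            local_ancestry_covariate(self._track(post, ["a", "b"]), ["z"])

    def test_independent_track_barely_moves_the_adjusted_test(self, region_cohort, rng):
        cohort, region, _ = region_cohort
        gm = cohort.genotypes
        cov = cohort.covariates[["age", "pc1"]]
        hits = exhaustive_haplotype_search(gm, region, cov, cohort.labels, len_max=6)
        post = rng.dirichlet([5, 5, 5], size=(gm.n_samples, gm.n_snps))
        track = LocalAncestryTrack(list(gm.samples["sample_id"]),
                                   list(gm.snps["snp_id"]), post)
        plain = verify_top_hit(hits[0], gm, cov, cohort.labels)
        with_la = verify_top_hit(hits[0], gm, cov, cohort.labels, la_track=track)
        assert with_la.local_ancestry_adjusted is not None
        assert np.log10(with_la.local_ancestry_adjusted.p) == pytest.approx(
            np.log10(plain.adjusted.p), abs=1.0)


class TestKnownRegionScan:
    def test_flank_and_wide_flank_bound_the_hits(self, region_cohort):
        cohort, _, _ = region_cohort
        gm = cohort.genotypes
        cov = cohort.covariates[["age"]]
        mid = int(gm.snps["pos"].iloc[6])
        anchor = gm.snps["snp_id"].iloc[6]
        out = known_region_scan(gm, [(anchor, "1", mid)], cov, cohort.labels,
                                flank=5000, len_max=4)
        assert anchor in out
        for h in out[anchor]:
            for sid in h.snp_ids:
                pos = int(gm.snps.loc[gm.snps["snp_id"] == sid, "pos"].iloc[0])
                assert mid - 5000 <= pos <= mid + 5000
        wide = known_region_scan(gm, [(anchor, "1", mid)], cov, cohort.labels,
                                 flank=5000, wide_flank_regions={anchor: 50_000},
                                 len_max=4)
        assert len(wide[anchor]) >= len(out[anchor])

    def test_verified_hit_adjusts_for_the_index_snp(self, region_cohort):
        cohort, _, _ = region_cohort
        gm = cohort.genotypes
        cov = cohort.covariates[["age"]]
        anchor = gm.snps["snp_id"].iloc[5]
        bp = int(gm.snps["pos"].iloc[5])
        out = known_region_scan(gm, [(anchor, "1", bp)], cov, cohort.labels,
                                flank=50_000, len_max=4)
        top = out[anchor][0]
        assert top.adjusted is not None
        assert anchor in top.adjusting_snps or top.best_snp == anchor

    def test_unpositioned_missing_index_snp_skipped(self, region_cohort):
        cohort, _, _ = region_cohort
        out = known_region_scan(cohort.genotypes, [("rsNOPE", None, None)],
                                cohort.covariates[["age"]], cohort.labels)
        assert out == {}


def test_merge_overlapping_regions():
    merged = merge_overlapping_regions([
        Region("1", 10, 100), Region("1", 50, 150), Region("1", 400, 500),
        Region("2", 10, 20),
    ])
    assert Region("1", 10, 150) in merged
    assert Region("1", 400, 500) in merged
    assert Region("2", 10, 20) in merged
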