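"""Permutation-null enrichment: analytic expectation, shuffles, p-values."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_domainset, mask_overlap_bp, random_intervals
from perimir.enrichment import (
    EnrichmentResult,
    ShuffleConfig,
    expected_overlap,
    observed_overlap,
    permutation_test,
    shuffle_features,
)
from perimir.intervals import DomainSet, GenomeAssembly, GenomicInterval, overlap_bp
from perimir.simulate import place_features_uniform


class TestExpectedOverlap:
    def test_bp_mode_product_of_coverages(self):
        asm = GenomeAssembly({"chr1": 1000})
        feats = [GenomicInterval("chr1", 0, 100)]
        dom = make_domainset("d", [("chr1", 500, 750)], asm)
        assert expected_overlap(feats, dom, mode="bp") == pytest.approx(25.0)

    def test_feature_count_mode_scales_by_coverage(self):
        asm = GenomeAssembly({"chr1": 1000})
        feats = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(4)]
        dom = make_domainset("d", [("chr1", 0, 250)], asm)
        assert expected_overlap(feats, dom, mode="feature_count") == pytest.approx(1.0)

    def test_unknown_mode_rejected(self):
        asm = GenomeAssembly({"chr1": 1000})
        dom = make_domainset("d", [("chr1", 0, 100)], asm)
        with pytest.raises(ValueError):
            expected_overlap([], dom, mode="bases")

    def test_mean_shuffled_overlap_matches_expectation(self, toy_assembly):
        # Monte-Carlo oracle: mean observed bp overlap over uniform shuffles
        # should sit within 3 SE of the analytic expectation.
        # features small vs chromosomes and mutually disjoint, so the
        # product-of-coverages expectation applies without edge effects
        rng = np.random.default_rng(11)
        feats = [GenomicInterval("chr1", 400 * i, 400 * i + 10) for i in range(20)]
        dom = DomainSet.from_intervals(
            "d", random_intervals(rng, 10, toy_assembly, max_len=800), toy_assembly
        )
        n_mc = 3000
        vals = np.empty(n_mc)
        for i in range(n_mc):
            shuffled = shuffle_features(feats, ShuffleConfig(seed=i), toy_assembly)
            vals[i] = overlap_bp(shuffled, dom)
        exp = expected_overlap(feats, dom, mode="bp")
        se = vals.std(ddof=1) / np.sqrt(n_mc)
        assert abs(vals.mean() - exp) < 3 * se + 1e-9


class TestShuffle:
    def test_length_multiset_and_count_preserved(self, toy_assembly):
        feats = [
            GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 0, 200), GenomicInterval("chr2", 0, 300),
            GenomicInterval("chr2", 0, 1000),
        ]
        out = shuffle_features(feats, ShuffleConfig(seed=5), toy_assembly)
        assert sorted(len(f) for f in out) == [100, 100, 200, 300, 1000]
        for f in out:
            toy_assembly.validate(f)

    def test_same_seed_reproduces(self, toy_assembly):
        feats = [GenomicInterval("chr1", 0, 50)] * 5
        a = shuffle_features(feats, ShuffleConfig(seed=9), toy_assembly)
        b = shuffle_features(feats, ShuffleConfig(seed=9), toy_assembly)
        assert a == b

    def test_placement_frequencies_proportional_to_chrom_length(self, toy_assembly):
        # exact binomial oracle for a 1 bp feature on a 2-chromosome genome
        feat = [GenomicInterval("chr1", 0, 1)]
        n = 10_000
        hits = sum(
            shuffle_features(feat, ShuffleConfig(seed=s), toy_assembly)[0].chrom == "chr1"
            for s in range(n)
        )
        p = 10_000 / 16_000  # chr1 share of valid positions
        assert stats.binomtest(hits, n, p).pvalue > 1e-4

    def test_oversized_feature_rejected(self, toy_assembly):
        with pytest.raises(ValueError):
            shuffle_features(
                [GenomicInterval("chr1", 0, 50_000)], ShuffleConfig(seed=0), toy_assembly
            )

    def test_disallowed_internal_overlap_is_respected(self, toy_assembly):
        feats = [GenomicInterval("chr1", 0, 2000)] * 6
        cfg = ShuffleConfig(seed=3, allow_overlap_between_shuffled=False)
        out = shuffle_features(feats, cfg, toy_assembly)
        merged_bp = sum(len(f) for f in out)
        from perimir.intervals import union_bp

        assert union_bp(out) == merged_bp

    def test_per_chromosome_shuffle_keeps_chromosome(self, toy_assembly):
        feats = [GenomicInterval("chr2", 0, 100)] * 10
        cfg = ShuffleConfig(seed=1, per_chromosome=True)
        out = shuffle_features(feats, cfg, toy_assembly)
        assert all(f.chrom == "chr2" for f in out)


class TestPermutationTest:
    def test_fully_planted_enrichment_ratio(self, toy_assembly):
        dom = make_domainset("d", [("chr1", 0, 4000)], toy_assembly)  # 25% of 16 kb
        feats = [GenomicInterval("chr1", 100 * i, 100 * i + 10) for i in range(10)]
        res = permutation_test(
            feats, dom, mode="feature_count", config=ShuffleConfig(n_perm=50, seed=2)
        )
        assert res.enrichment == pytest.approx(4.0)
        assert res.observed == 10

    def test_degenerate_null_counts_ties_in_both_tails(self, toy_assembly):
        # domain set = whole genome: every permutation ties with observed
        dom = make_domainset("d", [("chr1", 0, 10_000), ("chr2", 0, 6_000)], toy_assembly)
        feats = [GenomicInterval("chr1", 0, 10)] * 4
        res = permutation_test(
            feats, dom, mode="feature_count", config=ShuffleConfig(n_perm=20, seed=0)
        )
        assert res.p_enriched == 1.0 and res.p_depleted == 1.0
        assert res.enrichment == pytest.approx(1.0)

    def test_zero_tail_count_reports_bound(self, toy_assembly):
        # all features planted in a tiny domain: no shuffle can reach it
        dom = make_domainset("d", [("chr1", 0, 20)], toy_assembly)
        feats = [GenomicInterval("chr1", 0, 10)] * 12
        res = permutation_test(
            feats, dom, mode="feature_count", config=ShuffleConfig(n_perm=10, seed=1)
        )
        assert res.p_report == "<0.1"
        assert res.p_enriched == pytest.approx(0.1)

    def test_tails_sum_to_at_least_one(self, toy_assembly):
        rng = np.random.default_rng(0)
        dom = DomainSet.from_intervals(
            "d", random_intervals(rng, 8, toy_assembly, max_len=1000), toy_assembly
        )
        for seed in range(5):
            feats = random_intervals(rng, 30, toy_assembly, max_len=60)
            res = permutation_test(
                feats, dom, mode="feature_count", config=ShuffleConfig(n_perm=40, seed=seed)
            )
            assert res.p_enriched + res.p_depleted >= 1.0

    def test_identical_seed_gives_identical_result(self, toy_assembly):
        rng = np.random.default_rng(3)
        dom = DomainSet.from_intervals(
            "d", random_intervals(rng, 6, toy_assembly, max_len=900), toy_assembly
        )
        feats = random_intervals(rng, 25, toy_assembly, max_len=60)
        r1 = permutation_test(feats, dom, "bp", ShuffleConfig(n_perm=100, seed=42))
        r2 = permutation_test(feats, dom, "bp", ShuffleConfig(n_perm=100, seed=42))
        assert r1 == r2

    def test_bp_mode_observed_matches_per_bp_oracle(self, toy_assembly):
        rng = np.random.default_rng(8)
        dom = DomainSet.from_intervals(
            "d", random_intervals(rng, 10, toy_assembly, max_len=700), toy_assembly
        )
        feats = random_intervals(rng, 40, toy_assembly, max_len=80)
        res = permutation_test(feats, dom, "bp", ShuffleConfig(n_perm=5, seed=0))
        assert res.observed == mask_overlap_bp(feats, dom.intervals, toy_assembly)

    def test_planted_enrichment_recovered(self):
        # q/c ratio recovery within 10% at n = 500 (q < c: avoidance regime)
        from perimir.simulate import FeaturePlacementSpec, GenomeSpec, generate_genome, place_features

        asm, clad, cilad = generate_genome(GenomeSpec(), seed=21)
        q, c = 0.14, clad.coverage_fraction
        feats, truth = place_features(
            FeaturePlacementSpec(n_features=500, inside_probability=q), clad, cilad, seed=22
        )
        # the planted fraction itself is binomial around q
        assert stats.binomtest(int(truth.sum()), 500, q).pvalue > 1e-4
        res = permutation_test(
            feats, clad, mode="feature_count", config=ShuffleConfig(n_perm=200, seed=23)
        )
        # analysis recovers the realized planted ratio within 10%
        assert res.enrichment == pytest.approx(truth.mean() / c, rel=0.10)
        assert res.p_depleted <= 0.05

    def test_null_p_values_roughly_uniform(self, toy_assembly):
        # reduced-size calibration; the full 500-replicate version runs in
        # the acceptance suite
        dom = make_domainset("d", [("chr1", 2_000, 8_000)], toy_assembly)
        pvals = []
        for rep in range(60):
            feats = place_features_uniform(40, 20, toy_assembly, seed=1000 + rep)
            res = permutation_test(
                feats, dom, mode="feature_count",
                config=ShuffleConfig(n_perm=60, seed=rep),
            )
            pvals.append(res.p_enriched)
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.25
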