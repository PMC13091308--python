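"""LD scores, annotation BEDs, heritability regression, enrichment, rg."""

import numpy as np
import pandas as pd
import pytest

from crossgwas.ldsc import (
    compute_ld_scores,
    estimate_h2,
    fallback_enrichment,
    genetic_correlation,
    make_annotation_bed,
    partitioned_h2,
    snps_in_bed,
)
from crossgwas.simulate import (
    AnnotationSpec,
    LdBlocks,
    SimulationConfig,
    default_blocks,
    simulate_study,
)


class TestLdScores:
    def test_independent_snps_score_one(self):
        ld = LdBlocks([(1, 0.0)] * 10)
        assert np.allclose(ld.ld_scores(), 1.0)

    def test_near_perfect_pair_scores_two(self):
        ld = LdBlocks([(2, 0.999999)])
        assert np.allclose(ld.ld_scores(), 2.0, atol=1e-4)

    def test_ar1_center_closed_form(self):
        ld = LdBlocks([(5, 0.5)])
        # center SNP: 1 + 2*rho^2 + 2*rho^4
        assert ld.ld_scores()[2] == pytest.approx(1 + 2 * 0.25 + 2 * 0.0625)

    def test_annotation_partition_conserves_total(self, rng):
        ld = LdBlocks(default_blocks(1_000))
        mask = rng.random(1_000) < 0.3
        scores = compute_ld_scores(ld, {"in": mask, "out": ~mask})
        total = scores["l2_in"] + scores["l2_out"]
        assert np.allclose(total, scores["l2"])

    def test_block_permutation_invariance(self, rng):
        ld = LdBlocks([(20, 0.6)])
        l2 = ld.ld_scores()
        # AR(1) is symmetric under index reversal
        assert np.allclose(l2, l2[::-1])


class TestAnnotationBed:
    def genes(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        )

    def test_coordinate_conversion(self):
        bed = make_annotation_bed(
            self.genes([("g", "chr1", 50_000, 60_000, "+")]), pad=10_000
        )
        assert bed.iloc[0].tolist() == ["chr1", 39_999, 70_000]

    def test_overlapping_and_abutting_merge(self):
        bed = make_annotation_bed(
            self.genes([
                ("a", "1", 10_000, 20_000, "+"),
                ("b", "1", 35_000, 45_000, "+"),  # padded intervals abut
                ("c", "1", 200_000, 210_000, "+"),
            ]),
            pad=10_000,
        )
        assert len(bed) == 2
        assert bed.iloc[0]["end"] == 55_000

    def test_matches_per_base_union_oracle(self, rng):
        starts = np.sort(rng.integers(1, 400_000, 100))
        genes = self.genes([
            (f"g{i}", "1", int(s), int(s + rng.integers(500, 20_000)), "+")
            for i, s in enumerate(starts)
        ])
        pad = 10_000
        bed = make_annotation_bed(genes, pad)
        covered = np.zeros(500_000, dtype=bool)  # index = 1-based position
        for row in genes.itertuples(index=False):
            covered[max(1, row.start - pad): row.end + pad + 1] = True
        bed_total = int((bed["end"] - bed["start"]).sum())
        assert bed_total == int(covered.sum())

    def test_snps_in_bed_boundaries(self):
        bed = pd.DataFrame([("1", 99, 200)], columns=["chrom", "start", "end"])
        variants = pd.DataFrame({"chrom": "1", "pos": [99, 100, 200, 201]})
        mask = snps_in_bed(variants, bed)
        assert mask.tolist() == [False, True, True, False]


class TestEstimateH2:
    def test_noise_free_line_recovered_exactly(self):
        ld = LdBlocks(default_blocks(4_000))
        l2 = ld.ld_scores()
        n, m, h2 = 10_000, 4_000, 0.3
        chi2 = 1.0 + n * h2 * l2 / m
        res = estimate_h2(chi2, l2, n, m)
        assert res.h2 == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)
        assert res.h2_se == pytest.approx(0.0, abs=1e-10)

    def test_constant_ld_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_h2(np.ones(5_000), np.ones(5_000), 1_000)

    def test_recovers_simulated_h2(self):
        ests = []
        for seed in range(5):
            st = simulate_study(SimulationConfig(seed=seed, h2=(0.3, 0.3)))
            ests.append(
                estimate_h2(
                    st.studies["trait_a"]["chi2"].to_numpy(),
                    st.ld.ld_scores(), 50_000,
                ).h2
            )
        assert 0.25 <= np.mean(ests) <= 0.35


class TestPartitionedH2:
    def test_uniform_noise_free_enrichment_one(self):
        ld = LdBlocks(default_blocks(2_000))
        mask = np.zeros(2_000, dtype=bool)
        mask[:400] = True
        scores = compute_ld_scores(ld, {"a": mask})
        n, m, h2 = 10_000, 2_000, 0.3
        chi2 = 1.0 + n * h2 * scores["l2"].to_numpy() / m
        res = partitioned_h2(chi2, scores, {"a": mask}, n)
        assert res["enrichment"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_all_snps_annotation_exact(self):
        ld = LdBlocks(default_blocks(1_000))
        mask = np.ones(1_000, dtype=bool)
        scores = compute_ld_scores(ld, {"all": mask})
        chi2 = 1.0 + 2.0 * scores["l2"].to_numpy()
        res = partitioned_h2(chi2, scores, {"all": mask}, 1_000)
        row = res.iloc[0]
        assert row["prop_h2"] == 1.0 and row["enrichment"] == 1.0

    def test_collinear_annotations_named(self):
        ld = LdBlocks(default_blocks(1_000))
        mask = np.zeros(1_000, dtype=bool)
        mask[:100] = True
        scores = compute_ld_scores(ld, {"a": mask, "b": mask})
        with pytest.raises(ValueError, match="collinear"):
            partitioned_h2(np.ones(1_000), scores, {"a": mask, "b": mask}, 100)

    def test_partition_proportions_sum_to_one(self):
        ld = LdBlocks(default_blocks(2_000))
        m1 = np.zeros(2_000, dtype=bool)
        m1[:700] = True
        scores = compute_ld_scores(ld, {"a": m1, "b": ~m1})
        n, h2 = 10_000, 0.3
        chi2 = 1.0 + n * h2 * scores["l2"].to_numpy() / 2_000
        res = partitioned_h2(chi2, scores, {"a": m1, "b": ~m1}, n)
        assert res["prop_h2"].sum() == pytest.approx(1.0, abs=1e-6)


class TestFallbackEnrichment:
    def test_arithmetic_example(self):
        chi2 = np.array([1.6] * 50 + [1.3] * 50)
        mask = np.array([True] * 50 + [False] * 50)
        l2 = np.full(100, 2.0)
        res = fallback_enrichment(chi2, mask, l2)
        assert res["ratio"] == pytest.approx(2.0)

    def test_no_enrichment_on_noise_free_line(self):
        ld = LdBlocks(default_blocks(2_000))
        l2 = ld.ld_scores()
        chi2 = 1.0 + 1.5 * l2
        mask = np.zeros(2_000, dtype=bool)
        mask[:300] = True
        res = fallback_enrichment(chi2, mask, l2)
        assert res["ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            fallback_enrichment(np.ones(10), np.ones(10, dtype=bool),
                                np.ones(10))

    def test_negative_excess_floored(self):
        chi2 = np.array([0.5] * 10 + [1.5] * 10)
        mask = np.array([True] * 10 + [False] * 10)
        res = fallback_enrichment(chi2, mask, np.ones(20))
        assert res["floored"] and res["ratio"] > 0


class TestGeneticCorrelation:
    def test_self_correlation_is_one(self):
        st = simulate_study(SimulationConfig(seed=8, h2=(0.3, 0.3)))
        z = st.studies["trait_a"]["z"].to_numpy()
        res = genetic_correlation(z, z, st.ld.ld_scores(), 50_000, 50_000)
        assert res.rg == pytest.approx(1.0, abs=0.05)

    def test_symmetric_in_trait_order(self):
        st = simulate_study(SimulationConfig(seed=9, rg_true=0.4))
        za = st.studies["trait_a"]["z"].to_numpy()
        zb = st.studies["trait_b"]["z"].to_numpy()
        l2 = st.ld.ld_scores()
        ab = genetic_correlation(za, zb, l2, 50_000, 50_000)
        ba = genetic_correlation(zb, za, l2, 50_000, 50_000)
        assert ab.rg == pytest.approx(ba.rg)
        assert ab.se == pytest.approx(ba.se)

    def test_allele_flipped_copy_recovers_self_rg(self, small_scene):
        """End-to-end: harmonizing an allele-flipped copy of a study with
        itself yields the same rg as the study with itself."""
        from crossgwas.simulate import inject_allele_corruption
        from crossgwas.sumstats import harmonize_pair

        a = small_scene.studies["trait_a"]
        rng = np.random.default_rng(4)
        flipped, _ = inject_allele_corruption(a, rng, swap_frac=0.3,
                                              palindromic_frac=0.0)
        pair = harmonize_pair(a, flipped)
        assert len(pair.table) == len(a)
        l2 = small_scene.ld.ld_scores()
        idx = a.reset_index().merge(pair.table[["rsid"]], on="rsid")["index"]
        res = genetic_correlation(
            pair.table["z_a"].to_numpy(), pair.table["z_b"].to_numpy(),
            l2[idx.to_numpy()], 50_000, 50_000, m=len(a), n_blocks=40,
        )
        assert res.rg == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_h2_rejected(self):
        ld = LdBlocks(default_blocks(4_000))
        l2 = ld.ld_scores()
        # chi2 decreasing in the LD score forces a negative h2 slope
        z = np.sqrt(1.5 - 0.2 * l2)
        with pytest.raises(ValueError, match="heritability"):
            genetic_correlation(z, z, l2, 50_000, 50_000)

    def test_intercept_near_one_null(self):
        st = simulate_study(SimulationConfig(seed=12, rg_true=0.0))
        res = genetic_correlation(
            st.studies["trait_a"]["z"].to_numpy(),
            st.studies["trait_b"]["z"].to_numpy(),
            st.ld.ld_scores(), 50_000, 50_000,
        )
        # cross-intercept noise is ~0.03 SD at this scene size
        assert abs(res.cross_intercept) < 0.1
        assert res.intercept_a == pytest.approx(1.0, abs=0.1)
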