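"""Summary-statistics I/O, validation, and two-study harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossgwas.simulate import inject_allele_corruption
from crossgwas.sumstats import (
    MIN_PVALUE,
    TraitMeta,
    effective_sample_size,
    harmonize_pair,
    pair_to_tables,
    read_gwas_vcf,
    read_pgc_tsv,
    read_sumstats,
    validate_variants,
    write_gwas_vcf,
    write_pgc_tsv,
)

CORE = ["chrom", "pos", "rsid", "effect_allele", "other_allele",
        "beta", "se", "pvalue", "n"]


def make_variants(rows):
    df = pd.DataFrame(rows, columns=CORE)
    return df


class TestEffectiveSampleSize:
    @pytest.mark.parametrize(
        "nca,nco,expected",
        [(27_205, 110_881, 87_381), (500, 500, 1_000), (100, 300, 300)],
    )
    def test_known_values(self, nca, nco, expected):
        assert effective_sample_size(nca, nco) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            effective_sample_size(0, 100)

    def test_trait_meta_consistency_enforced(self):
        with pytest.raises(ValueError):
            TraitMeta("x", n_effective=50_000, n_cases=27_205, n_controls=110_881)


class TestValidation:
    def test_z_derivation_and_se_exclusion(self):
        df = make_variants([
            ("1", 100, "rs1", "A", "G", 0.1, 0.05, 0.045, 1000.0),
            ("1", 200, "rs2", "A", "G", 0.1, 0.0, 0.5, 1000.0),
        ])
        from collections import Counter

        ledger = Counter()
        out = validate_variants(df, ledger)
        assert len(out) == 1
        assert out["z"].iloc[0] == pytest.approx(2.0)
        assert out["chi2"].iloc[0] == pytest.approx(4.0)
        assert ledger["nonpositive_se"] == 1

    def test_pvalue_zero_floored_not_dropped(self):
        df = make_variants([("1", 100, "rs1", "A", "G", 0.1, 0.05, 0.0, 1000.0)])
        out = validate_variants(df)
        assert out["pvalue"].iloc[0] == MIN_PVALUE
        assert bool(out["pvalue_floored"].iloc[0])

    def test_identical_alleles_dropped(self):
        df = make_variants([("1", 100, "rs1", "A", "A", 0.1, 0.05, 0.5, 1000.0)])
        assert len(validate_variants(df)) == 0


class TestDialectRoundTrips:
    def test_tsv_round_trip_bit_exact(self, small_scene, tmp_path):
        a = small_scene.studies["trait_a"]
        path = tmp_path / "a.tsv"
        write_pgc_tsv(a, path, small_scene.metas["trait_a"])
        back, meta, ledger = read_pgc_tsv(path)
        for col in CORE:
            assert (a[col].to_numpy() == back[col].to_numpy()).all(), col
        assert sum(ledger.values()) == 0

    def test_vcf_round_trip_bit_exact(self, small_scene, tmp_path):
        a = small_scene.studies["trait_a"]
        path = tmp_path / "a.vcf"
        write_gwas_vcf(a, path, small_scene.metas["trait_a"])
        back, meta, _ = read_gwas_vcf(path)
        for col in ["chrom", "pos", "effect_allele", "other_allele", "beta", "se", "n"]:
            assert (a[col].to_numpy() == back[col].to_numpy()).all(), col
        # p is stored as -log10 and regenerated; equal to double rounding
        assert np.allclose(a["pvalue"], back["pvalue"], rtol=1e-12)
        assert meta.n_effective == small_scene.metas["trait_a"].n_effective

    def test_cross_dialect_equality(self, small_scene, tmp_path):
        """The same study written in both dialects parses to the same z."""
        a = small_scene.studies["trait_a"]
        write_pgc_tsv(a, tmp_path / "a.tsv", small_scene.metas["trait_a"])
        write_gwas_vcf(a, tmp_path / "a.vcf", small_scene.metas["trait_a"])
        t, _, _ = read_sumstats(tmp_path / "a.tsv")
        v, _, _ = read_sumstats(tmp_path / "a.vcf")
        assert (t["z"].to_numpy() == v["z"].to_numpy()).all()
        assert (t["beta"].to_numpy() == v["beta"].to_numpy()).all()

    def test_emitted_vcf_is_valid_per_pysam(self, small_scene, tmp_path):
        pysam = pytest.importorskip("pysam")
        a = small_scene.studies["trait_a"].head(50)
        path = tmp_path / "a.vcf"
        write_gwas_vcf(a, path, small_scene.metas["trait_a"])
        recs = list(pysam.VariantFile(str(path)))
        assert len(recs) == 50
        first = recs[0]
        assert first.alts[0] == a["effect_allele"].iloc[0]
        assert first.ref == a["other_allele"].iloc[0]
        # htslib floats are 32-bit: agreement to float32 precision
        assert float(first.samples[0]["ES"][0]) == pytest.approx(
            a["beta"].iloc[0], rel=1e-6
        )

    def test_vcf_lp_to_pvalue(self, tmp_path):
        df = make_variants([("1", 100, "rs1", "G", "A", -0.2, 0.1, 0.001, 500.0)])
        df = validate_variants(df)
        path = tmp_path / "x.vcf"
        write_gwas_vcf(df, path, TraitMeta("x", 500.0))
        with open(path) as fh:
            line = [l for l in fh if l.startswith("1\t")][0]
        assert line.split("\t")[9].split(":")[2].startswith("3.0")
        back, _, _ = read_gwas_vcf(path)
        assert back["pvalue"].iloc[0] == pytest.approx(0.001)
        assert back["z"].iloc[0] == pytest.approx(-2.0)
        assert back["chi2"].iloc[0] == pytest.approx(4.0)

    def test_multiallelic_skipped(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=ES,Number=A,Type=Float,Description="es">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts\n"
            "1\t100\trs1\tA\tG,C\t.\tPASS\t.\tES:SE:LP:SS\t0.1:0.05:3:100\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tES:SE:LP:SS\t0.1:0.05:3:100\n"
        )
        df, _, ledger = read_gwas_vcf(path)
        assert len(df) == 1
        assert ledger["multiallelic"] == 1

    def test_missing_mandatory_column_fatal(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tCHR\tBP\n")
        with pytest.raises(ValueError, match="mandatory"):
            read_pgc_tsv(path)

    def test_case_control_counts_give_effective_n(self, tmp_path):
        path = tmp_path / "cc.tsv"
        path.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\tNCA\tNCO\n"
            "rs1\t1\t100\tA\tG\t0.1\t0.05\t0.5\t27205\t110881\n"
        )
        df, meta, _ = read_pgc_tsv(path)
        assert round(df["n"].iloc[0]) == 87_381
        assert meta.n_cases == 27_205


def _pal_free(df):
    return df


class TestHarmonization:
    def test_allele_swap_negates_z(self):
        a = validate_variants(make_variants(
            [("1", 100, "rs1", "A", "G", 0.1, 0.05, 0.045, 1000.0)]
        ))
        b = validate_variants(make_variants(
            [("1", 100, "rs1", "G", "A", 0.1, 0.05, 0.045, 1000.0)]
        ))
        pair = harmonize_pair(a, b)
        assert len(pair.table) == 1
        assert pair.table["z_b"].iloc[0] == pytest.approx(-2.0)

    def test_strand_complement_match(self):
        a = validate_variants(make_variants(
            [("1", 100, "rs1", "A", "G", 0.1, 0.05, 0.045, 1000.0)]
        ))
        b = validate_variants(make_variants(
            [("1", 100, "rs1", "T", "C", 0.1, 0.05, 0.045, 1000.0)]
        ))
        pair = harmonize_pair(a, b)
        assert len(pair.table) == 1
        assert pair.table["z_b"].iloc[0] == pytest.approx(2.0)

    def test_palindromic_always_excluded(self):
        a = validate_variants(make_variants(
            [("1", 100, "rs1", "A", "T", 0.1, 0.05, 0.045, 1000.0)]
        ))
        b = a.copy()
        pair = harmonize_pair(a, b)
        assert len(pair.table) == 0
        assert pair.ledger["palindromic_a"] == 1
        assert pair.ledger["palindromic_b"] == 1

    def test_build_mismatch_fatal(self):
        a = validate_variants(make_variants(
            [("1", 100, "rs1", "A", "G", 0.1, 0.05, 0.045, 1000.0)]
        ))
        with pytest.raises(ValueError, match="build"):
            harmonize_pair(
                a, a, TraitMeta("a", 10, genome_build="GRCh37"),
                TraitMeta("b", 10, genome_build="GRCh38"),
            )

    def test_rsid_fallback_and_position_conflict(self):
        a = validate_variants(make_variants([
            ("1", np.nan, "rs1", "A", "G", 0.1, 0.05, 0.045, 1000.0),
            ("1", 500, "rs9", "A", "G", 0.1, 0.05, 0.045, 1000.0),
        ]))
        b = validate_variants(make_variants([
            ("1", 100, "rs1", "A", "G", 0.1, 0.05, 0.045, 1000.0),
            ("1", 600, "rs9", "A", "G", 0.1, 0.05, 0.045, 1000.0),
        ]))
        pair = harmonize_pair(a, b)
        # rs1 rescued through the rsID fallback (no position on side a);
        # rs9 has conflicting coordinates and is rejected
        assert len(pair.table) == 1
        assert pair.ledger["position_conflict"] == 1

    def test_corrupted_study_recovered(self, small_scene, rng):
        a = small_scene.studies["trait_a"]
        b = small_scene.studies["trait_b"]
        b_cor, truth = inject_allele_corruption(
            b, rng, swap_frac=0.05, strand_frac=0.02, palindromic_frac=0.03
        )
        pair = harmonize_pair(a, b_cor)
        n_pal = len(truth["palindromic"])
        assert len(pair.table) == len(a) - n_pal
        # every surviving z_b equals the uncorrupted original
        orig = dict(zip(b["rsid"], b["z"]))
        assert np.allclose(
            pair.table["z_b"].to_numpy(),
            [orig[r] for r in pair.table["rsid"]],
        )

    def test_ledger_conservation(self, small_scene, rng):
        a = small_scene.studies["trait_a"]
        b_cor, _ = inject_allele_corruption(
            small_scene.studies["trait_b"], rng, swap_frac=0.1, palindromic_frac=0.05
        )
        pair = harmonize_pair(a, b_cor)
        led = pair.ledger
        attributed_a = (
            led["palindromic_a"] + led["duplicate_key_a"] + led["unmatched_a"]
            + led["position_conflict"] + led["allele_mismatch"]
        )
        attributed_b = (
            led["palindromic_b"] + led["duplicate_key_b"] + led["unmatched_b"]
            + led["position_conflict"] + led["allele_mismatch"]
        )
        assert len(a) == len(pair.table) + attributed_a
        assert len(b_cor) == len(pair.table) + attributed_b

    def test_harmonization_is_involution(self, small_scene, rng):
        a = small_scene.studies["trait_a"]
        b_cor, _ = inject_allele_corruption(
            small_scene.studies["trait_b"], rng, swap_frac=0.05
        )
        once = harmonize_pair(a, b_cor)
        a2, b2 = pair_to_tables(once)
        twice = harmonize_pair(a2, b2)
        assert len(twice.table) == len(once.table)
        assert np.allclose(twice.table["z_a"], once.table["z_a"])
        assert np.allclose(twice.table["z_b"], once.table["z_b"])

    def test_sign_consistency_under_global_flip(self, small_scene):
        """Negating every beta in study b and swapping its allele columns
        encodes the same associations, so harmonization must be invariant."""
        a = small_scene.studies["trait_a"]
        b = small_scene.studies["trait_b"]
        flipped = b.copy()
        flipped["beta"] = -flipped["beta"]
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped = validate_variants(flipped)
        ref = harmonize_pair(a, b)
        alt = harmonize_pair(a, flipped)
        assert np.allclose(ref.table["z_b"], alt.table["z_b"])

    def test_duplicate_key_keeps_first(self):
        a = validate_variants(make_variants([
            ("1", 100, "rs1", "A", "G", 0.1, 0.05, 0.045, 1000.0),
            ("1", 100, "rs1b", "A", "C", 0.3, 0.05, 0.045, 1000.0),
        ]))
        b = validate_variants(make_variants(
            [("1", 100, "rs1", "A", "G", 0.2, 0.05, 0.045, 1000.0)]
        ))
        pair = harmonize_pair(a, b)
        assert pair.ledger["duplicate_key_a"] == 1
        assert pair.table["z_a"].iloc[0] == pytest.approx(2.0)


@settings(max_examples=30, deadline=None)
@given(
    beta=st.floats(-1, 1, allow_nan=False),
    se=st.floats(0.01, 1, allow_nan=False),
)
def test_z_and_chi2_consistent(beta, se):
    df = validate_variants(make_variants(
        [("1", 100, "rs1", "A", "G", beta, se, 0.5, 100.0)]
    ))
    assert df["chi2"].iloc[0] == pytest.approx(df["z"].iloc[0] ** 2)
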