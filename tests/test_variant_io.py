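"""Dialect VCF parsing, key normalization, CN segments, gene lists, tables."""

import pytest

from clonaltrack.errors import ConfigurationError, ValidationError, VcfParseError
from clonaltrack.variant_io import (
    CNSegment, VariantKey, normalize_variant, read_caller_vcf, read_cn_segments,
    read_gene_list, read_variant_table, write_variant_table,
)

from conftest import qv, write_vcf


class TestNormalization:
    def test_chr_prefix_and_case(self):
        k = normalize_variant("chr7", 100, "a", "t")
        assert (k.chrom, k.ref, k.alt) == ("7", "A", "T")

    @pytest.mark.parametrize(
        "raw,expected",
        [
            # padded deletion: shared trailing base then anchored
            (("1", 100, "ATG", "AG"), ("1", 100, "AT", "A")),
            # shared leading base beyond the anchor
            (("1", 100, "CAT", "CT"), ("1", 100, "CA", "C")),
            # insertion with both-side padding: right-trim runs first
            (("1", 100, "TACGG", "TAACGG"), ("1", 100, "T", "TA")),
            # SNV already minimal
            (("1", 100, "G", "C"), ("1", 100, "G", "C")),
        ],
    )
    def test_indel_trimming(self, raw, expected):
        k = normalize_variant(*raw)
        assert (k.chrom, k.pos, k.ref, k.alt) == expected

    def test_idempotent(self):
        k1 = normalize_variant("chr1", 100, "ATG", "AG")
        k2 = normalize_variant(k1.chrom, k1.pos, k1.ref, k1.alt)
        assert k1 == k2

    def test_invalid_keys_rejected(self):
        with pytest.raises(ValidationError):
            VariantKey(chrom="1", pos=1, ref="A", alt="A")
        with pytest.raises(ValidationError):
            VariantKey(chrom="1", pos=1, ref="", alt="T")


class TestDialectParsing:
    def test_tier_counts_snv(self, tmp_path):
        # per-nucleotide tier-1 counts: A=0, C=38, G=49, T=0; REF=G ALT=C
        p = write_vcf(tmp_path / "s.vcf", "tier_counts", [
            "1\t1000\t.\tG\tC\t.\tPASS\tSOMATIC\tAU:CU:GU:TU\t0,0:38,40:49,50:0,0",
        ])
        (rec,) = read_caller_vcf(p, "tier_counts")
        assert (rec.trv, rec.trr) == (38, 49)
        assert rec.depth == 87

    def test_tier_counts_indel_uses_tar_tir(self, tmp_path):
        p = write_vcf(tmp_path / "s.vcf", "tier_counts", [
            "1\t1000\t.\tAT\tA\t.\tPASS\tSOMATIC\tTAR:TIR\t60,65:22,25",
        ])
        (rec,) = read_caller_vcf(p, "tier_counts")
        assert (rec.trv, rec.trr) == (22, 60)
        assert rec.is_indel

    def test_allele_depths_ref_first(self, tmp_path):
        p = write_vcf(tmp_path / "m.vcf", "allele_depths", [
            "1\t2000\t.\tA\tT\t.\tPASS\tSOMATIC\tGT:AD\t0/1:56,44",
        ])
        (rec,) = read_caller_vcf(p, "allele_depths")
        assert (rec.trv, rec.trr) == (44, 56)

    def test_ref_alt_depths(self, tmp_path):
        p = write_vcf(tmp_path / "v.vcf", "ref_alt_depths", [
            "1\t3000\t.\tC\tG\t.\tPASS\tSOMATIC\tGT:RD:AD:FREQ\t0/1:74:17:18.68%",
        ])
        (rec,) = read_caller_vcf(p, "ref_alt_depths")
        assert (rec.trv, rec.trr) == (17, 74)

    def test_non_pass_rows_excluded(self, tmp_path):
        p = write_vcf(tmp_path / "f.vcf", "allele_depths", [
            "1\t2000\t.\tA\tT\t.\tLowQual\tSOMATIC\tGT:AD\t0/1:56,44",
            "1\t3000\t.\tA\tT\t.\tPASS\tSOMATIC\tGT:AD\t0/1:50,50",
            "1\t4000\t.\tA\tT\t.\t.\tSOMATIC\tGT:AD\t0/1:50,10",
        ])
        recs = read_caller_vcf(p, "allele_depths")
        assert [r.key.pos for r in recs] == [3000, 4000]  # PASS and '.' kept

    def test_multiallelic_split_conserves_records(self, tmp_path):
        p = write_vcf(tmp_path / "ma.vcf", "allele_depths", [
            "1\t2000\t.\tA\tT,G\t.\tPASS\tSOMATIC\tGT:AD\t0/1:60,30,10",
        ])
        recs = read_caller_vcf(p, "allele_depths")
        assert len(recs) == 2
        by_alt = {r.key.alt: r for r in recs}
        assert (by_alt["T"].trv, by_alt["T"].trr) == (30, 60)
        assert (by_alt["G"].trv, by_alt["G"].trr) == (10, 60)

    def test_unknown_dialect_is_config_error(self, tmp_path):
        p = write_vcf(tmp_path / "x.vcf", "allele_depths", [])
        with pytest.raises(ConfigurationError, match="dialect"):
            read_caller_vcf(p, "no_such_dialect")

    def test_missing_format_field_names_it(self, tmp_path):
        p = write_vcf(tmp_path / "x.vcf", "ref_alt_depths", [
            "1\t2000\t.\tA\tT\t.\tPASS\tSOMATIC\tGT:AD\t0/1:44",
        ])
        with pytest.raises(VcfParseError, match="RD"):
            read_caller_vcf(p, "ref_alt_depths")


class TestCNSegments:
    def test_read_sorted_with_header(self, tmp_path):
        p = tmp_path / "cn.tsv"
        p.write_text("chrom\tstart\tend\tcn\n1\t1001\t2000\t3\n1\t1\t1000\t2\n")
        segs = read_cn_segments(p)
        assert [(s.start, s.cn) for s in segs] == [(1, 2), (1001, 3)]

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "cn.tsv"
        p.write_text("1\t1\t1000\t2\n1\t500\t1500\t3\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_cn_segments(p)

    def test_non_integer_cn_strict(self, tmp_path):
        p = tmp_path / "cn.tsv"
        p.write_text("1\t1\t1000\t2.5\n")
        with pytest.raises(ValidationError, match="copy number"):
            read_cn_segments(p)
        assert read_cn_segments(p, strict_integer=False)[0].cn == 2

    def test_inclusive_coordinates(self):
        seg = CNSegment(chrom="1", start=10, end=20, cn=3)
        assert seg.contains(10) and seg.contains(20) and not seg.contains(21)


class TestGeneList:
    def test_case_fold_dedup(self, tmp_path):
        p = tmp_path / "kg.txt"
        p.write_text("NRAS\nKRAS\nnras\n")
        assert read_gene_list(p) == {"NRAS", "KRAS"}

    def test_comments_and_blanks_ignored(self, tmp_path):
        p = tmp_path / "kg.txt"
        p.write_text("# comment\n\nATM\n")
        assert read_gene_list(p) == {"ATM"}

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "kg.txt"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert read_gene_list(p) == set()


class TestVariantTable:
    def test_empty_list_header_only(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_variant_table([], p)
        df = read_variant_table(p)
        assert len(df) == 0 and "vaf_percent" in df.columns

    def test_karyotype_row_order(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_variant_table([qv(chrom="2", pos=5), qv(chrom="1", pos=9),
                             qv(chrom="X", pos=1)], p)
        df = read_variant_table(p)
        assert list(df["chrom"]) == ["1", "2", "X"]

    def test_round_trip_preserves_values(self, tmp_path):
        p = tmp_path / "t.tsv"
        vs = [qv(pos=10, trv=38, trr=49, cn=3, gene="NRAS", effect="missense_variant",
                 is_key_gene=True),
              qv(pos=20, trv=10, trr=90, cn=2)]
        write_variant_table(vs, p, header_comments=["provenance line"])
        df = read_variant_table(p)
        assert len(df) == 2
        row = df[df.pos == 10].iloc[0]
        assert row["vaf_percent"] == pytest.approx(100 * 38 / 87)
        assert row["dp"] == 87 and row["cn"] == 3 and bool(row["is_key_gene"])
        assert row["abundance"] == pytest.approx((38 / 87) * 87 * 3)
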