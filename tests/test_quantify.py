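"""VAF/abundance/cell-frequency arithmetic, CN assignment, filters, summaries."""

import pytest
from hypothesis import given, settings, strategies as st

from clonaltrack.errors import DomainError
from clonaltrack.quantify import (
    FilterConfig, apply_filters, assign_copy_number, compute_abundance,
    compute_cell_frequency, compute_vaf, flag_key_genes, round_half_away,
    summarize_by_chromosome, summarize_effect_types, variants_from_table,
)
from clonaltrack.variant_io import CNSegment, VariantKey, variant_table

from conftest import qv, qv_with_vaf


class TestVaf:
    @pytest.mark.parametrize("trv,trr,expected", [
        (44, 56, 0.44),
        (0, 50, 0.0),
        (17, 74, 17 / 91),  # 18.68% -> displays as 19 at DP 91
    ])
    def test_values(self, trv, trr, expected):
        assert compute_vaf(trv, trr) == pytest.approx(expected, abs=1e-12)

    def test_zero_depth_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_vaf(0, 0)

    def test_display_rounding(self):
        assert round_half_away(100 * 17 / 91) == 19
        assert round_half_away(43.5) == 44
        assert round_half_away(0.4) == 0


class TestAbundance:
    @pytest.mark.parametrize("vaf,dp,cn,expected", [
        (0.44, 87, 2, 76.56),   # dominant-clone oncogene at presentation
        (0.0, 100, 2, 0.0),
        (0.26, 70, 3, 54.6),
    ])
    def test_product(self, vaf, dp, cn, expected):
        assert compute_abundance(vaf, dp, cn) == pytest.approx(expected)

    def test_variant_consistency_property(self):
        v = qv(trv=38, trr=49, cn=3)
        assert v.abundance / (v.dp * v.cn) == pytest.approx(v.vaf, abs=1e-9)


class TestCellFrequency:
    @pytest.mark.parametrize("vaf,cn,mult,expected", [
        (0.5, 2, 1, 1.0),    # clonal heterozygous diploid
        (0.25, 2, 1, 0.5),
        (0.8, 2, 1, 1.0),    # capped at 1
        (0.3, 3, 2, 0.45),
    ])
    def test_values(self, vaf, cn, mult, expected):
        assert compute_cell_frequency(vaf, cn, mult) == pytest.approx(expected)

    def test_cn_zero_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_cell_frequency(0.5, 0)


class TestCopyNumberAssignment:
    SEGS = [CNSegment("1", 1, 1000, 3), CNSegment("1", 1001, 2000, 1)]

    def test_containing_segment(self):
        cn, imputed = assign_copy_number(VariantKey("1", 500, "A", "T"), self.SEGS)
        assert (cn, imputed) == (3, False)

    def test_boundaries_inclusive(self):
        assert assign_copy_number(VariantKey("1", 1000, "A", "T"), self.SEGS)[0] == 3
        assert assign_copy_number(VariantKey("1", 1001, "A", "T"), self.SEGS)[0] == 1

    def test_uncovered_gets_default_imputed(self):
        cn, imputed = assign_copy_number(VariantKey("2", 500, "A", "T"), self.SEGS,
                                         default_cn=2)
        assert (cn, imputed) == (2, True)


class TestFilters:
    def test_boundary_retention(self):
        # lower VAF bound and both DP bounds are inclusive
        kept = apply_filters([
            qv_with_vaf(0.10, dp=40, pos=1),
            qv_with_vaf(0.10, dp=250, pos=2),
            qv_with_vaf(0.50, dp=40, pos=3),
        ])
        assert len(kept) == 3

    def test_boundary_exclusion(self):
        dropped = apply_filters([
            qv(pos=1, trv=999, trr=9001),   # vaf 9.99%
            qv_with_vaf(0.5, dp=39, pos=2),
            qv_with_vaf(0.5, dp=251, pos=3),
        ])
        assert dropped == []

    def test_known_subset_retained(self):
        vs = [
            qv_with_vaf(0.5, dp=30, pos=1),
            qv_with_vaf(0.5, dp=251, pos=2),
            qv_with_vaf(0.12, dp=100, pos=3),
            qv_with_vaf(0.05, dp=100, pos=4),
            qv_with_vaf(0.10, dp=250, pos=5),
        ]
        kept = apply_filters(vs)
        assert [v.key.pos for v in kept] == [3, 5]

    def test_idempotent_and_order_preserving(self):
        vs = [qv_with_vaf(0.2, dp=100, pos=p) for p in (9, 3, 5)]
        once = apply_filters(vs)
        assert apply_filters(once) == once
        assert [v.key.pos for v in once] == [9, 3, 5]

    @given(st.lists(st.tuples(st.floats(0, 1), st.integers(1, 400)), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_property_exact_band(self, pairs):
        cfg = FilterConfig()
        vs = [qv(pos=i + 1, trv=round(f * d), trr=d - round(f * d))
              for i, (f, d) in enumerate(pairs)]
        for v in apply_filters(vs, cfg):
            assert v.vaf >= cfg.min_vaf and cfg.min_dp <= v.dp <= cfg.max_dp


class TestKeyGenes:
    def test_flagging(self):
        vs = flag_key_genes([qv(pos=1, gene="NRAS"), qv(pos=2, gene="BRAF"),
                             qv(pos=3, gene="")], {"NRAS", "KRAS"})
        assert [v.is_key_gene for v in vs] == [True, False, False]

    def test_restrict_mode(self):
        vs = [qv(pos=i, gene=("ATM" if i % 3 == 0 else f"G{i}")) for i in range(1, 11)]
        kept = flag_key_genes(vs, {"ATM"}, restrict=True)
        assert len(kept) == 3
        assert all(v.gene == "ATM" for v in kept)


class TestSummaries:
    def test_by_chromosome_counts_and_order(self):
        df = summarize_by_chromosome([qv(chrom="1", pos=p) for p in (1, 2, 3)]
                                     + [qv(chrom="X", pos=9)])
        assert df.iloc[0]["chrom"] == "1" and df.iloc[0]["n_variants"] == 3
        assert int(df[df.chrom == "X"]["n_variants"].iloc[0]) == 1
        assert df["n_variants"].sum() == 4
        assert len(df) == 25  # every karyotype chromosome listed

    def test_empty_input_all_zero(self):
        df = summarize_by_chromosome([])
        assert df["n_variants"].sum() == 0

    def test_effect_types(self):
        df = summarize_effect_types([
            qv(pos=1, effect="missense_variant"),
            qv(pos=2, effect="missense_variant"),
            qv(pos=3, effect="stop_gained"),
            qv(pos=4, effect=""),
        ])
        counts = dict(zip(df["effect"], df["n_variants"]))
        assert counts == {"missense_variant": 2, "stop_gained": 1, "unannotated": 1}
        assert df["n_variants"].sum() == 4


def test_variants_from_table_round_trip():
    vs = [qv(pos=10, trv=38, trr=49, cn=3, gene="NRAS", is_key_gene=True),
          qv(chrom="2", pos=20, trv=25, trr=75)]
    back = variants_from_table(variant_table(vs))
    assert {v.key for v in back} == {v.key for v in vs}
    assert sorted((v.trv, v.trr, v.cn) for v in back) == sorted(
        (v.trv, v.trr, v.cn) for v in vs)
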