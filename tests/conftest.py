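"""Shared fixtures: quick variant factories and hand-written dialect VCFs."""

from __future__ import annotations

from pathlib import Path

import pytest

from clonaltrack.quantify import QuantifiedVariant
from clonaltrack.variant_io import VariantKey

VCF_HEADER_COMMON = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic">',
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Annotation">',
    "##contig=<ID=1,length=249250621>",
    "##contig=<ID=2,length=243199373>",
]

DIALECT_FORMAT_HEADERS = {
    "tier_counts": [
        '##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A tier1,tier2">',
        '##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C tier1,tier2">',
        '##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G tier1,tier2">',
        '##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T tier1,tier2">',
        '##FORMAT=<ID=TAR,Number=2,Type=Integer,Description="ref tier1,tier2">',
        '##FORMAT=<ID=TIR,Number=2,Type=Integer,Description="indel tier1,tier2">',
    ],
    "allele_depths": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ],
    "ref_alt_depths": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Ref depth">',
        '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt depth">',
        '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="VAF">',
    ],
}


def write_vcf(path: Path, dialect: str, rows: list[str], sample: str = "TUMOR") -> Path:
    """Write a minimal single-sample VCF with the dialect's FORMAT headers.

    ``rows`` are pre-formatted tab-separated data lines (CHROM..sample).
    """
    lines = VCF_HEADER_COMMON + DIALECT_FORMAT_HEADERS[dialect]
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    lines += rows
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def qv(
    chrom: str = "1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "T",
    trv: int = 50,
    trr: int = 50,
    cn: int = 2,
    gene: str = "",
    effect: str = "",
    is_key_gene: bool = False,
    functional_class: str = "unknown",
    cn_imputed: bool = False,
) -> QuantifiedVariant:
    """Compact QuantifiedVariant factory for tests."""
    return QuantifiedVariant(
        key=VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt),
        trv=trv, trr=trr, cn=cn, gene=gene, effect=effect,
        is_key_gene=is_key_gene, functional_class=functional_class,
        cn_imputed=cn_imputed,
    )


def qv_with_vaf(vaf: float, dp: int = 100, pos: int = 100, **kw) -> QuantifiedVariant:
    """Variant whose trv/trr realize the requested VAF at depth dp as closely
    as integer counts allow (exact when vaf*dp is integral)."""
    trv = round(vaf * dp)
    return qv(pos=pos, trv=trv, trr=dp - trv, **kw)


@pytest.fixture
def study():
    from clonaltrack.datasets import serial_study
    return serial_study()
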