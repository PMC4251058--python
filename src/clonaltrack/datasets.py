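"""Bundled example data: a published serial multiple-myeloma case study.

The dataset reconstructs the key-gene mutation matrix of a single myeloma
patient sampled at disease presentation (2003), first relapse (2010) and
second relapse (2014): fifteen cancer-relevant genes with the reported
integer VAF percent, copy number and depth in each sample where the mutation
passed filtering, and NP (not present) elsewhere.  Whole-sample totals
(number of filtered variants and Shannon diversity index) are carried as
published per-sample statistics; the full variant lists behind them were not
published, so only the key-gene subset is reconstructable.

Genomic coordinates are NOT part of the published matrix: each gene is given
a deterministic representative locus on its true chromosome so that the
variants have well-formed keys.  They are placeholders, stable across
samples, and must not be interpreted as real mutation positions.

Read counts are back-computed from (VAF%, DP) as trv = round(VAF * DP), the
integer split whose recomputed VAF rounds back to the printed percent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .quantify import QuantifiedVariant
from .tracking import SampleVariantSet
from .variant_io import VariantKey

SAMPLE_LABELS = ("Presentation", "Relapse #1", "Relapse #2")
SAMPLE_YEARS = {"Presentation": 2003, "Relapse #1": 2010, "Relapse #2": 2014}

#: published per-sample totals: all filtered variants (N) and Shannon index
PUBLISHED_STATS = {
    "Presentation": {"n_variants": 132, "sdi": 4.67},
    "Relapse #1": {"n_variants": 256, "sdi": 5.30},
    "Relapse #2": {"n_variants": 196, "sdi": 5.11},
}

#: gene -> (functional class, per-sample (VAF%, CN, DP) or None for NP)
KEY_GENE_MATRIX: dict[str, tuple[str, tuple[tuple[int, int, int] | None, ...]]] = {
    "ARHGAP26": ("VUS", ((26, 3, 70), (25, 3, 59), (26, 2, 46))),
    "ARID1A":   ("TSG", ((50, 2, 52), (44, 2, 57), (28, 2, 43))),
    "ATM":      ("TSG", ((49, 3, 49), (54, 3, 46), None)),
    "CD36":     ("VUS", (None, None, (23, 2, 73))),
    "ERBB4":    ("VUS", ((34, 2, 76), (37, 2, 79), (32, 2, 50))),
    "ESR1":     ("VUS", (None, (15, 2, 107), None)),
    "FOXO3":    ("VUS", (None, (21, 2, 68), None)),
    "JAK3":     ("OG",  (None, (12, 3, 66), None)),
    "KRAS":     ("OG",  (None, None, (35, 2, 40))),
    "NRAS":     ("OG",  ((44, 2, 87), (19, 1, 91), None)),
    "NTRK3":    ("VUS", (None, (18, 3, 119), None)),
    "PARP1":    ("DR",  ((45, 2, 65), (39, 2, 66), (32, 2, 41))),
    "PMS2P3":   ("DR",  (None, (11, 3, 76), None)),
    "POLE":     ("DR",  (None, None, (29, 2, 48))),
    "POLK":     ("DR",  (None, (19, 2, 58), None)),
}

#: representative placeholder loci (chrom is the gene's true chromosome)
_GENE_LOCI: dict[str, tuple[str, int, str, str]] = {
    "ARHGAP26": ("5", 142770000, "C", "T"),
    "ARID1A":   ("1", 27100000, "G", "A"),
    "ATM":      ("11", 108120000, "A", "G"),
    "CD36":     ("7", 80300000, "C", "A"),
    "ERBB4":    ("2", 212580000, "G", "T"),
    "ESR1":     ("6", 152130000, "T", "C"),
    "FOXO3":    ("6", 108880000, "C", "G"),
    "JAK3":     ("19", 17940000, "G", "A"),
    "KRAS":     ("12", 25380000, "A", "C"),
    "NRAS":     ("1", 115258744, "C", "G"),
    "NTRK3":    ("15", 88420000, "T", "A"),
    "PARP1":    ("1", 226550000, "G", "C"),
    "PMS2P3":   ("7", 75090000, "A", "T"),
    "POLE":     ("12", 133220000, "C", "T"),
    "POLK":     ("5", 74880000, "G", "T"),
}

_EFFECTS = {"NRAS": "missense_variant", "KRAS": "missense_variant"}


@dataclass
class SerialStudy:
    """The reconstructed three-sample case: samples, key genes and classes."""

    samples: list[SampleVariantSet]
    key_genes: set[str]
    classes: dict[str, str]
    published: dict[str, dict]


def trv_for_percent(vaf_percent: int, dp: int) -> int:
    """Integer variant-read count whose VAF best matches a printed percent."""
    return round(vaf_percent * dp / 100)


def serial_study() -> SerialStudy:
    """Reconstruct the three-sample key-gene study.

    Each non-NP cell becomes one QuantifiedVariant with read counts
    back-computed from the printed VAF percent and depth; the same gene keeps
    the same variant key across samples, so serial tracking sees a surviving
    mutation rather than three unrelated ones.
    """
    samples = []
    for i, label in enumerate(SAMPLE_LABELS):
        variants = []
        for gene, (cls, cells) in KEY_GENE_MATRIX.items():
            cell = cells[i]
            if cell is None:
                continue
            vaf_pct, cn, dp = cell
            chrom, pos, ref, alt = _GENE_LOCI[gene]
            trv = trv_for_percent(vaf_pct, dp)
            variants.append(
                QuantifiedVariant(
                    key=VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt),
                    trv=trv,
                    trr=dp - trv,
                    cn=cn,
                    gene=gene,
                    effect=_EFFECTS.get(gene, "missense_variant"),
                    functional_class=cls,
                    is_key_gene=True,
                )
            )
        s = SampleVariantSet.from_variants(
            label=label, variants=variants, year=SAMPLE_YEARS[label]
        )
        s.meta["published"] = PUBLISHED_STATS[label]
        samples.append(s)
    return SerialStudy(
        samples=samples,
        key_genes=set(KEY_GENE_MATRIX),
        classes={g: cls for g, (cls, _) in KEY_GENE_MATRIX.items()},
        published=PUBLISHED_STATS,
    )
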