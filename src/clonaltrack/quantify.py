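"""Per-variant quantification: VAF, copy number, abundance, cell frequency.

The central quantities, all computed from the designated evidence record of a
consensus variant:

* VAF = TRV / (TRV + TRR), the fraction of reads supporting the variant.
  Kept as a fraction in [0, 1] internally; percent only at presentation.
* DP = TRV + TRR.  Defined from the evidence counts rather than the VCF
  FORMAT ``DP`` field so that the VAF and DP selection filters are
  self-consistent.
* CN: integer copy number of the segment containing the variant; variants in
  regions without a segment get a diploid default and are marked imputed.
* abundance = VAF x DP x CN, the weight of a variant treated as a molecular
  species in diversity calculations.
* cell frequency = min(1, VAF x CN / multiplicity), the estimated fraction
  of cells carrying the mutation, assuming one mutated copy per cell unless
  a higher multiplicity is given.

Variant selection keeps VAF >= 10% and 40 <= DP <= 250 by default (both
bounds inclusive): the lower bounds suppress noise and sub-detectable
subclones, the upper depth bound guards against collapsed repeats and other
pile-up artifacts.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, ValidationError
from .genome import CHROMOSOMES, chrom_sort_key
from .consensus import ConsensusVariant
from .variant_io import CNSegment, VariantKey

FUNCTIONAL_CLASSES = ("OG", "TSG", "DR", "VUS", "unknown")


@dataclass(frozen=True)
class FilterConfig:
    """Variant-selection bounds; defaults are the standard exome filter."""

    min_vaf: float = 0.10
    min_dp: int = 40
    max_dp: int = 250

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValidationError(f"min_vaf must be a fraction in [0,1], got {self.min_vaf}")
        if self.min_dp > self.max_dp:
            raise ValidationError(f"min_dp {self.min_dp} > max_dp {self.max_dp}")


@dataclass(frozen=True)
class QuantifiedVariant:
    """A consensus variant with its clonality quantities and annotation."""

    key: VariantKey
    trv: int
    trr: int
    cn: int
    gene: str = ""
    effect: str = ""
    functional_class: str = "unknown"
    is_key_gene: bool = False
    cn_imputed: bool = False
    multiplicity: int = 1
    callers: frozenset[str] = field(default_factory=frozenset)

    @property
    def vaf(self) -> float:
        return compute_vaf(self.trv, self.trr)

    @property
    def dp(self) -> int:
        return self.trv + self.trr

    @property
    def abundance(self) -> float:
        return compute_abundance(self.vaf, self.dp, self.cn)

    @property
    def cell_frequency(self) -> float:
        return compute_cell_frequency(self.vaf, self.cn, self.multiplicity)


def compute_vaf(trv: int, trr: int) -> float:
    """Variant allele fraction TRV / (TRV + TRR)."""
    total = trv + trr
    if total <= 0:
        raise DomainError("VAF undefined at zero depth (trv + trr = 0)")
    return trv / total


def compute_abundance(vaf: float, dp: int, cn: int) -> float:
    """Molecular-species abundance VAF x DP x CN (VAF as a fraction)."""
    return vaf * dp * cn


def compute_cell_frequency(vaf: float, cn: int, multiplicity: int = 1) -> float:
    """Fraction of cells carrying the mutation: min(1, VAF x CN / multiplicity).

    Assumes the variant sits on ``multiplicity`` of the ``cn`` copies in every
    mutated cell; the conservative default of one mutated copy makes a clonal
    heterozygous diploid variant (VAF 0.5, CN 2) map to cell frequency 1.
    """
    if cn < 1:
        raise DomainError("cell frequency undefined for CN = 0 (flag zero-copy regions upstream)")
    if multiplicity < 1:
        raise DomainError("multiplicity must be >= 1")
    return min(1.0, vaf * cn / multiplicity)


class CNIndex:
    """Bisect-based position lookup over validated, non-overlapping segments."""

    def __init__(self, segments: Sequence[CNSegment]):
        self._by_chrom: dict[str, tuple[list[int], list[CNSegment]]] = {}
        for seg in sorted(segments, key=lambda s: (*chrom_sort_key(s.chrom), s.start)):
            starts, segs = self._by_chrom.setdefault(seg.chrom, ([], []))
            if segs and seg.start <= segs[-1].end:
                raise ValidationError(f"overlapping segments {segs[-1]} and {seg}")
            starts.append(seg.start)
            segs.append(seg)

    def lookup(self, chrom: str, pos: int) -> CNSegment | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, segs = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and segs[i].contains(pos):
            return segs[i]
        return None


def assign_copy_number(
    key: VariantKey,
    segments: Sequence[CNSegment] | CNIndex,
    default_cn: int = 2,
) -> tuple[int, bool]:
    """Copy number of the segment containing the variant, else (default, imputed=True).

    Segment intervals are 1-based inclusive on both ends.
    """
    index = segments if isinstance(segments, CNIndex) else CNIndex(segments)
    seg = index.lookup(key.chrom, key.pos)
    if seg is None:
        return default_cn, True
    return seg.cn, False


# ---------------------------------------------------------------------------
# Annotation extraction

_SNPEFF_ANN_GENE_FIELD = 3  # Allele | Annotation | Impact | Gene_Name | ...
_SNPEFF_ANN_EFFECT_FIELD = 1


def extract_annotation(raw_info: Mapping[str, object]) -> tuple[str, str]:
    """(gene, effect) from an annotation INFO field.

    Understands the ``ANN=`` pipe-delimited convention (first, most severe
    entry wins) and falls back to plain ``GENE=`` / ``EFFECT=`` keys.
    Returns empty strings when no annotation is present.
    """
    ann = raw_info.get("ANN")
    if isinstance(ann, str) and ann:
        first = ann.split(",")[0].split("|")
        effect = first[_SNPEFF_ANN_EFFECT_FIELD] if len(first) > _SNPEFF_ANN_EFFECT_FIELD else ""
        gene = first[_SNPEFF_ANN_GENE_FIELD] if len(first) > _SNPEFF_ANN_GENE_FIELD else ""
        return gene.upper(), effect
    gene = raw_info.get("GENE", "")
    effect = raw_info.get("EFFECT", "")
    return (str(gene).upper() if gene else ""), (str(effect) if effect else "")


def quantify_variants(
    consensus: Iterable[ConsensusVariant],
    segments: Sequence[CNSegment] = (),
    default_cn: int = 2,
    key_genes: set[str] | None = None,
    functional_classes: Mapping[str, str] | None = None,
    multiplicity: int = 1,
) -> list[QuantifiedVariant]:
    """Attach VAF/DP/CN/abundance/annotation to each consensus variant.

    Read counts come from each variant's evidence record; gene and effect are
    taken from its annotation INFO content when present.  ``functional_classes``
    maps gene symbol to one of OG / TSG / DR / VUS.
    """
    index = CNIndex(segments)
    key_genes = {g.upper() for g in key_genes} if key_genes else set()
    classes = {g.upper(): c for g, c in (functional_classes or {}).items()}
    out: list[QuantifiedVariant] = []
    for cv in consensus:
        cn, imputed = assign_copy_number(cv.key, index, default_cn)
        gene, effect = extract_annotation(cv.evidence.raw_info)
        out.append(
            QuantifiedVariant(
                key=cv.key,
                trv=cv.evidence.trv,
                trr=cv.evidence.trr,
                cn=cn,
                cn_imputed=imputed,
                gene=gene,
                effect=effect,
                functional_class=classes.get(gene, "unknown"),
                is_key_gene=bool(gene) and gene in key_genes,
                multiplicity=multiplicity,
                callers=frozenset(cv.supporting_callers),
            )
        )
    return out


def apply_filters(
    variants: Iterable[QuantifiedVariant], cfg: FilterConfig | None = None
) -> list[QuantifiedVariant]:
    """Keep variants with vaf >= min_vaf and min_dp <= dp <= max_dp.

    All bounds inclusive; input order preserved; idempotent.
    """
    cfg = cfg or FilterConfig()
    return [
        v for v in variants
        if v.vaf >= cfg.min_vaf and cfg.min_dp <= v.dp <= cfg.max_dp
    ]


def flag_key_genes(
    variants: Iterable[QuantifiedVariant],
    key_genes: set[str],
    restrict: bool = False,
) -> list[QuantifiedVariant]:
    """Set ``is_key_gene`` by membership of ``gene`` in the key-gene list.

    With ``restrict=True`` only key-gene variants are returned (the
    key-gene-intersection selection mode).
    """
    kg = {g.upper() for g in key_genes}
    out = [replace(v, is_key_gene=bool(v.gene) and v.gene.upper() in kg) for v in variants]
    if restrict:
        out = [v for v in out if v.is_key_gene]
    return out


def summarize_by_chromosome(variants: Iterable[QuantifiedVariant]) -> pd.DataFrame:
    """Per-chromosome variant tallies in karyotype order (all chromosomes listed)."""
    counts = {c: 0 for c in CHROMOSOMES}
    extra: dict[str, int] = {}
    for v in variants:
        if v.key.chrom in counts:
            counts[v.key.chrom] += 1
        else:
            extra[v.key.chrom] = extra.get(v.key.chrom, 0) + 1
    rows = [{"chrom": c, "n_variants": n} for c, n in counts.items()]
    rows += [{"chrom": c, "n_variants": n} for c, n in sorted(extra.items())]
    return pd.DataFrame(rows, columns=["chrom", "n_variants"])


def summarize_effect_types(variants: Iterable[QuantifiedVariant]) -> pd.DataFrame:
    """Counts per distinct annotation effect string; empty effects pool as 'unannotated'."""
    counts: dict[str, int] = {}
    for v in variants:
        eff = v.effect or "unannotated"
        counts[eff] = counts.get(eff, 0) + 1
    rows = [{"effect": e, "n_variants": n} for e, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["effect", "n_variants"])


def variants_from_table(df: pd.DataFrame) -> list[QuantifiedVariant]:
    """Rebuild QuantifiedVariants from a table written by ``write_variant_table``.

    Read counts are recovered from (vaf_percent, dp); exact when the table
    was produced by this package (vaf_percent is written at full precision).
    """
    out = []
    for row in df.itertuples(index=False):
        dp = int(row.dp)
        trv = int(round(row.vaf_percent / 100.0 * dp))
        out.append(
            QuantifiedVariant(
                key=VariantKey(chrom=str(row.chrom), pos=int(row.pos),
                               ref=str(row.ref), alt=str(row.alt)),
                trv=trv,
                trr=dp - trv,
                cn=int(row.cn),
                gene="" if pd.isna(row.gene) else str(row.gene),
                effect="" if pd.isna(row.effect) else str(row.effect),
                functional_class=str(getattr(row, "functional_class", "unknown")),
                is_key_gene=bool(row.is_key_gene),
                cn_imputed=bool(getattr(row, "cn_imputed", False)),
                callers=frozenset(
                    str(getattr(row, "callers", "")).split(",")
                ) if getattr(row, "callers", "") else frozenset(),
            )
        )
    return out


def round_half_away(x: float) -> int:
    """Round half away from zero (display convention for integer VAF percent)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
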