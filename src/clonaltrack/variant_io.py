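"""Reading caller-specific somatic VCF dialects, copy-number segments and gene lists.

Somatic callers agree on the VCF container but not on how per-allele read
support is encoded in FORMAT.  Three conventions cover the common tools:

``tier_counts``
    Per-nucleotide tier-stratified counts (``AU``, ``CU``, ``GU``, ``TU``,
    each ``tier1,tier2``); indels use ``TAR``/``TIR`` (tier-stratified
    reference / indel read counts).  Only tier-1 (high-confidence) counts are
    used.  This is the Strelka convention.
``allele_depths``
    A single REF-first allele-depth array ``AD`` (the MuTect / GATK
    convention).
``ref_alt_depths``
    Separate reference-depth ``RD`` and alternate-depth ``AD`` scalars plus a
    ``FREQ`` string (the VarScan2 convention).

New dialects can be registered without touching the readers: each dialect is
a small declarative entry in :data:`DIALECTS` mapping FORMAT fields to read
counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Any, Callable, Iterable

import pandas as pd
from cyvcf2 import VCF

from .errors import ConfigurationError, ValidationError, VcfParseError
from .genome import chrom_sort_key, normalize_chrom

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import QuantifiedVariant

logger = logging.getLogger(__name__)

_NUCS = ("A", "C", "G", "T")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic identity of a variant.

    Equal variants emitted by different callers in different paddings compare
    equal after :func:`normalize_variant`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValidationError(f"empty allele in variant key {self}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt in variant key {self}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def sort_key(self) -> tuple[int, str, int, str, str]:
        return (*chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build a :class:`VariantKey` in canonical form.

    Strips any ``chr`` prefix, uppercases alleles and, for indels, trims
    shared trailing then leading ref/alt bases down to one anchor base,
    adjusting ``pos``.  Idempotent: normalizing an already-normal key is a
    no-op.
    """
    chrom = normalize_chrom(chrom)
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


@dataclass(frozen=True)
class CallerRecord:
    """One caller's read-count evidence for a variant.

    ``trv``/``trr`` are the total reads supporting the variant and the
    reference; their sum serves as the record's depth.
    """

    key: VariantKey
    caller_id: str
    trv: int
    trr: int
    is_indel: bool = False
    raw_info: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.trv < 0 or self.trr < 0:
            raise ValidationError(f"negative read count in {self.key}: trv={self.trv} trr={self.trr}")

    @property
    def depth(self) -> int:
        return self.trv + self.trr


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment, 1-based inclusive [start, end]."""

    chrom: str
    start: int
    end: int
    cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment start > end: {self}")
        if self.cn < 0:
            raise ValidationError(f"negative copy number: {self}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# Dialects


@dataclass(frozen=True)
class Dialect:
    """Declarative mapping from a caller's FORMAT fields to (trv, trr)."""

    name: str
    extract: Callable[["_RecordView", str, str], tuple[int, int]]
    description: str = ""


class _RecordView:
    """Thin accessor over one cyvcf2 record + selected sample column."""

    def __init__(self, variant: Any, sample_index: int, line_no: int, caller: str):
        self._v = variant
        self._i = sample_index
        self.line_no = line_no
        self.caller = caller

    def fmt_ints(self, name: str) -> list[int]:
        arr = self._v.format(name)
        if arr is None:
            raise VcfParseError(
                f"{self.caller}: missing FORMAT field {name!r} at record "
                f"{self._v.CHROM}:{self._v.POS} (data line {self.line_no})"
            )
        return [int(x) for x in arr[self._i]]


def _extract_tier_counts(rec: _RecordView, ref: str, alt: str) -> tuple[int, int]:
    if len(ref) == 1 and len(alt) == 1 and ref in _NUCS and alt in _NUCS:
        trv = rec.fmt_ints(f"{alt}U")[0]
        trr = rec.fmt_ints(f"{ref}U")[0]
    else:  # indel convention of the same caller family: TAR=ref, TIR=indel
        trv = rec.fmt_ints("TIR")[0]
        trr = rec.fmt_ints("TAR")[0]
    return trv, trr


def _extract_allele_depths(rec: _RecordView, ref: str, alt: str) -> tuple[int, int]:
    ad = rec.fmt_ints("AD")
    alts = list(rec._v.ALT)
    idx = alts.index(alt) + 1  # REF occupies slot 0
    if idx >= len(ad):
        raise VcfParseError(
            f"{rec.caller}: AD array too short for ALT {alt!r} at "
            f"{rec._v.CHROM}:{rec._v.POS} (data line {rec.line_no})"
        )
    return ad[idx], ad[0]


def _extract_ref_alt_depths(rec: _RecordView, ref: str, alt: str) -> tuple[int, int]:
    return rec.fmt_ints("AD")[0], rec.fmt_ints("RD")[0]


DIALECTS: dict[str, Dialect] = {
    "tier_counts": Dialect(
        "tier_counts", _extract_tier_counts,
        "per-nucleotide tier-1/tier-2 counts (AU/CU/GU/TU; TAR/TIR for indels)",
    ),
    "allele_depths": Dialect(
        "allele_depths", _extract_allele_depths,
        "single REF-first allele-depth array AD",
    ),
    "ref_alt_depths": Dialect(
        "ref_alt_depths", _extract_ref_alt_depths,
        "separate RD (reference) and AD (alternate) depth fields",
    ),
}

#: conventional dialect for each supported caller tag
CALLER_DIALECTS: dict[str, str] = {
    "strelka": "tier_counts",
    "mutect": "allele_depths",
    "varscan2": "ref_alt_depths",
}


def register_dialect(dialect: Dialect) -> None:
    DIALECTS[dialect.name] = dialect


# ---------------------------------------------------------------------------
# Readers


def _pick_sample(samples: list[str]) -> int:
    """Tumor-sample column: the one named TUMOR if present, else the last."""
    for i, s in enumerate(samples):
        if s.upper() == "TUMOR":
            return i
    return max(len(samples) - 1, 0)


def read_caller_vcf(
    path: str | Path,
    dialect: str,
    caller_id: str | None = None,
    sample: str | None = None,
) -> list[CallerRecord]:
    """Parse one caller's somatic VCF into uniform :class:`CallerRecord` s.

    Multi-allelic rows are split into one record per ALT allele.  Rows whose
    FILTER column is anything other than PASS or ``.`` are excluded: the
    caller itself rejected them, and downstream selection filters on VAF/DP
    assume caller-accepted evidence.

    Parameters
    ----------
    path:
        VCF 4.x file (plain or bgzipped).
    dialect:
        One of the registered dialect tags (see :data:`DIALECTS`).
    caller_id:
        Tag stored on each record; defaults to the dialect name.
    sample:
        Sample column to read counts from; default is the column named
        ``TUMOR`` if present, otherwise the last column.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        )
    d = DIALECTS[dialect]
    caller_id = caller_id or dialect
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample is not None:
        if sample not in samples:
            raise ConfigurationError(f"sample {sample!r} not in VCF {path} (has {samples})")
        si = samples.index(sample)
    else:
        si = _pick_sample(samples)

    records: list[CallerRecord] = []
    for line_no, v in enumerate(vcf, start=1):
        if v.FILTER is not None:  # cyvcf2: None means PASS or '.'
            continue
        info = dict(v.INFO)
        for alt in v.ALT:
            key = normalize_variant(v.CHROM, v.POS, v.REF, alt)
            rec_view = _RecordView(v, si, line_no, caller_id)
            trv, trr = d.extract(rec_view, v.REF.upper(), alt.upper())
            records.append(
                CallerRecord(
                    key=key, caller_id=caller_id, trv=trv, trr=trr,
                    is_indel=key.is_indel, raw_info=info,
                )
            )
    vcf.close()
    return records


def read_cn_segments(path: str | Path, strict_integer: bool = True) -> list[CNSegment]:
    """Read a (chrom, start, end, cn) TSV of copy-number segments.

    A header line is tolerated.  Segments are normalized to bare chromosome
    labels, sorted by karyotype order then start, and checked for overlap —
    two segments covering the same base on one chromosome is a validation
    error, because copy-number assignment must be unambiguous.
    """
    path = Path(path)
    segments: list[CNSegment] = []
    first_data_line = True
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                parts = line.split()
            if len(parts) < 4:
                raise ValidationError(f"{path}: expected >=4 columns, got {line!r}")
            chrom, start_s, end_s, cn_s = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                if first_data_line:  # tolerate a single header line
                    first_data_line = False
                    continue
                raise ValidationError(f"{path}: non-integer coordinates in {line!r}")
            first_data_line = False
            cn_f = float(cn_s)
            if cn_f != int(cn_f):
                if strict_integer:
                    raise ValidationError(
                        f"{path}: non-integer copy number {cn_s!r}; round ratio-based "
                        f"CN calls to integers upstream or pass strict_integer=False"
                    )
                cn = round(cn_f)
            else:
                cn = int(cn_f)
            segments.append(CNSegment(chrom=normalize_chrom(chrom), start=start, end=end, cn=cn))

    segments.sort(key=lambda s: (*chrom_sort_key(s.chrom), s.start))
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValidationError(f"{path}: overlapping segments {a} and {b}")
    return segments


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; uppercased and deduplicated.

    Blank lines and ``#`` comments are ignored.  An empty result is legal
    (warning only): it disables key-gene flagging rather than failing a run.
    """
    genes: set[str] = set()
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split()[0].upper())
    if not genes:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
        logger.warning("gene list %s is empty", path)
    return genes


# ---------------------------------------------------------------------------
# Tabular output

VARIANT_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "effect", "vaf_percent", "cn", "dp",
    "abundance", "cell_frequency", "is_key_gene", "callers",
    "functional_class", "cn_imputed",
]


def variant_table(variants: Iterable["QuantifiedVariant"]) -> pd.DataFrame:
    """Quantified variants as a DataFrame in the stable column/row order."""
    rows = []
    for v in sorted(variants, key=lambda v: v.key.sort_key()):
        rows.append({
            "chrom": v.key.chrom, "pos": v.key.pos, "ref": v.key.ref, "alt": v.key.alt,
            "gene": v.gene, "effect": v.effect,
            "vaf_percent": v.vaf * 100.0, "cn": v.cn, "dp": v.dp,
            "abundance": v.abundance, "cell_frequency": v.cell_frequency,
            "is_key_gene": v.is_key_gene, "callers": ",".join(sorted(v.callers)),
            "functional_class": v.functional_class, "cn_imputed": v.cn_imputed,
        })
    return pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)


def write_variant_table(
    variants: Iterable["QuantifiedVariant"],
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    """Write quantified variants as TSV (UTF-8, LF), deterministically ordered.

    Rows sort by karyotype order, then position, then alt allele.  Optional
    ``header_comments`` become ``#``-prefixed provenance lines above the header.
    """
    df = variant_table(variants)
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_variant_table`."""
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
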