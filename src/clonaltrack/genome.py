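"""Chromosome naming, karyotype ordering and GRCh37 chromosome sizes."""

from __future__ import annotations

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

_KARYOTYPE_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

# GRCh37/hg19 chromosome lengths (bp), primary assembly.
GRCH37_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
    "MT": 16569,
}


def normalize_chrom(chrom: str) -> str:
    """Strip any ``chr`` prefix and map mitochondrial aliases to ``MT``."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("M", "MT"):
        return "MT"
    return c.upper() if c.upper() in ("X", "Y") else c


def chrom_rank(chrom: str) -> int:
    """Karyotype rank (1..22, X, Y, MT). Unknown labels sort last, alphabetically."""
    return _KARYOTYPE_RANK.get(chrom, len(CHROMOSOMES))


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (chrom_rank(chrom), chrom)


def cumulative_offsets(lengths: dict[str, int] | None = None) -> dict[str, int]:
    """Cumulative genomic start offset per chromosome, in karyotype order.

    ``offset[c] + pos`` places a 1-based position on a single concatenated axis,
    as used by whole-genome overview plots.
    """
    lengths = GRCH37_LENGTHS if lengths is None else lengths
    chroms = sorted(lengths, key=chrom_sort_key)
    offsets: dict[str, int] = {}
    total = 0
    for c in chroms:
        offsets[c] = total
        total += lengths[c]
    return offsets
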