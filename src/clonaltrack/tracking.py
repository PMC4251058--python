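"""Serial-sample variant tracking and fate classification.

Given a time-ordered series of filtered variant sets (e.g. presentation,
first relapse, second relapse), each consecutive pair of samples defines a
transition across a selection event such as definitive therapy.  Every
variant key present in either sample takes exactly one fate:

* survived  — present in both samples,
* gained    — absent before, present after,
* dead pool — present before, absent after (lost through selection).

Matching is by exact normalized genomic key.  The key-gene matrix aggregates
to gene level on top of that: a gene is present in a sample when any of its
filtered variants is, and its cell shows the (VAF%, CN, DP) of the
highest-abundance variant.  Presence means membership in the *post-filter*
set — a variant dropped by the VAF/DP filters counts as absent, but callers
may still have detected it, so an optional pre-filter key set is carried for
diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diversity import DiversityReport, diversity_report
from .errors import ValidationError
from .quantify import QuantifiedVariant, round_half_away
from .variant_io import VariantKey


@dataclass
class SampleVariantSet:
    """All filtered variants of one time-point sample, keyed by variant identity."""

    label: str
    year: int | None
    variants: dict[VariantKey, QuantifiedVariant]
    diversity: DiversityReport | None = None
    prefilter_keys: frozenset[VariantKey] = frozenset()
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_variants(
        cls,
        label: str,
        variants: Iterable[QuantifiedVariant],
        year: int | None = None,
        weight_mode: str = "abundance",
        prefilter_keys: Iterable[VariantKey] = (),
        compute_diversity: bool = True,
    ) -> "SampleVariantSet":
        vmap: dict[VariantKey, QuantifiedVariant] = {}
        for v in variants:
            if v.key in vmap:
                raise ValidationError(f"duplicate variant key {v.key} in sample {label!r}")
            vmap[v.key] = v
        div = diversity_report(vmap.values(), weight_mode) if (vmap and compute_diversity) else None
        return cls(label=label, year=year, variants=vmap, diversity=div,
                   prefilter_keys=frozenset(prefilter_keys))

    @property
    def keys(self) -> frozenset[VariantKey]:
        return frozenset(self.variants)

    def key_gene_symbols(self) -> set[str]:
        """Distinct key-gene symbols mutated in this sample (post-filter)."""
        return {v.gene for v in self.variants.values() if v.is_key_gene and v.gene}


def pair_samples(
    a: SampleVariantSet, b: SampleVariantSet
) -> tuple[frozenset[VariantKey], frozenset[VariantKey], frozenset[VariantKey]]:
    """Exact-key three-way partition: (shared, only in a, only in b)."""
    shared = a.keys & b.keys
    return shared, a.keys - shared, b.keys - shared


@dataclass(frozen=True)
class Transition:
    """Fates of variant keys across one selection event."""

    from_label: str
    to_label: str
    survived: frozenset[VariantKey]
    gained: frozenset[VariantKey]
    dead_pool: frozenset[VariantKey]
    kg_survived: frozenset[VariantKey]
    kg_gained: frozenset[VariantKey]
    kg_dead_pool: frozenset[VariantKey]


@dataclass
class EvolutionReport:
    """Per-transition fate sets over a time-ordered sample series."""

    samples: list[SampleVariantSet]
    transitions: list[Transition]

    def to_jsonable(self) -> dict:
        def keys(ks: Iterable[VariantKey]) -> list[str]:
            return sorted(f"{k.chrom}:{k.pos}:{k.ref}>{k.alt}" for k in ks)

        return {
            "samples": [
                {
                    "label": s.label,
                    "year": s.year,
                    "n_variants": len(s.variants),
                    "sdi": s.diversity.shannon if s.diversity else None,
                    "kg_count": len(s.key_gene_symbols()),
                }
                for s in self.samples
            ],
            "transitions": [
                {
                    "from": t.from_label,
                    "to": t.to_label,
                    "survived": keys(t.survived),
                    "gained": keys(t.gained),
                    "dead_pool": keys(t.dead_pool),
                    "kg_survived": keys(t.kg_survived),
                    "kg_gained": keys(t.kg_gained),
                    "kg_dead_pool": keys(t.kg_dead_pool),
                }
                for t in self.transitions
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_jsonable(), indent=2)


def classify_fates(series: Sequence[SampleVariantSet]) -> EvolutionReport:
    """Classify every variant's fate at each consecutive transition.

    At each transition the three sets are pairwise disjoint and satisfy
    survived | dead_pool = previous keys, survived | gained = next keys.
    Key-gene subsets use the ``is_key_gene`` flag of the variant in the
    sample where it is present (the earlier sample for survivors).
    """
    if len(series) < 2:
        raise ValidationError("fate classification needs at least two time-ordered samples")
    transitions: list[Transition] = []
    for a, b in zip(series, series[1:]):
        shared, only_a, only_b = pair_samples(a, b)

        def is_kg(k: VariantKey) -> bool:
            v = a.variants.get(k) or b.variants.get(k)
            return bool(v and v.is_key_gene)

        transitions.append(
            Transition(
                from_label=a.label,
                to_label=b.label,
                survived=shared,
                gained=only_b,
                dead_pool=only_a,
                kg_survived=frozenset(k for k in shared if is_kg(k)),
                kg_gained=frozenset(k for k in only_b if is_kg(k)),
                kg_dead_pool=frozenset(k for k in only_a if is_kg(k)),
            )
        )
    return EvolutionReport(samples=list(series), transitions=transitions)


# ---------------------------------------------------------------------------
# Key-gene matrix


@dataclass(frozen=True)
class MatrixCell:
    """One gene x sample cell: display values of the representative variant."""

    vaf_percent: int
    cn: int
    dp: int
    n_variants: int = 1


@dataclass
class KeyGeneMatrix:
    """Gene x sample matrix of (VAF%, CN, DP) cells; absent cells are NP."""

    genes: list[str]
    sample_labels: list[str]
    cells: dict[tuple[str, str], MatrixCell]
    classes: dict[str, str]

    def cell(self, gene: str, label: str) -> MatrixCell | None:
        return self.cells.get((gene, label))

    def genes_present(self, label: str) -> set[str]:
        return {g for (g, s) in self.cells if s == label}

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per gene, (VAF%, CN, DP) columns per sample."""
        rows = []
        for g in self.genes:
            row: dict[str, object] = {"GeneSymbol": g, "Func.Class": self.classes.get(g, "unknown")}
            for label in self.sample_labels:
                c = self.cells.get((g, label))
                row[f"{label} VAF%"] = c.vaf_percent if c else "NP"
                row[f"{label} CN"] = c.cn if c else "NP"
                row[f"{label} DP"] = c.dp if c else "NP"
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def build_key_gene_matrix(
    series: Sequence[SampleVariantSet],
    key_genes: set[str] | None = None,
    classes: Mapping[str, str] | None = None,
) -> KeyGeneMatrix:
    """One row per key gene mutated in at least one sample.

    When a gene carries several filtered variants in one sample, the cell
    shows the highest-abundance one (ties broken by lower position) and
    records the variant count.  ``key_genes=None`` accepts any gene already
    flagged ``is_key_gene``.
    """
    kg = {g.upper() for g in key_genes} if key_genes is not None else None
    classes = {g.upper(): c for g, c in (classes or {}).items()}
    cells: dict[tuple[str, str], MatrixCell] = {}
    gene_classes: dict[str, str] = {}
    for s in series:
        by_gene: dict[str, list[QuantifiedVariant]] = {}
        for v in s.variants.values():
            if not v.gene:
                continue
            g = v.gene.upper()
            eligible = (g in kg) if kg is not None else v.is_key_gene
            if eligible:
                by_gene.setdefault(g, []).append(v)
        for g, vs in by_gene.items():
            rep = max(vs, key=lambda v: (v.abundance, -v.key.pos))
            cells[(g, s.label)] = MatrixCell(
                vaf_percent=round_half_away(rep.vaf * 100),
                cn=rep.cn,
                dp=rep.dp,
                n_variants=len(vs),
            )
            cls = classes.get(g) or rep.functional_class
            gene_classes[g] = cls
    genes = sorted({g for (g, _) in cells})
    return KeyGeneMatrix(
        genes=genes,
        sample_labels=[s.label for s in series],
        cells=cells,
        classes={g: gene_classes.get(g, "unknown") for g in genes},
    )


def summarize_evolution(
    report: EvolutionReport,
    matrix: KeyGeneMatrix | None = None,
) -> dict:
    """Per-sample and per-transition summary of the evolution report.

    Gene-level key-gene fates (survived / gained / dead-pool gene symbols per
    transition, and genes surviving the whole series) are derived from each
    sample's key-gene symbol sets; variant-level counts come from the fate
    sets themselves.  ``matrix`` supplies functional classes for gene lists.
    """
    classes = matrix.classes if matrix else {}
    samples = [
        {
            "label": s.label,
            "year": s.year,
            "n_variants": len(s.variants),
            "sdi": s.diversity.shannon if s.diversity else None,
            "kg_count": len(s.key_gene_symbols()),
            "kg_genes": sorted(s.key_gene_symbols()),
        }
        for s in report.samples
    ]
    transitions = []
    for t, a, b in zip(report.transitions, report.samples, report.samples[1:]):
        ga, gb = a.key_gene_symbols(), b.key_gene_symbols()
        gained_genes = sorted(gb - ga)
        transitions.append(
            {
                "from": t.from_label,
                "to": t.to_label,
                "n_survived": len(t.survived),
                "n_gained": len(t.gained),
                "n_dead_pool": len(t.dead_pool),
                "n_kg_survived": len(t.kg_survived),
                "n_kg_gained": len(t.kg_gained),
                "n_kg_dead_pool": len(t.kg_dead_pool),
                "kg_genes_survived": sorted(ga & gb),
                "kg_genes_gained": gained_genes,
                "kg_genes_dead_pool": sorted(ga - gb),
                "kg_gained_classes": {g: classes.get(g, "unknown") for g in gained_genes},
            }
        )
    series_survivors = set(report.samples[0].key_gene_symbols())
    for s in report.samples[1:]:
        series_survivors &= s.key_gene_symbols()
    return {
        "samples": samples,
        "transitions": transitions,
        "kg_series_survivors": sorted(series_survivors),
    }
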