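"""End-to-end workflow: consensus -> quantify -> filter -> diversity -> tracking -> plots.

The run configuration (JSON or YAML) names the per-sample caller VCFs with
their dialects, the copy-number segments, the key-gene list and the analysis
settings.  :func:`run_pipeline` executes the whole sequence and writes, per
sample, the quantified and filtered variant tables, a diversity report and
the clonality plots; across samples it writes the evolution report, the
key-gene matrix and paired scatter plots.  Every table carries the config
hash as a provenance comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .consensus import ConsensusRule, build_consensus, split_snv_indel
from .diversity import WEIGHT_MODES
from .errors import ConfigurationError
from .quantify import (FilterConfig, apply_filters, quantify_variants,
                       summarize_by_chromosome, summarize_effect_types)
from .tracking import (SampleVariantSet, build_key_gene_matrix, classify_fates,
                       summarize_evolution)
from .variant_io import (read_caller_vcf, read_cn_segments, read_gene_list,
                         write_variant_table)
from .viz import (PlotSpec, plot_cn_stratified_density, plot_density_scatter,
                  plot_genomic_overview, plot_paired_scatter)

logger = logging.getLogger(__name__)


@dataclass
class SampleConfig:
    label: str
    vcfs: dict[str, str]            # caller tag -> VCF path
    dialects: dict[str, str]        # caller tag -> dialect tag
    segments: str | None = None
    year: int | None = None


@dataclass
class RunConfig:
    """Validated run configuration for the full pipeline."""

    samples: list[SampleConfig]
    key_genes: str | None = None
    gene_classes: str | None = None
    snv_rule: str = "majority"
    indel_rule: str = "intersection"
    caller_priority: list[str] | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    weight_mode: str = "abundance"
    default_cn: int = 2
    plot_format: str = "png"
    make_plots: bool = True

    def __post_init__(self) -> None:
        labels = [s.label for s in self.samples]
        if len(labels) != len(set(labels)):
            raise ConfigurationError(f"duplicate sample labels in manifest: {labels}")
        if self.weight_mode not in WEIGHT_MODES:
            raise ConfigurationError(f"weight_mode must be one of {WEIGHT_MODES}")
        ConsensusRule.parse(self.snv_rule)
        ConsensusRule.parse(self.indel_rule)

    def validate_paths(self) -> None:
        missing = []
        for s in self.samples:
            for caller, p in s.vcfs.items():
                if not Path(p).exists():
                    missing.append(f"{s.label}/{caller}: {p}")
                if caller not in s.dialects:
                    raise ConfigurationError(f"sample {s.label!r}: no dialect for caller {caller!r}")
            if s.segments and not Path(s.segments).exists():
                missing.append(f"{s.label}/segments: {s.segments}")
        for p in (self.key_genes, self.gene_classes):
            if p and not Path(p).exists():
                missing.append(p)
        if missing:
            raise ConfigurationError("missing input files:\n  " + "\n  ".join(missing))

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "samples": [vars(s) for s in self.samples],
            "key_genes": self.key_genes,
            "gene_classes": self.gene_classes,
            "snv_rule": self.snv_rule,
            "indel_rule": self.indel_rule,
            "caller_priority": self.caller_priority,
            "filters": vars(self.filters),
            "weight_mode": self.weight_mode,
            "default_cn": self.default_cn,
            "plot_format": self.plot_format,
            "make_plots": self.make_plots,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a JSON or YAML file."""
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw)
    return config_from_dict(data)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    samples = [
        SampleConfig(
            label=s["label"],
            vcfs=dict(s["vcfs"]),
            dialects=dict(s["dialects"]),
            segments=s.get("segments"),
            year=s.get("year"),
        )
        for s in data.get("samples", [])
    ]
    if not samples:
        raise ConfigurationError("config lists no samples")
    filt = data.get("filters", {})
    return RunConfig(
        samples=samples,
        key_genes=data.get("key_genes"),
        gene_classes=data.get("gene_classes"),
        snv_rule=data.get("snv_rule", "majority"),
        indel_rule=data.get("indel_rule", "intersection"),
        caller_priority=data.get("caller_priority"),
        filters=FilterConfig(
            min_vaf=float(filt.get("min_vaf", 0.10)),
            min_dp=int(filt.get("min_dp", 40)),
            max_dp=int(filt.get("max_dp", 250)),
        ),
        weight_mode=data.get("weight_mode", "abundance"),
        default_cn=int(data.get("default_cn", 2)),
        plot_format=data.get("plot_format", "png"),
        make_plots=bool(data.get("make_plots", True)),
    )


def config_from_manifest(manifest: dict[str, Any], base_dir: str | Path = ".",
                         **overrides: Any) -> RunConfig:
    """Build a RunConfig from a simulator bundle manifest (they compose directly).

    Manifest paths are relative to the bundle root; pass it as ``base_dir``.
    """
    base = Path(base_dir)
    samples = [
        {**s,
         "vcfs": {c: str(base / p) for c, p in s["vcfs"].items()},
         "segments": str(base / s["segments"]) if s.get("segments") else None}
        for s in manifest["samples"]
    ]
    data: dict[str, Any] = {
        "samples": samples,
        "key_genes": str(base / manifest["key_genes"]) if manifest.get("key_genes") else None,
        "filters": manifest.get("filters", {}),
    }
    data.update(overrides)
    return config_from_dict(data)


def read_gene_classes(path: str | Path) -> dict[str, str]:
    """gene<TAB>class table mapping symbols to OG/TSG/DR/VUS."""
    classes: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) >= 2:
            classes[parts[0].upper()] = parts[1]
    return classes


def process_sample(scfg: SampleConfig, cfg: RunConfig, kg: set[str],
                   classes: dict[str, str]) -> tuple[SampleVariantSet, list]:
    """One sample through read -> consensus -> quantify -> filter."""
    caller_sets = {
        caller: read_caller_vcf(path, dialect=scfg.dialects[caller], caller_id=caller)
        for caller, path in scfg.vcfs.items()
    }
    snv_sets = {c: split_snv_indel(recs)[0] for c, recs in caller_sets.items()}
    indel_sets = {c: split_snv_indel(recs)[1] for c, recs in caller_sets.items()}
    consensus = build_consensus(snv_sets, rule=cfg.snv_rule, priority=cfg.caller_priority)
    if any(indel_sets.values()):
        consensus += build_consensus(indel_sets, rule=cfg.indel_rule,
                                     priority=cfg.caller_priority)
    segments = read_cn_segments(scfg.segments) if scfg.segments else []
    quantified = quantify_variants(
        consensus, segments, default_cn=cfg.default_cn, key_genes=kg,
        functional_classes=classes,
    )
    filtered = apply_filters(quantified, cfg.filters)
    logger.info("%s: %d consensus variants, %d pass filters",
                scfg.label, len(quantified), len(filtered))
    svs = SampleVariantSet.from_variants(
        label=scfg.label, variants=filtered, year=scfg.year,
        weight_mode=cfg.weight_mode,
        prefilter_keys=[v.key for v in quantified],
    )
    return svs, quantified


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full workflow; returns a machine-readable run summary."""
    cfg.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    provenance = [f"clonaltrack {__version__}", f"config_hash {chash}",
                  f"snv_rule {cfg.snv_rule}", f"indel_rule {cfg.indel_rule}"]
    kg = read_gene_list(cfg.key_genes) if cfg.key_genes else set()
    classes = read_gene_classes(cfg.gene_classes) if cfg.gene_classes else {}

    series: list[SampleVariantSet] = []
    for scfg in cfg.samples:
        sdir = out / _slug(scfg.label)
        sdir.mkdir(exist_ok=True)
        svs, quantified = process_sample(scfg, cfg, kg, classes)
        write_variant_table(quantified, sdir / "consensus_variants.tsv", provenance)
        write_variant_table(svs.variants.values(), sdir / "filtered_variants.tsv", provenance)
        summarize_by_chromosome(svs.variants.values()).to_csv(
            sdir / "by_chromosome.tsv", sep="\t", index=False)
        summarize_effect_types(svs.variants.values()).to_csv(
            sdir / "effect_types.tsv", sep="\t", index=False)
        if svs.diversity:
            (sdir / "diversity.json").write_text(svs.diversity.to_json(), encoding="utf-8")
        if cfg.make_plots and svs.variants:
            fmt = cfg.plot_format
            plot_genomic_overview(svs, PlotSpec(out_path=sdir / f"genomic_overview.{fmt}", format=fmt))
            plot_density_scatter(svs, PlotSpec(out_path=sdir / f"density_scatter.{fmt}", format=fmt))
            if any(v.is_key_gene for v in svs.variants.values()):
                plot_density_scatter(svs, PlotSpec(out_path=sdir / f"density_scatter_kg.{fmt}", format=fmt),
                                     kg_only=True)
            plot_cn_stratified_density(svs, PlotSpec(out_path=sdir / f"cn_stratified.{fmt}", format=fmt))
        series.append(svs)

    summary: dict[str, Any] = {
        "version": __version__,
        "config_hash": chash,
        "samples": {s.label: len(s.variants) for s in series},
        "out_dir": str(out),
    }
    if len(series) >= 2:
        report = classify_fates(series)
        matrix = build_key_gene_matrix(series, key_genes=kg or None, classes=classes)
        evo = summarize_evolution(report, matrix)
        (out / "evolution.json").write_text(report.to_json(), encoding="utf-8")
        (out / "evolution_summary.json").write_text(json.dumps(evo, indent=2), encoding="utf-8")
        matrix.write_tsv(out / "key_gene_matrix.tsv")
        if cfg.make_plots:
            fmt = cfg.plot_format
            for a, b in zip(series, series[1:]):
                name = f"paired_{_slug(a.label)}_vs_{_slug(b.label)}.{fmt}"
                plot_paired_scatter(a, b, PlotSpec(out_path=out / name, format=fmt))
        summary["evolution"] = evo
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
    return summary


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label).strip("_").lower()
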