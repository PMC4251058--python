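"""Synthetic serial-study generator with known ground truth.

Simulates what the analysis consumes — per-caller somatic VCFs in their
native FORMAT dialects, copy-number segments, a key-gene list — for a
time-ordered series of tumor samples with planted clonal structure:

* Each clone is a :class:`ClonePlan`: a cell fraction, a variant count, the
  copy number of the region its variants occupy, and a fate vector saying in
  which samples the clone is present.  A variant's expected VAF is
  cell_fraction x multiplicity / CN (the inverse of the cell-frequency
  estimate used downstream).
* Read evidence is sampled per variant and sample: depth from a negative
  binomial around the configured mean (dispersion 1 collapses to Poisson,
  truncated to >= 1), variant reads binomially at the expected VAF.
* Caller disagreement is controlled per caller by a false-negative rate
  (true variants dropped from that caller's VCF) and a false-positive rate
  (spurious private calls injected).

Everything derives from a single seed, so a bundle is byte-reproducible.
The generator writes no read-level data (no FASTQ/BAM) and models no
sequencing-error or mapping artifacts: caller behavior is reduced to
set-level agreement plus shared read counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quantify import FilterConfig
from .variant_io import CALLER_DIALECTS

_NUCS = ("A", "C", "G", "T")

#: cancer-relevant symbols used for planted key-gene variants
SYNTH_KEY_GENES = (
    "NRAS", "KRAS", "TP53", "ATM", "BRAF", "ARID1A", "PARP1", "ERBB4",
    "JAK3", "FOXO3", "ESR1", "NTRK3", "POLE", "POLK", "PMS2", "ARHGAP26",
    "CD36", "BRCA1", "BRCA2", "MYC",
)

_EFFECTS = ("missense_variant", "synonymous_variant", "stop_gained",
            "splice_region_variant", "intron_variant")


@dataclass(frozen=True)
class ClonePlan:
    """One planted clone: its size, genomic context and per-sample fate."""

    label: str
    cell_fraction: float
    n_variants: int
    cn: int = 2
    multiplicity: int = 1
    fates: tuple[bool, ...] = (True, True, True)

    @property
    def expected_vaf(self) -> float:
        return self.cell_fraction * self.multiplicity / self.cn


@dataclass(frozen=True)
class CallerSpec:
    """A simulated caller: its dialect plus error rates."""

    caller_id: str
    dialect: str
    fn_rate: float = 0.0
    fp_rate: float = 0.0


def default_callers(fn_rate: float = 0.05, fp_rate: float = 0.02) -> tuple[CallerSpec, ...]:
    """The standard three-SNV-caller panel, one per supported dialect."""
    return tuple(
        CallerSpec(caller_id=c, dialect=d, fn_rate=fn_rate, fp_rate=fp_rate)
        for c, d in CALLER_DIALECTS.items()
    )


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults emulate a serial whole-exome design: three samples, 100x mean
    depth, three SNV callers with mild disagreement, and the standard
    selection filters as the target of the planted VAFs.
    """

    seed: int = 0
    n_samples: int = 3
    mean_depth: float = 100.0
    depth_dispersion: float = 1.0  # variance = dispersion * mean; 1 -> Poisson
    callers: tuple[CallerSpec, ...] = field(default_factory=default_callers)
    key_gene_fraction: float = 0.15
    filters: FilterConfig = field(default_factory=FilterConfig)
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1": 1_000_000, "2": 1_000_000})
    sample_labels: tuple[str, ...] | None = None
    sample_years: tuple[int, ...] | None = None

    def labels(self) -> list[str]:
        if self.sample_labels:
            return list(self.sample_labels)
        return [f"S{i + 1}" for i in range(self.n_samples)]

    def years(self) -> list[int]:
        if self.sample_years:
            return list(self.sample_years)
        return [2003 + 3 * i for i in range(self.n_samples)]


def default_clone_plans(n_samples: int = 3) -> list[ClonePlan]:
    """Founder + dying + arising clones, the canonical serial-relapse pattern.

    A founder clone persists through every sample; a subclone present from
    the start dies at the last selection event; a new subclone arises in the
    final sample — the pattern in which one oncogenic driver (an NRAS-like
    mutation) is replaced by another (a KRAS-like one).
    """
    persist = tuple(True for _ in range(n_samples))
    dying = tuple(i < n_samples - 1 for i in range(n_samples))
    arising = tuple(i == n_samples - 1 for i in range(n_samples))
    return [
        ClonePlan("founder", cell_fraction=1.0, n_variants=40, cn=2, fates=persist),
        ClonePlan("dying", cell_fraction=0.6, n_variants=30, cn=2, fates=dying),
        ClonePlan("arising", cell_fraction=0.7, n_variants=30, cn=2, fates=arising),
    ]


@dataclass
class TruthTable:
    """Planted ground truth: one row per variant plus per-sample observations."""

    variants: pd.DataFrame      # variant_id, clone, chrom, pos, ref, alt, gene, ...
    observations: pd.DataFrame  # variant_id, sample_index, trv, trr
    sample_labels: list[str]
    sample_years: list[int]
    key_genes: set[str]

    def expected_keys(self, sample_index: int) -> set[str]:
        mask = self.variants["fates"].str[sample_index] == "1"
        return set(self.variants.loc[mask, "key"])

    def expected_evolution(self) -> dict:
        """Ground-truth survived/gained/dead-pool key sets per transition."""
        out = []
        for i in range(len(self.sample_labels) - 1):
            a, b = self.expected_keys(i), self.expected_keys(i + 1)
            out.append({
                "from": self.sample_labels[i],
                "to": self.sample_labels[i + 1],
                "survived": sorted(a & b),
                "gained": sorted(b - a),
                "dead_pool": sorted(a - b),
            })
        return {"transitions": out}


def _draw_depth(rng: np.random.Generator, cfg: SimConfig, size: int) -> np.ndarray:
    m, d = cfg.mean_depth, cfg.depth_dispersion
    if d <= 1.0:
        depths = rng.poisson(m, size=size)
    else:
        # NB with variance d*m: size parameter r = m / (d - 1)
        r = m / (d - 1.0)
        p = r / (r + m)
        depths = rng.negative_binomial(r, p, size=size)
    return np.maximum(depths, 1)


def simulate_clonal_structure(plans: list[ClonePlan], cfg: SimConfig,
                              rng: np.random.Generator | None = None) -> TruthTable:
    """Plant variants for each clone and sample their read evidence.

    Each clone occupies its own contiguous genomic block (so copy-number
    segments are trivially non-overlapping); variant positions are uniform
    within the block.  For every sample in which a clone is present, each of
    its variants gets an observed (trv, trr) pair at the clone's expected VAF.
    """
    if not plans:
        raise ConfigurationError("no clone plans given")
    for p in plans:
        if len(p.fates) != cfg.n_samples:
            raise ConfigurationError(
                f"clone {p.label!r}: fate vector length {len(p.fates)} != n_samples {cfg.n_samples}"
            )
        if p.expected_vaf > 1.0:
            raise ConfigurationError(
                f"clone {p.label!r}: expected VAF {p.expected_vaf:.3f} > 1 "
                f"(cell_fraction x multiplicity / CN)"
            )
    rng = rng or np.random.default_rng(cfg.seed)
    chroms = list(cfg.chrom_lengths)

    rows = []
    vid = 0
    block_starts = {c: 10_000 for c in chroms}
    n_total = sum(p.n_variants for p in plans)
    n_kg = round(cfg.key_gene_fraction * n_total)
    kg_ids = set(rng.choice(n_total, size=min(n_kg, n_total), replace=False).tolist())
    kg_cycle = 0
    for ci, plan in enumerate(plans):
        chrom = chroms[ci % len(chroms)]
        span = plan.n_variants * 200
        start = block_starts[chrom]
        if start + span > cfg.chrom_lengths[chrom] - 50_000:
            raise ConfigurationError("clone blocks exceed the miniature genome; enlarge chrom_lengths")
        positions = np.sort(rng.choice(np.arange(start, start + span), size=plan.n_variants,
                                       replace=False))
        block_starts[chrom] = start + span + 1_000
        for pos in positions:
            ref, alt = rng.choice(_NUCS, size=2, replace=False)
            if vid in kg_ids:
                gene = SYNTH_KEY_GENES[kg_cycle % len(SYNTH_KEY_GENES)]
                kg_cycle += 1
                is_kg = True
            else:
                gene = f"GENE{vid:04d}"
                is_kg = False
            rows.append({
                "variant_id": vid,
                "clone": plan.label,
                "chrom": chrom,
                "pos": int(pos),
                "ref": str(ref),
                "alt": str(alt),
                "key": f"{chrom}:{int(pos)}:{ref}>{alt}",
                "gene": gene,
                "is_key_gene": is_kg,
                "effect": str(rng.choice(_EFFECTS)),
                "cn": plan.cn,
                "multiplicity": plan.multiplicity,
                "expected_vaf": plan.expected_vaf,
                "block_start": start,
                "block_end": start + span,
                "fates": "".join("1" if f else "0" for f in plan.fates),
            })
            vid += 1
    variants = pd.DataFrame(rows)

    obs_rows = []
    for si in range(cfg.n_samples):
        present = variants[variants["fates"].str[si] == "1"]
        depths = _draw_depth(rng, cfg, len(present))
        trvs = rng.binomial(depths, present["expected_vaf"].to_numpy())
        for (vid_, evaf), dp, trv in zip(present[["variant_id", "expected_vaf"]].to_numpy(),
                                         depths, trvs):
            obs_rows.append({"variant_id": int(vid_), "sample_index": si,
                             "trv": int(trv), "trr": int(dp - trv)})
    observations = pd.DataFrame(obs_rows)
    return TruthTable(
        variants=variants,
        observations=observations,
        sample_labels=cfg.labels(),
        sample_years=cfg.years(),
        key_genes=set(variants.loc[variants["is_key_gene"], "gene"]),
    )


# ---------------------------------------------------------------------------
# VCF / segment emission

_DIALECT_HEADERS = {
    "tier_counts": [
        '##FORMAT=<ID=AU,Number=2,Type=Integer,Description="Number of A alleles used in tiers 1,2">',
        '##FORMAT=<ID=CU,Number=2,Type=Integer,Description="Number of C alleles used in tiers 1,2">',
        '##FORMAT=<ID=GU,Number=2,Type=Integer,Description="Number of G alleles used in tiers 1,2">',
        '##FORMAT=<ID=TU,Number=2,Type=Integer,Description="Number of T alleles used in tiers 1,2">',
        '##FORMAT=<ID=TAR,Number=2,Type=Integer,Description="Reads supporting the reference, tiers 1,2">',
        '##FORMAT=<ID=TIR,Number=2,Type=Integer,Description="Reads supporting the indel, tiers 1,2">',
    ],
    "allele_depths": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths, REF first">',
    ],
    "ref_alt_depths": [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Depth of reference-supporting reads">',
        '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Depth of variant-supporting reads">',
        '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency">',
    ],
}


def _vcf_sample_fields(dialect: str, ref: str, alt: str, trv: int, trr: int) -> tuple[str, str]:
    """(FORMAT column, sample column) encoding (trv, trr) under a dialect."""
    if dialect == "tier_counts":
        if len(ref) == 1 and len(alt) == 1:
            counts = {n: 0 for n in _NUCS}
            counts[ref] = trr
            counts[alt] = trv
            return ("AU:CU:GU:TU",
                    ":".join(f"{counts[n]},{counts[n]}" for n in _NUCS))
        return "TAR:TIR", f"{trr},{trr}:{trv},{trv}"
    if dialect == "allele_depths":
        return "GT:AD", f"0/1:{trr},{trv}"
    if dialect == "ref_alt_depths":
        freq = f"{100 * trv / max(trv + trr, 1):.2f}%"
        return "GT:RD:AD:FREQ", f"0/1:{trr}:{trv}:{freq}"
    raise ConfigurationError(f"no VCF encoding for dialect {dialect!r}")


def emit_caller_vcfs(
    truth: TruthTable,
    cfg: SimConfig,
    out_dir: str | Path,
    sample_index: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Write one VCF 4.2 per configured caller for one sample.

    All callers encode the same planted (trv, trr) evidence in their own
    dialect.  Per-caller dropout (false negatives) removes true calls;
    spurious private calls (false positives) are injected at distinct
    positions outside the clone blocks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = rng or np.random.default_rng(cfg.seed + 7919 * (sample_index + 1))

    obs = truth.observations
    obs_s = obs[obs["sample_index"] == sample_index].set_index("variant_id")
    present = truth.variants[truth.variants["variant_id"].isin(obs_s.index)]

    paths: dict[str, Path] = {}
    fp_base = max(cfg.chrom_lengths.values()) - 40_000
    for caller_n, caller in enumerate(cfg.callers):
        keep = rng.random(len(present)) >= caller.fn_rate
        rows = []
        for keep_it, (_, v) in zip(keep, present.iterrows()):
            if not keep_it:
                continue
            o = obs_s.loc[v["variant_id"]]
            fmt, val = _vcf_sample_fields(caller.dialect, v["ref"], v["alt"],
                                          int(o["trv"]), int(o["trr"]))
            ann = f"{v['alt']}|{v['effect']}|MODERATE|{v['gene']}|g{v['variant_id']}"
            rows.append((v["chrom"], int(v["pos"]), v["ref"], v["alt"],
                         f"SOMATIC;ANN={ann}", fmt, val))
        n_fp = int(rng.poisson(caller.fp_rate * max(len(present), 1)))
        for j in range(n_fp):
            chrom = list(cfg.chrom_lengths)[-1]
            pos = fp_base + 100 * (caller_n * 200 + j) + int(rng.integers(0, 50))
            ref, alt = rng.choice(_NUCS, size=2, replace=False)
            dp = int(_draw_depth(rng, cfg, 1)[0])
            trv = int(rng.binomial(dp, rng.uniform(0.05, 0.4)))
            fmt, val = _vcf_sample_fields(caller.dialect, str(ref), str(alt), trv, dp - trv)
            ann = f"{alt}|{str(rng.choice(_EFFECTS))}|MODERATE|FPGENE{j:03d}|fp"
            rows.append((chrom, pos, str(ref), str(alt), f"SOMATIC;ANN={ann}", fmt, val))

        rows.sort(key=lambda r: (r[0], r[1], r[3]))
        path = out_dir / f"{caller.caller_id}.vcf"
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=clonaltrack-synthetic caller={caller.caller_id}\n")
            fh.write('##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic mutation">\n')
            fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotation">\n')
            for line in _DIALECT_HEADERS[caller.dialect]:
                fh.write(line + "\n")
            for chrom, length in cfg.chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n")
            for chrom, pos, ref, alt, info, fmt, val in rows:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\t{fmt}\t{val}\n")
        paths[caller.caller_id] = path
    return paths


def emit_cn_segments(truth: TruthTable, out_path: str | Path) -> Path:
    """Write non-overlapping CN segments covering every planted variant."""
    out_path = Path(out_path)
    blocks = (
        truth.variants[["chrom", "block_start", "block_end", "cn"]]
        .drop_duplicates()
        .sort_values(["chrom", "block_start"])
    )
    with out_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("chrom\tstart\tend\tcn\n")
        for _, b in blocks.iterrows():
            fh.write(f"{b['chrom']}\t{int(b['block_start'])}\t{int(b['block_end'])}\t{int(b['cn'])}\n")
    return out_path


def simulate_serial_study(
    plans: list[ClonePlan] | None = None,
    cfg: SimConfig | None = None,
    out_dir: str | Path = "synthetic_study",
) -> dict:
    """Generate a complete study bundle on disk and return its manifest.

    Layout: one directory per sample with per-caller VCFs and a segments
    TSV; a key-gene list; the truth table and ground-truth evolution report
    as JSON; and a ``manifest.json`` tying it together with the seed.
    """
    cfg = cfg or SimConfig()
    if cfg.n_samples < 2:
        raise ConfigurationError("a serial study needs at least two samples")
    plans = plans if plans is not None else default_clone_plans(cfg.n_samples)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_clonal_structure(plans, cfg, rng)

    samples = []
    for si, label in enumerate(truth.sample_labels):
        sdir = out_dir / f"sample_{si + 1:02d}"
        vcfs = emit_caller_vcfs(truth, cfg, sdir, sample_index=si, rng=rng)
        seg_path = emit_cn_segments(truth, sdir / "segments.tsv")
        # manifest paths are relative to the bundle root, so a bundle is
        # byte-reproducible from the seed regardless of where it is written
        samples.append({
            "label": label,
            "year": truth.sample_years[si],
            "vcfs": {c: str(p.relative_to(out_dir)) for c, p in vcfs.items()},
            "dialects": {c.caller_id: c.dialect for c in cfg.callers},
            "segments": str(seg_path.relative_to(out_dir)),
        })

    kg_path = out_dir / "key_genes.txt"
    kg_path.write_text("".join(f"{g}\n" for g in sorted(truth.key_genes)), encoding="utf-8")

    kg_rel = kg_path.relative_to(out_dir)

    truth_path = out_dir / "truth.json"
    truth_payload = {
        "variants": truth.variants.to_dict(orient="records"),
        "observations": truth.observations.to_dict(orient="records"),
        "evolution": truth.expected_evolution(),
        "clone_plans": [asdict(p) for p in plans],
    }
    truth_path.write_text(json.dumps(truth_payload, indent=1), encoding="utf-8")

    manifest = {
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "mean_depth": cfg.mean_depth,
        "samples": samples,
        "key_genes": str(kg_rel),
        "truth": str(truth_path.relative_to(out_dir)),
        "filters": asdict(cfg.filters),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
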