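"""Per-variant clonality quantities and the standard selection filters.

For each consensus variant: VAF = TRV/(TRV+TRR), DP = TRV+TRR, CN from the
segment containing it, abundance = VAF x DP x CN, and the mutated-cell
fraction min(1, VAF x CN).  Filters keep VAF >= 10% and 40 <= DP <= 250.
"""

from pathlib import Path

from clonaltrack import (SimConfig, apply_filters, build_consensus,
                         quantify_variants, read_caller_vcf, read_cn_segments,
                         read_gene_list, simulate_serial_study)

out = Path("scratch/example_quantify")
manifest = simulate_serial_study(cfg=SimConfig(seed=11), out_dir=out)
s1 = manifest["samples"][0]

caller_sets = {c: read_caller_vcf(out / p, s1["dialects"][c], caller_id=c)
               for c, p in s1["vcfs"].items()}
consensus = build_consensus(caller_sets, rule="majority")
segments = read_cn_segments(out / s1["segments"])
key_genes = read_gene_list(out / manifest["key_genes"])

quantified = quantify_variants(consensus, segments, key_genes=key_genes)
filtered = apply_filters(quantified)
print(f"{len(quantified)} consensus variants, {len(filtered)} pass filters")

v = max(filtered, key=lambda v: v.abundance)
print(f"highest-abundance variant: {v.key.chrom}:{v.key.pos} {v.key.ref}>{v.key.alt}"
      f" gene={v.gene or '-'}")
print(f"  VAF {v.vaf:.3f}  DP {v.dp}  CN {v.cn}  abundance {v.abundance:.1f}"
      f"  cell frequency {v.cell_frequency:.2f}")
# A clonal heterozygous diploid variant has VAF ~0.5 and cell frequency ~1:
# essentially every tumor cell carries it.
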