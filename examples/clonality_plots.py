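"""Render the four clonality plot families for one synthetic sample.

Density peaks over VAF suggest dominant clones and subclones; the
CN-stratified view separates the picture by copy-number state.
"""

from pathlib import Path

from clonaltrack import SimConfig, config_from_manifest, simulate_serial_study
from clonaltrack.pipeline import process_sample, read_gene_classes
from clonaltrack.variant_io import read_gene_list
from clonaltrack.viz import (PlotSpec, plot_cn_stratified_density,
                             plot_density_scatter, plot_genomic_overview,
                             plot_paired_scatter)

out = Path("scratch/example_plots")
manifest = simulate_serial_study(cfg=SimConfig(seed=5), out_dir=out / "bundle")
cfg = config_from_manifest(manifest, base_dir=out / "bundle")
kg = read_gene_list(cfg.key_genes)

series = [process_sample(s, cfg, kg, {})[0] for s in cfg.samples]
s1, s2 = series[0], series[1]

paths = [
    plot_genomic_overview(s1, PlotSpec(out_path=out / "genomic_overview.png")),
    plot_density_scatter(s1, PlotSpec(out_path=out / "density_scatter.png")),
    plot_cn_stratified_density(s1, PlotSpec(out_path=out / "cn_stratified.png")),
    plot_paired_scatter(s1, s2, PlotSpec(out_path=out / "paired.png")),
]
for p in paths:
    print("wrote", p)
# In the density panel, each local maximum marks a cluster of variants at a
# shared VAF — a candidate (sub)clone; in the paired scatter, points on the
# axes are variants private to one time point.
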