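"""Static clonality visualizations.

Four plot families give complementary views of a sample's mutational
landscape:

* genomic overview — every variant on a concatenated chromosome axis
  (1..22, X, Y sized by bp) against VAF%, colored by depth;
* paired scatter — VAF% of one sample against another, with shared variants
  in a common color and sample-private variants on the axes;
* density + scatter — a weighted Gaussian kernel density over VAF% (peaks
  suggest dominant clones and subclones) above a scatter of VAF% versus
  CN x depth, with key genes labeled;
* CN-stratified density — the same view separated into one density/scatter
  layer per copy-number state, scatter y = depth (the SciClone-style view).

All rendering is deterministic: no unseeded jitter, fixed geometry, greedy
(not randomized) label placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import gaussian_kde

from .errors import ValidationError
from .genome import GRCH37_LENGTHS, chrom_sort_key, cumulative_offsets
from .tracking import SampleVariantSet, pair_samples

logger = logging.getLogger(__name__)

KDE_GRID_POINTS = 512
KDE_WEIGHT_MODES = ("cn", "cell_frequency", "uniform")


@dataclass
class PlotSpec:
    """Rendering options shared by the plot families.

    ``bandwidth`` is a Gaussian-KDE bandwidth factor (scales Silverman's
    rule); None keeps plain Silverman.  ``kde_weight_mode`` selects how the
    density is adjusted per variant: ``cn`` weights each variant by its copy
    number, ``cell_frequency`` by its estimated mutated-cell fraction,
    ``uniform`` not at all.
    """

    out_path: str | Path = "plot.png"
    format: str = "png"
    figsize: tuple[float, float] = (8.0, 6.0)
    dpi: int = 120
    title: str = ""
    bandwidth: float | None = None
    kde_weight_mode: str = "cn"
    vaf_range: tuple[float, float] = (0.0, 100.0)
    colors: dict[str, str] = field(default_factory=dict)

    def resolve_path(self) -> Path:
        p = Path(self.out_path)
        if p.suffix.lstrip(".").lower() != self.format.lower():
            p = p.with_suffix(f".{self.format}")
        return p


def _bw_method(spec: PlotSpec):
    if spec.bandwidth is None:
        return "silverman"
    return spec.bandwidth


def vaf_kde(
    vaf_percent: np.ndarray,
    weights: np.ndarray | None = None,
    bandwidth: float | str | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Gaussian KDE of VAF% on a fixed 512-point grid over [0, 100].

    Returns (grid, density).  ``bandwidth`` follows scipy's ``bw_method``
    (default Silverman's rule).  Needs >= 2 distinct values.
    """
    x = np.asarray(vaf_percent, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 100.0, KDE_GRID_POINTS)
    if x.size < 2 or np.allclose(x, x[0]):
        raise ValidationError("KDE needs at least two distinct VAF values")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    kde = gaussian_kde(x, bw_method=bandwidth or "silverman", weights=weights)
    return grid, kde(grid)


def find_density_peaks(grid: np.ndarray, density: np.ndarray) -> np.ndarray:
    """VAF% locations of local density maxima, highest density first."""
    d = np.asarray(density)
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    idx = np.flatnonzero(interior) + 1
    idx = idx[np.argsort(d[idx])[::-1]]
    return np.asarray(grid)[idx]


def _kde_weights(sample: SampleVariantSet, mode: str) -> np.ndarray | None:
    if mode not in KDE_WEIGHT_MODES:
        raise ValidationError(f"kde_weight_mode must be one of {KDE_WEIGHT_MODES}")
    if mode == "uniform":
        return None
    vs = sample.variants.values()
    if mode == "cn":
        return np.array([v.cn for v in vs], dtype=float)
    return np.array([v.cell_frequency for v in vs], dtype=float)


def _finalize(fig, spec: PlotSpec) -> Path:
    path = spec.resolve_path()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=spec.dpi, format=spec.format)
    plt.close(fig)
    return path


def _label_points(ax, xs, ys, labels, min_dy: float) -> None:
    """Greedy non-overlap gene labeling: displace labels upward by y order."""
    order = np.argsort(ys)
    last_y = -np.inf
    for i in order:
        y = max(ys[i], last_y + min_dy)
        last_y = y
        ax.annotate(labels[i], (xs[i], ys[i]), xytext=(xs[i] + 1.0, y),
                    fontsize=7, alpha=0.9)


# ---------------------------------------------------------------------------
# Plot families


def plot_genomic_overview(
    sample: SampleVariantSet,
    spec: PlotSpec,
    chrom_lengths: dict[str, int] | None = None,
) -> Path:
    """Genome-wide variant overview: cumulative position vs VAF%, color = depth."""
    lengths = chrom_lengths or GRCH37_LENGTHS
    offsets = cumulative_offsets(lengths)
    xs, ys, depths = [], [], []
    for v in sample.variants.values():
        if v.key.chrom not in offsets:
            raise ValidationError(
                f"chromosome {v.key.chrom!r} of {v.key} missing from the length table"
            )
        xs.append(offsets[v.key.chrom] + v.key.pos)
        ys.append(v.vaf * 100)
        depths.append(v.dp)

    fig, ax = plt.subplots(figsize=spec.figsize)
    chroms = sorted(lengths, key=chrom_sort_key)
    total = sum(lengths.values())
    for i, c in enumerate(chroms):
        if i % 2:
            ax.axvspan(offsets[c], offsets[c] + lengths[c], color="0.92", zorder=0)
    if xs:
        sc = ax.scatter(xs, ys, c=depths, s=12, cmap="viridis", alpha=0.8, zorder=2)
        fig.colorbar(sc, ax=ax, label="depth (DP)")
    ax.set_xlim(0, total)
    ax.set_ylim(*spec.vaf_range)
    ax.set_xticks([offsets[c] + lengths[c] / 2 for c in chroms])
    ax.set_xticklabels(chroms, fontsize=7)
    ax.set_xlabel("chromosome (sized by bp)")
    ax.set_ylabel("VAF (%)")
    ax.set_title(spec.title or f"Genomic overview — {sample.label}")
    return _finalize(fig, spec)


def plot_paired_scatter(a: SampleVariantSet, b: SampleVariantSet, spec: PlotSpec) -> Path:
    """VAF% of sample a vs sample b; private variants sit on the axes."""
    shared, only_a, only_b = pair_samples(a, b)
    col = {"shared": "tab:blue", "a": "tab:green", "b": "tab:red", **spec.colors}
    fig, ax = plt.subplots(figsize=spec.figsize)
    if shared:
        pts = [(a.variants[k].vaf * 100, b.variants[k].vaf * 100) for k in sorted(shared, key=lambda k: k.sort_key())]
        ax.scatter(*zip(*pts), c=col["shared"], alpha=0.45, s=16,
                   label=f"shared (n={len(shared)})")
    if only_a:
        pts = [(a.variants[k].vaf * 100, 0.0) for k in sorted(only_a, key=lambda k: k.sort_key())]
        ax.scatter(*zip(*pts), c=col["a"], alpha=0.45, s=16,
                   label=f"{a.label} only (n={len(only_a)})")
    if only_b:
        pts = [(0.0, b.variants[k].vaf * 100) for k in sorted(only_b, key=lambda k: k.sort_key())]
        ax.scatter(*zip(*pts), c=col["b"], alpha=0.45, s=16,
                   label=f"{b.label} only (n={len(only_b)})")
    ax.set_xlim(*spec.vaf_range)
    ax.set_ylim(*spec.vaf_range)
    ax.set_xlabel(f"{a.label} VAF (%)")
    ax.set_ylabel(f"{b.label} VAF (%)")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title(spec.title or f"{a.label} vs {b.label}")
    return _finalize(fig, spec)


def plot_density_scatter(
    sample: SampleVariantSet, spec: PlotSpec, kg_only: bool = False
) -> Path:
    """Clonality view: weighted VAF% density above a VAF% vs CN x DP scatter.

    Density peaks suggest dominant clones and subclones.  Key-gene points are
    annotated with their gene symbol; ``kg_only`` restricts the whole plot to
    key-gene variants.
    """
    vs = list(sample.variants.values())
    if kg_only:
        vs = [v for v in vs if v.is_key_gene]
    fig, (ax_d, ax_s) = plt.subplots(
        2, 1, figsize=spec.figsize, sharex=True,
        gridspec_kw={"height_ratios": [1, 1.4]},
    )
    vafs = np.array([v.vaf * 100 for v in vs])
    if vs and len(vs) >= 2 and not np.allclose(vafs, vafs[0]):
        sub = SampleVariantSet(label=sample.label, year=sample.year,
                               variants={v.key: v for v in vs})
        grid, dens = vaf_kde(vafs, weights=_kde_weights(sub, spec.kde_weight_mode),
                             bandwidth=_bw_method(spec))
        ax_d.plot(grid, dens, color="tab:blue")
        ax_d.fill_between(grid, dens, alpha=0.25, color="tab:blue")
    else:
        logger.warning("sample %s: <2 distinct VAFs, skipping density curve", sample.label)
    ax_d.set_ylabel(f"density ({spec.kde_weight_mode}-weighted)")

    ys = np.array([v.cn * v.dp for v in vs], dtype=float)
    if vs:
        ax_s.scatter(vafs, ys, alpha=0.45, s=18, color="tab:blue")
        kg_idx = [i for i, v in enumerate(vs) if v.is_key_gene and v.gene]
        if kg_idx:
            ax_s.scatter(vafs[kg_idx], ys[kg_idx], s=26, color="tab:orange", zorder=3)
            _label_points(ax_s, vafs[kg_idx], ys[kg_idx],
                          [vs[i].gene for i in kg_idx],
                          min_dy=0.04 * (ys.max() - ys.min() + 1))
    ax_s.set_xlim(*spec.vaf_range)
    ax_s.set_xlabel("VAF (%)")
    ax_s.set_ylabel("CN x DP")
    ax_d.set_title(spec.title or f"Clonality — {sample.label}"
                   + (" (key genes)" if kg_only else ""))
    return _finalize(fig, spec)


def plot_cn_stratified_density(sample: SampleVariantSet, spec: PlotSpec) -> Path:
    """Per-copy-number density and scatter layers; scatter y = depth."""
    vs = list(sample.variants.values())
    cns = sorted({v.cn for v in vs})
    cmap = plt.get_cmap("tab10")
    fig, (ax_d, ax_s) = plt.subplots(
        2, 1, figsize=spec.figsize, sharex=True,
        gridspec_kw={"height_ratios": [1, 1.4]},
    )
    for i, cn in enumerate(cns):
        layer = [v for v in vs if v.cn == cn]
        vafs = np.array([v.vaf * 100 for v in layer])
        color = cmap(i % 10)
        if len(layer) >= 2 and not np.allclose(vafs, vafs[0]):
            grid, dens = vaf_kde(vafs, bandwidth=_bw_method(spec))
            ax_d.plot(grid, dens, color=color)
        ax_s.scatter(vafs, [v.dp for v in layer], alpha=0.5, s=18, color=color,
                     label=f"CN={cn} (n={len(layer)})")
    ax_s.set_xlim(*spec.vaf_range)
    ax_s.set_xlabel("VAF (%)")
    ax_s.set_ylabel("depth (DP)")
    ax_d.set_ylabel("density")
    if cns:
        ax_s.legend(loc="upper right", fontsize=8)
    ax_d.set_title(spec.title or f"CN-stratified clonality — {sample.label}")
    return _finalize(fig, spec)
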