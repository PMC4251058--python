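# Methods

## Variant identity and dialect parsing

A variant's identity is its normalized genomic key (chrom, pos, ref, alt):
`chr` prefixes stripped, alleles uppercased, and indel representations
reduced by right-trimming then left-trimming shared ref/alt bases down to a
single anchor base (position adjusted on left trims). Normalization is
idempotent, so the same indel emitted with different padding by different
callers compares equal. No fuzzy position matching is done: breakpoint-
tolerant indel merging would risk silent mismerges, and exact-key matching
keeps consensus auditable.

Read support is extracted per caller dialect from the tumor sample column
(the column named `TUMOR` if present, else the last one):

| dialect | variant reads (TRV) | reference reads (TRR) |
|---|---|---|
| `tier_counts` | tier-1 count of the ALT base (`{ALT}U`); `TIR` tier 1 for indels | tier-1 count of the REF base; `TAR` tier 1 |
| `allele_depths` | `AD[i+1]` for the i-th ALT | `AD[0]` |
| `ref_alt_depths` | `AD` | `RD` |

Tier-1 counts are the high-confidence subset in the tier-count convention;
tier 2 is ignored. Only rows whose FILTER is PASS or `.` are read — the
caller itself rejected the rest, and downstream VAF/DP filtering assumes
caller-accepted evidence. Multi-allelic rows split into one record per ALT.
Dialects are declarative entries in a registry, so a new caller convention
is a data addition, not a code change.

## Consensus

Records group by normalized key; a key is emitted when the number of
distinct supporting callers meets the rule's threshold: intersection (all
n), majority (⌊n/2⌋+1, i.e. 2 of 3), union (1), or an explicit k. SNVs and
indels can use different rules — the defaults are majority for SNVs (typical
three-caller panels) and intersection for indels (typical two-caller
panels). Which rule a study should use is a judgment call; all are
supported and the choice is echoed in logs and table headers.

One caller's record must supply the downstream read counts. The evidence
record is chosen by a configurable caller priority, defaulting to the order
the callers appear in the input mapping; this is a determinism device, not a
claim that any caller's counts are more accurate.

## Quantification

For the evidence record: VAF = TRV/(TRV+TRR) and DP = TRV+TRR. DP is
deliberately not the VCF `DP` FORMAT field, so the VAF and DP filters refer
to the same reads. CN comes from the unique validated (non-overlapping,
1-based inclusive) segment containing the position; positions outside all
segments get CN = 2 with `cn_imputed=True` — autosomal diploid is the
neutral assumption for uncovered regions, and imputed variants remain
countable. Abundance = VAF·DP·CN is the molecular-species weight used for
diversity. The mutated-cell fraction is min(1, VAF·CN/m) with multiplicity
m = 1 by default (one mutated copy per cell — the conservative reading;
m is overridable but never inferred).

Selection keeps VAF ≥ 0.10 and 40 ≤ DP ≤ 250, all bounds inclusive. VAF is
a fraction internally; percent appears only at the presentation layer,
rounded half-away-from-zero for display cells. Filters are applied to the
tumor evidence record only.

Gene and effect come from the `ANN=` INFO field's first (most severe) entry,
with plain `GENE=`/`EFFECT=` keys as fallback; functional classes
(OG/TSG/DR/VUS) come from a user-supplied gene→class table — no attempt is
made to derive driver status computationally.

## Diversity

Species weights w(i) (abundance by default; cell frequency or uniform for
sensitivity analysis) are normalized to p(i) = w(i)/Σw after dropping
zero-weight species (the 0·ln 0 convention). SDI = −Σ p ln p in nats —
natural log, no base option. Simpson's index 1 − Σ p² is reported alongside,
together with the ceiling ln N and evenness SDI/ln N (undefined for N < 2).
Diversity is computed over variants, not over clustered clones: no clone
inference happens anywhere in the package, and the per-variant reading keeps
the statistic reproducible from the variant table alone.

## Serial tracking

Fates are classified at variant-key level per consecutive sample pair:
survived = present in both, gained = new, dead pool = lost. Presence means
membership in the *post-filter* set (a pre-filter key set is retained so
"filtered out" is distinguishable from "not called"). The key-gene matrix
aggregates to gene level: a gene is present when any of its filtered
variants is, and its cell shows the highest-abundance variant's (VAF %, CN,
DP) — ties broken by lower position — with the variant count recorded when
a gene has several.

## Visualization

KDE uses a Gaussian kernel with Silverman's rule-of-thumb bandwidth
(overridable as a scale factor) evaluated on a 512-point grid over
[0, 100] % VAF. The "density adjusted by copy number" panel weights each
variant by CN (normalized); weighting by cell frequency is offered as an
alternative reading, since either interpretation of a CN adjustment is
defensible. Scatter y-axes: CN × DP in the combined view, DP in the
CN-stratified view. Rendering is deterministic — fixed geometry, no jitter,
greedy upward label displacement for key-gene annotations — so identical
inputs give byte-identical images under fixed library versions.

## Synthetic studies

The generator plants clones, not reads. Each clone has a cell fraction f,
copy number c and multiplicity m; its variants' expected VAF is f·m/c, the
inverse of the cell-frequency estimate. Per sample and variant, depth is
drawn negative-binomially around the configured mean (dispersion 1 collapses
to Poisson; truncated to ≥ 1) and TRV binomially at the expected VAF. All
callers encode the same counts in their own dialect; disagreement is modeled
only as per-caller false-negative dropout and false-positive injection.
Clones occupy disjoint genomic blocks on a miniature two-chromosome genome,
making CN segments non-overlapping by construction. Everything flows from
one seed; manifests store bundle-relative paths so a seed reproduces a
bundle byte-for-byte anywhere.

Defaults are the study conditions emulated throughout: three samples, 100×
mean depth, three SNV callers (FN 0.05 / FP 0.02 where disagreement is
wanted, zero where exact recovery is being demonstrated), and a
founder/dying/arising clone pattern (cell fractions 1.0/0.6/0.7, 40/30/30
variants) mirroring a driver-replacement trajectory. What the generator does
*not* model — mapping artifacts, sequencing error, caller-specific biases
correlated with sequence context, subclonal copy-number change — bounds what
passing tests show: recovery results demonstrate the bookkeeping and
arithmetic are correct under the stated sampling model, not robustness to
real-data artifacts.

Binomial sampling sets the floor on VAF recovery: at depth n the expected
absolute deviation of observed from planted VAF is √(2/π)·√(p(1−p)/n)
(≈ 0.039 at p = 0.4, n = 100). Tests therefore check unbiasedness and
noise at this theoretical scale rather than a flat constant.

## The bundled serial case

`datasets.serial_study()` reconstructs a published three-sample myeloma
key-gene matrix (15 genes × presentation/relapse-1/relapse-2, integer VAF %,
CN, DP, NP for absent). Read counts are back-computed as
TRV = round(VAF·DP), the integer split whose recomputed VAF rounds back to
the printed percent (verified for every cell). Genomic loci are
deterministic placeholders on each gene's true chromosome — the published
matrix prints no coordinates — and identical across samples so tracking sees
survival rather than three unrelated mutations. Whole-sample totals
(N = 132/256/196, SDI = 4.67/5.30/5.11) are carried as metadata; the full
variant lists behind them were not published, so the whole-sample SDIs can
only be bounded (SDI ≤ ln N), not recomputed.

## Problem sizes and tolerances

The test suite and the acceptance script use: 100-variant universes × 200
random triples for the consensus oracle; 100-variant three-sample bundles at
depth 100 for end-to-end recovery (exact fate and VAF equality required);
k = 40 equal-abundance species for diversity recovery (|SDI − ln k| < 0.05);
two 100-variant clusters at 20 % and 45 % VAF, depth 100, for KDE peak
recovery (within 2 VAF points). Numerical tolerances: entropy closed forms
to 1e-9; abundance/VAF consistency to 1e-9; probability normalization to
1e-12.

## Known limitations

No tumor purity estimation, no multiplicity inference, no germline
subtraction (inputs are assumed somatic), no structural variants or gVCF,
no clone clustering or phylogeny reconstruction, and no interactive
exploration — the plots are static renderings of the standard clonality
views.
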