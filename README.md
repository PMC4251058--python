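# clonaltrack

Consensus somatic-variant selection and tumor clonal-evolution analysis for
serial whole-exome studies.

Tumors are mixtures of clones that expand, shrink and die under selection
events such as chemotherapy. Given somatic VCFs from several variant callers
for each time-point sample of one patient, plus copy-number segments and a
list of cancer-relevant "key genes", `clonaltrack`:

1. **parses caller-specific VCF dialects** (tier-count per-nucleotide,
   REF-first allele-depth array, separate ref/alt depth fields) into uniform
   read-count records;
2. **takes a set-based consensus** (intersection, majority, union or k-of-n)
   over the callers, keeping every caller's evidence;
3. **quantifies each variant**: VAF = TRV/(TRV+TRR), DP = TRV+TRR, copy
   number CN from the containing segment, abundance = VAF·DP·CN, and the
   mutated-cell fraction min(1, VAF·CN/m); then filters (VAF ≥ 10 %,
   40 ≤ DP ≤ 250);
4. **measures clonal diversity** per sample with the Shannon index
   SDI = −Σᵢ p(i) ln p(i) over abundance-normalized species weights
   (Simpson's 1 − Σ p² as companion);
5. **tracks variant fates** across the time-ordered samples — survived,
   gained, or in the transition's *dead pool* (present before, absent after)
   — and builds the key-gene VAF/CN/DP matrix;
6. **renders clonality plots**: genome-wide overview, paired-sample VAF
   scatter, Gaussian-KDE density + scatter (peaks suggest clones), and a
   copy-number-stratified density view.

A fully seeded synthetic-study generator (`clonaltrack.synthetic`) emits
multi-caller VCF bundles with planted clonal structure and ground truth, so
the whole pipeline is testable without patient data. A reconstruction of a
published three-sample serial multiple-myeloma case is bundled in
`clonaltrack.datasets`.

Intended users: bioinformaticians analyzing serial tumor biopsies, and
method developers who need a small, fully-testable reference implementation
of consensus calling plus clonality bookkeeping.

## Worked example

Track the bundled serial myeloma case (presentation 2003, relapses 2010 and
2014):

```sh
python examples/serial_tracking.py
```

prints (abridged):

```
Presentation (2003): 6 key genes mutated: ARHGAP26, ARID1A, ATM, ERBB4, NRAS, PARP1
Relapse #1   (2010): 12 key genes mutated: ...
Relapse #2   (2014): 7 key genes mutated: ...

Presentation -> Relapse #1
  gained:    ESR1, FOXO3, JAK3, NTRK3, PMS2P3, POLK
  dead pool: -
Relapse #1 -> Relapse #2
  gained:    CD36, KRAS, POLE
  dead pool: ATM, ESR1, FOXO3, JAK3, NRAS, NTRK3, PMS2P3, POLK

survive the whole series: ARHGAP26, ARID1A, ERBB4, PARP1
```

Every key-gene mutation survives the first selection event; the second one
kills eight key-gene mutations — including the founder NRAS driver (VAF 44 %
at presentation) — while a KRAS driver arises in its place, keeping the
RAS/MAPK proliferation signal alive. Four mutations survive the whole
series.

The other examples (`examples/*.py`) each demonstrate one capability:
simulation, consensus rules, quantification + filtering, diversity, plots.

End-to-end from the shell:

```sh
clonaltrack simulate --out bundle --seed 42
clonaltrack run --manifest bundle/manifest.json --out results_dir
```

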