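"""Consensus variant selection across three caller VCF dialects.

Reads one synthetic sample's three caller VCFs (tier-count, allele-depth and
ref/alt-depth conventions) and compares consensus rules.
"""

from pathlib import Path

from clonaltrack import SimConfig, build_consensus, read_caller_vcf, simulate_serial_study
from clonaltrack.synthetic import default_callers

out = Path("scratch/example_consensus")
# mild disagreement: each caller misses 10% of true calls and adds spurious ones
cfg = SimConfig(seed=7, callers=default_callers(fn_rate=0.10, fp_rate=0.05))
manifest = simulate_serial_study(cfg=cfg, out_dir=out)

s1 = manifest["samples"][0]
caller_sets = {
    caller: read_caller_vcf(out / rel, dialect=s1["dialects"][caller], caller_id=caller)
    for caller, rel in s1["vcfs"].items()
}
for caller, records in caller_sets.items():
    print(f"{caller:10s} reports {len(records)} variants")

for rule in ("intersection", "majority", "union"):
    n = len(build_consensus(caller_sets, rule=rule))
    print(f"rule={rule:13s} -> {n} consensus variants")
# intersection <= majority <= union always holds; majority (2 of 3) discards
# most caller-private spurious calls while tolerating single-caller dropout.
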