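"""Generate a synthetic serial tumor study with known ground truth.

Three bone-marrow-style samples, three simulated callers (one per VCF
dialect), a founder clone plus one dying and one arising subclone.
"""

import json
from pathlib import Path

from clonaltrack import SimConfig, default_clone_plans, simulate_serial_study

out = Path("scratch/example_bundle")
manifest = simulate_serial_study(default_clone_plans(3), SimConfig(seed=42), out)

print(f"bundle written to {out}/ with {manifest['n_samples']} samples")
truth = json.loads((out / manifest["truth"]).read_text())
for t in truth["evolution"]["transitions"]:
    print(f"  {t['from']} -> {t['to']}: {len(t['survived'])} survive, "
          f"{len(t['gained'])} gained, {len(t['dead_pool'])} in the dead pool")
# The dead pool is the planted dying subclone; the gains are the arising one.
# Running the full pipeline on this bundle should reproduce these sets exactly.
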