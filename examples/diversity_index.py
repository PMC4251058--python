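"""Shannon diversity of a sample's variant set.

Each variant is a molecular species weighted by its abundance VAF x DP x CN;
SDI = -sum p ln p rises with both the number of species and the evenness of
their weights, and is capped at ln N.
"""

import math

from clonaltrack.datasets import serial_study
from clonaltrack.diversity import diversity_report

study = serial_study()
for sample in study.samples:
    rep = diversity_report(sample.variants.values(), weight_mode="abundance")
    pub = sample.meta["published"]
    print(f"{sample.label:12s} ({sample.year}): key-gene subset N={rep.n_variants}, "
          f"SDI={rep.shannon:.3f} (max ln N = {rep.max_entropy:.3f}, "
          f"evenness {rep.evenness:.2f})")
    print(f"{'':12s}  published whole-sample: N={pub['n_variants']}, "
          f"SDI={pub['sdi']} <= ln N = {math.log(pub['n_variants']):.3f}")
# The bundled dataset carries only the 15 key genes, so its SDI is computed
# over that subset; the published whole-sample SDIs (all passing variants)
# each respect the maximum-entropy bound ln N, rising from presentation to
# first relapse (diversification) and dipping slightly at second relapse.
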