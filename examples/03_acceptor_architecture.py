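"""Acceptor-side architecture: branchpoint, AGEZ, PPT and terminal NAG.

Introns preceding Zn exons carry uridine-richer polypyrimidine tracts
than those preceding Ca exons; the median test quantifies the PPT-score
shift between the two synthetic groups.
"""

import numpy as np

from metalsplice import acceptor_architecture, stattests
from metalsplice.simulate import CohortSpec, gen_intron

spec = CohortSpec(seed=2)
rng = spec.rng_for("example")

scores = {"ZF": [], "EF": []}
for group in scores:
    for i in range(200):
        intron, bp = gen_intron(spec, group, rng)
        arch = acceptor_architecture(f"{group}_{i}", intron)
        scores[group].append(arch.ppt_score)
        if i == 0:
            print(f"{group} example: NAG={arch.terminal_nag}  "
                  f"BP at {arch.bp.pos}  AGEZ={arch.agez_len} nt  "
                  f"PPT score={arch.ppt_score:.1f}  (U)4 x{arch.u4_count}")

for group, vals in scores.items():
    print(f"{group}: mean PPT score {np.mean(vals):.2f}")
res = stattests.median_test(scores["ZF"], scores["EF"])
print(f"median test: chi2 = {res.statistic:.1f}, p = {res.p_value:.2e}")
# The Zn-like group (PPT uridine content 0.75 vs 0.55) shows the higher
# PPT score, mirroring the compensatory uridine enrichment.
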