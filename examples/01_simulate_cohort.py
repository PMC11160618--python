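"""Simulate a cohort of N2 offspring from F1 hybrid sires.

Crossovers are placed by a stationary gamma renewal chiasma process
(shape nu, rate 2*nu per Morgan) thinned by 1/2, so the expected number of
crossovers per meiosis equals the map length in Morgans.
"""

import numpy as np

from gammaxo import simulate_cohort, small_sim_config

cfg = small_sim_config(seed=1, n_per_group=50)
res = simulate_cohort(cfg)

counts = [sum(len(p) for p in m.positions_cm.values()) for m in res.meioses]
print(f"offspring:               {len(res.meioses)}")
print(f"markers (dense+sparse):  {len(res.genetic_map)}")
print(f"autosomal map length:    {cfg.chromosome_lengths.sum():.0f} cM")
print(f"mean crossovers/meiosis: {np.mean(counts):.2f}  (range "
      f"{min(counts)}-{max(counts)})")
# A 1230-cM map means 12.3 crossovers expected per transmitted gamete;
# the simulated mean should sit within sampling error of that value.
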