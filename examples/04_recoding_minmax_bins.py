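"""Amino-acid recoding: Dayhoff groups and minmax chi-squared bins.

Simulates a compositionally heterogeneous amino-acid alignment, recodes
it with the six fixed Dayhoff classes, and then searches for the bin
partition that minimizes the worst per-taxon chi-square statistic.  The
bin count is chosen as the largest k whose minmax partition cannot reject
compositional homogeneity (min P > 0.05).
"""

import numpy as np

import mitocomp as mc
from mitocomp.alignment import AA_STATES
from mitocomp.heterogeneity import BinPartition, max_taxon_chi2

base = np.full(20, 0.05)
shifted = base.copy()
shifted[:5] += 0.09
shifted[5:] -= 0.45 / 15

al, _ = mc.simulate_alignment(mc.SimulationConfig(
    "((a:0.4,b:0.4):0.2,(c:0.4,d:0.4):0.2,(e:0.4,f:0.4):0.2);",
    AA_STATES, tuple(base), 1200, seed=7,
    shifts=[mc.CompositionShift("a", 0.0, tuple(shifted)),
            mc.CompositionShift("b", 0.0, tuple(shifted))]))

counts = mc.count_matrix(al)
stat20, p20 = max_taxon_chi2(counts, tuple(sorted(AA_STATES)))
print(f"Unbinned (20 states): worst-taxon chi-square {stat20:.1f}, min P {p20:.4f}")

dayhoff = mc.recode(al, BinPartition(mc.DAYHOFF_GROUPS))
stat6, p6 = max_taxon_chi2(mc.count_matrix(al), mc.DAYHOFF_GROUPS)
print(f"Dayhoff groups (k=6):  worst-taxon chi-square {stat6:.1f}, min P {p6:.4f}")

k_star, parts = mc.select_bin_count(al, k_max=8, alpha=0.05, seed=1, restarts=25)
part = parts[max(k_star, 2)]
print(f"\nLargest homogeneous bin count: k* = {k_star}")
print(f"  minmax partition: {part.serialize()}  (min P = {part.min_p:.3f})")
print("\nRecoding trades information for homogeneity: fewer bins blur the "
      "amino-acid signal but remove the composition differences that "
      "stationary models mistake for shared ancestry.")
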