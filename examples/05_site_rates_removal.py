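"""Sitewise rates on a fixed tree and removal of the fastest sites.

Simulates a 16-taxon nucleotide alignment with gamma-distributed site
rates, re-estimates the rates with the pruning algorithm under a
discrete-gamma GTR model, and removes the fastest 20% of columns - the
standard saturation-reduction step before re-running tree inference.
"""

import numpy as np
from scipy.stats import spearmanr

import mitocomp as mc
from mitocomp.models import SubstitutionModel


def balanced(n, term=0.3, inner=0.1):
    labels = [f"t{i}" for i in range(n)]

    def build(lo, hi):
        if hi - lo == 1:
            return f"{labels[lo]}:{term}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{inner}"

    return build(0, n) + ";"


newick = balanced(16)
freqs = (0.3, 0.2, 0.2, 0.3)
al, true_rates = mc.simulate_alignment(mc.SimulationConfig(
    newick, "ACGT", freqs, 2000, gamma_shape=0.5, seed=11))

model = SubstitutionModel.gtr(freqs, alpha=0.5, n_categories=8)
est = mc.posterior_mean_rates(mc.site_likelihoods(al, newick, model))
rho = spearmanr(true_rates, est).statistic
print(f"Simulated {al.n_taxa} taxa x {al.n_columns} sites, "
      f"gamma(0.5) site rates")
print(f"rank correlation of estimated vs true rates: {rho:.3f}")
print(f"mean estimated rate: {est.mean():.3f} (model calibrates it to 1)")

reduced, removed = mc.remove_fast_sites(al, est, 0.20)
print(f"\nremoved the {len(removed)} fastest columns; "
      f"{reduced.n_columns} of {al.n_columns} remain")
print(f"mean true rate of removed columns: {true_rates[removed].mean():.2f} "
      f"vs kept: {np.delete(true_rates, removed).mean():.2f}")
print("\nHigh-rate columns saturate first and drive long-branch artefacts; "
      "dropping them is a blunt but common guard before phylogenetics.")
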