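"""Test chromosome-wide LD statistics against the haplotype-shift null.

The null pairs each haplotype's left-site allele with the NEXT haplotype's
right-site allele on a randomly permuted list: allele frequencies and
short-range structure survive, genuine long-range coupling does not.
"""

import numpy as np

from lrldscan import (
    PlantedAssociation,
    ScanConfig,
    SimConfig,
    empirical_p,
    null_distributions,
    scan_chromosome,
    simulate,
)
from lrldscan.synthetic import feasible_planted_pair, plant_association

for label, planted in [("no signal", False), ("planted signal", True)]:
    hm = simulate(SimConfig(n_hap=60, n_snp=300, seed=1001))
    if planted:
        i, j = feasible_planted_pair(hm, 20.0, 0.9)
        hm = plant_association(hm, PlantedAssociation(i, j, 0.9), 0.4,
                               np.random.default_rng(7))
    res = scan_chromosome(hm, ScanConfig(p_cap=5e-3, n_1=10, mean_mode="geometric"))
    nd_pd, nd_np = null_distributions(hm, r_min=0.25, threshold=res.threshold,
                                      n_reps=200, seed=55, mean_mode="geometric")
    p_pd, raw = empirical_p(res.pd_max, nd_pd, "lower_is_extreme")
    p_np, _ = empirical_p(res.n_p, nd_np, "higher_is_extreme")
    print(f"{label:15s} pd_max = {res.pd_max:9.3g}  p = {p_pd:.4f} "
          f"(raw {raw:.3f});  n_p = {res.n_p}  p = {p_np:.4f}")
print("with no signal both p-values are unremarkable; the planted panel's")
print("pd_max drops far below every permutation replicate (raw 0 -> p = 1/201).")
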