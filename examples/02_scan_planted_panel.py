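"""Scan a synthetic chromosome carrying one planted long-range association.

Generates a 60-haplotype founder-mosaic panel (short-range LD only), plants
a strength-0.9 association between two sites more than 20 cM apart, and runs
the patch scan.  The planted pair should surface as the patch with the
smallest p_D.
"""

import numpy as np

from lrldscan import PlantedAssociation, ScanConfig, SimConfig, scan_chromosome, simulate
from lrldscan.synthetic import feasible_planted_pair, plant_association

base = simulate(SimConfig(n_hap=60, n_snp=300, seed=500))
i, j = feasible_planted_pair(base, min_gap_cm=20.0, strength=0.9)
hm = plant_association(base, PlantedAssociation(i, j, 0.9), 0.4,
                       np.random.default_rng(501))
print(f"planted: sites {hm.sites[i].id} and {hm.sites[j].id}, "
      f"{hm.cm[j] - hm.cm[i]:.1f} cM apart")

res = scan_chromosome(hm, ScanConfig(p_cap=5e-3, n_1=10, mean_mode="geometric"))
print(f"threshold p* = {res.threshold:.3g} chosen for ~{res.n_target} patches; "
      f"found n_p = {res.n_p}")
for p in res.patches:
    tag = " <- planted" if (p.left_span_bp[0] <= hm.sites[i].bp <= p.left_span_bp[1]
                            and p.right_span_bp[0] <= hm.sites[j].bp <= p.right_span_bp[1]) else ""
    print(f"  patch: {len(p):2d} pair(s), min p_D = {p.min_p:9.3g}, "
          f"left {p.left_span_cm[0]:5.1f}-{p.left_span_cm[1]:5.1f} cM, "
          f"right {p.right_span_cm[0]:5.1f}-{p.right_span_cm[1]:5.1f} cM{tag}")
print(f"pd_max (geometric mean of patch minima) = {res.pd_max:.3g}")
print("the planted patch's minimum is orders of magnitude below the noise")
print("patches, which sit just under the adaptive threshold.")
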