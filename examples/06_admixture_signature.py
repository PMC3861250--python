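"""Admixture as a genome-wide source of long-range LD.

Mixing two diverged populations puts every frequency-differentiated pair of
sites in LD regardless of distance.  The scan flags the admixed panel; the
block-heterozygosity correlation (computed between non-overlapping 10-SNP
blocks, across individuals) shows the same signature independently.
"""

import numpy as np

from lrldscan import (
    ScanConfig,
    SimConfig,
    empirical_p,
    null_distributions,
    scan_chromosome,
    simulate,
)
from lrldscan.trends import sved_block_correlation

for label, proportion in [("admixed 50/50", 0.5), ("single source", 1.0)]:
    hm = simulate(SimConfig(n_hap=120, n_snp=100, seed=700,
                            admixture=(proportion, 0.6)))
    res = scan_chromosome(hm, ScanConfig(p_cap=5e-3, n_1=10, mean_mode="geometric"))
    nd, _ = null_distributions(hm, 0.25, res.threshold, 200, seed=800,
                               mean_mode="geometric")
    p, _ = empirical_p(res.pd_max, nd, "lower_is_extreme")
    corrs = [r for _d, r in sved_block_correlation(hm, block_size=10)]
    print(f"{label:15s} pd_max = {res.pd_max:9.3g}  p = {p:.4f}; "
          f"mean block-het correlation = {np.mean(corrs):+.3f}")
print("admixture drives pd_max far below its null AND inflates the")
print("between-block heterozygosity correlation; the single-source panel")
print("shows neither signature.")
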