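"""Score a two-site haplotype table with the exact-test LD statistic p_D.

p_D is the probability, conditioning on the allele counts at both sites, of
a disequilibrium D at least as large as observed — the tail of Fisher's
exact test.  Small p_D = strong evidence of association.
"""

from lrldscan import (
    HaplotypeTable2x2,
    disequilibrium_D,
    kosambi_r_from_cM,
    p_D,
    scaled_recombination_rho,
)

# 10 haplotypes, alleles perfectly coupled: 5 carry 1-1, 5 carry 0-0
coupled = HaplotypeTable2x2(n11=5, n10=0, n01=0, n00=5)
print(f"coupled table    D = {disequilibrium_D(coupled):+.3f}  "
      f"p_D = {p_D(coupled):.6f}   (1/252: only 1 of 252 margin-fixed tables)")

# independent-looking table: D = 0, the tail holds most of the mass
flat = HaplotypeTable2x2(2, 2, 2, 2)
print(f"balanced table   D = {disequilibrium_D(flat):+.3f}  "
      f"p_D = {p_D(flat):.4f}   (no evidence of association)")

# the long-range cutoff: 0.25 cM via Kosambi, scaled by N_e = 7,500
r = kosambi_r_from_cM(0.25)
rho = scaled_recombination_rho(7500, r)
print(f"r(0.25 cM) = {r:.7f};  rho = 4*N_e*r = {rho:.2f}")
print("rho ~ 75 marks enough recombination to erase ancestry LD, so pairs")
print("beyond 0.25 cM are 'long range' for a population of this size.")
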