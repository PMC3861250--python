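# lrldscan

Chromosome-wide detection of **long-range linkage disequilibrium (LRLD)** in
phased haplotype panels.

Most LD in a large outbred population is short-range: tightly linked sites
travel together because of shared ancestry, and recombination erases the
association within fractions of a centimorgan. Associations between *distant*
sites — beyond the scale where the population-scaled recombination rate
ρ = 4·N_e·r is large — are therefore interesting: they can point to
epistatic selection, admixture, inversions, or genotyping artifacts. This
package implements a scan for such associations, aimed at population
geneticists working with phased reference panels (VCF or IMPUTE-style
`.hap`/`.legend` files plus a genetic map).

## Method

For each pair of biallelic sites separated by more than `r_min` on the
genetic map (default 0.25 cM, which at N_e = 7,500 corresponds to ρ ≈ 75 —
enough recombination to largely eliminate ancestry LD), the scan computes

- **p_D** — the tail of Fisher's exact test on the 2×2 haplotype table: the
  probability, conditioning on the sampled allele counts at both sites, of a
  disequilibrium D = f(AB) − f(A)f(B) at least as large as observed, in the
  direction of the observed D. Smaller p_D = stronger evidence. Map
  distances convert to recombination fractions with the Kosambi function
  r = ½·tanh(2d).

Extreme pairs (p_D ≤ an adaptively chosen threshold p\*) are aggregated into
**patches**: two pairs (A,B) and (A′,B′) merge when |A−A′| < r_min and
|B−B′| < r_min, and patches are the connected components of this relation
(single linkage via a disjoint-set structure). A patch represents LD between
two chromosome blocks. p\* is chosen so that approximately `n_target`
patches result, with `n_target` scaled across chromosomes to keep the patch
density per SNP pair constant.

Each chromosome is summarized by **p_D^max** (the mean over patches of each
patch's smallest p_D; arithmetic and geometric means are both available) and
**n_P** (the patch count). Significance comes from a **haplotype-shift
permutation null**: haplotype identifiers are randomly permuted once per
replicate, and every pair is re-scored on artificial haplotypes combining
the left-site allele of one haplotype with the right-site allele of the
*next* haplotype on the permuted list. This preserves allele frequencies at
every site exactly and keeps short-range haplotype structure intact while
destroying genuine long-range coupling.

Supporting analyses: overlap of patch anchor sites with annotation
catalogues (BED) against a random-placement null; distance-decay
diagnostics (Spearman correlation of patch extremeness vs distance, binned
patch density); and block-heterozygosity correlations between distant SNP
blocks, a classical genome-wide admixture signature.

A synthetic-data module generates founder-mosaic panels with tunable LD
decay, planted long-range associations (by block-row permutation, which
preserves all allele frequencies and within-block LD exactly), and
two-population admixture — so the whole pipeline is testable without any
data download.

## Worked example

`examples/02_scan_planted_panel.py` generates a 60-haplotype, 300-SNP
founder-mosaic panel, plants one strength-0.9 association between sites
22 cM apart, and scans:

```
planted: sites s00001 and s00134, 22.2 cM apart
threshold p* = 0.000269 chosen for ~10 patches; found n_p = 10
  patch:  1 pair(s), min p_D =   2.4e-14, left   0.0-  0.0 cM, right  22.2- 22.2 cM <- planted
  patch:  1 pair(s), min p_D =  0.000269, left  10.0- 10.0 cM, right  16.1- 16.1 cM
  ...
pd_max (geometric mean of patch minima) = 1.13e-05
```

The planted patch's minimum (2.4×10⁻¹⁴) sits orders of magnitude below the
nine noise patches, which cluster just under the adaptive threshold.
Against 200 shift-permutation replicates (`examples/03_permutation_null.py`)
the same panel gives

```
no signal       pd_max =  0.000227  p = 0.7562 (raw 0.755);  n_p = 10  p = 0.3333
planted signal  pd_max =  3.75e-05  p = 0.0050 (raw 0.000);  n_p = 10  p = 0.3383
```

— the planted panel's p_D^max is more extreme than every replicate
(add-one p = 1/201), while the no-signal panel is unremarkable.

The other examples cover the exact test itself (`01`), catalogue overlap
(`04`), distance trends (`05`) and the admixture signature (`06`).

## Command line

A thin CLI wraps the same library calls:

```sh
lrldscan simulate --n-hap 60 --n-snp 300 --seed 5 --out-dir sim/
lrldscan scan  --haps sim/panel.hap --legend sim/panel.legend \
               --map sim/panel.map --chrom chrS --p-cap 5e-3 --n1 10 --out-dir scan/
lrldscan null  ... --reps 1000 --seed 1 --out-dir null/
lrldscan overlap ... --regions catalogue.bed --out-dir overlap/
lrldscan sweep ... --r-min-grid 0.125,0.25,0.5 --n1-grid 125,250,500 --out-dir sweep/
```

Every command writes tab-delimited tables plus a `*.meta.json` sidecar with
all parameters and seeds; reruns with identical inputs are byte-identical.

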