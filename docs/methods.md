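# Methods

## The statistic

For two biallelic sites on phased haplotypes, the observed 2×2 table
(n11, n10, n01, n00) records the four two-site haplotype classes. Classical
disequilibrium is D = n11/n − (n11+n10)(n11+n01)/n². D's sampling noise
depends strongly on allele frequencies, so the scan instead uses **p_D**:
the probability, under the hypergeometric distribution that fixes both
margins at their sampled values, of a 1–1 count at least as extreme as the
observed one *in the direction of the observed D* (the observed table
included). This is the one-sided tail of Fisher's exact test. For distant
pairs (ρ = 4·N_e·r ≫ 1) the two-locus haplotype sampling distribution
converges on exactly this conditional distribution, which is what makes a
small p_D evidence of non-random association rather than of drift.

Properties relied on throughout, and property-tested:

- p_D ∈ (0, 1]; it shrinks monotonically as n11 moves away from its
  conditional expectation in the direction of D;
- relabeling alleles at both sites simultaneously leaves p_D unchanged;
  relabeling at one site flips D's sign and selects the opposite tail;
- a tie D = 0 takes the upper tail, whose mass is ≥ ~0.5 — it can never
  cross an extremeness threshold, so the tie-break is inert.

A `two_sided=True` variant (sum of all tables with point probability not
exceeding the observed) exists for comparison; the scan does not use it,
because D's sign is a labeling artifact and the directional tail is the
reading that is invariant in the sense above.

### Numerics

Each log-pmf term is assembled by addition from a shared table of ln k!
(`LogFactorialTable`), and tails accumulate in log space starting from the
most extreme table, so tails of order 10⁻⁶⁰ lose no precision. Scalar p_D
agrees with an exact-rational (Fraction arithmetic) brute-force tail to
1e-10 relative on an exhaustive sweep of tables up to n = 60, and to 1e-9
on spot checks at n = 10,000.

Whole-chromosome scans use the fact that at fixed panel size n, p_D is a
function of (left margin, right margin, n11) only. A precomputed cube of
all such values (`PDTailTable`, ~14 MB at n = 120; limited to n ≤ 400)
turns a scan or a permutation replicate into one integer matrix product for
the n11 counts plus an array lookup. The cube is built from the same
log-pmf machinery as the scalar path and is tested against the same
rational oracle.

## Pairs, patches, chromosome statistics

- **Eligibility**: pairs with map separation strictly > `r_min` (default
  0.25 cM). At N_e = 7,500 this is ρ ≈ 75, enough recombination to largely
  erase ancestry LD; the same `r_min` is reused as the patch merge radius.
  Kosambi's map function r = ½·tanh(2d) (d in Morgans) converts distances;
  all public interfaces speak cM.
- **Patches**: among pairs with p_D ≤ p\*, pairs (A,B) and (A′,B′) merge
  when |A−A′| < r_min AND |B−B′| < r_min (strict on both sides; boundary
  equality excluded in both the eligibility and merge tests). Patches are
  connected components of the transitive closure, computed with a
  disjoint-set structure and verified against explicit-graph connected
  components. Merging near the r_min boundary can in principle produce a
  patch whose left and right spans touch; such patches are flagged
  (`self_overlapping`), not silently dropped.
- **Threshold choice**: candidate thresholds are the distinct p values
  present; an incremental union-find pass yields the patch count at every
  candidate in one sweep (the count is not monotone — adding pairs can
  merge patches). The chosen p\* minimizes |count − n_target|, ties toward
  the smaller threshold. `patch_target` keeps patch density per SNP pair
  constant across chromosomes: n_target = n_1·(n_S/n_S,ref)², rounded half
  away from zero, floored at 1.
- **p_cap** (default 1e-4) bounds how many scored pairs are retained; it is
  purely a memory bound and provably transparent whenever the chosen
  threshold lands below it (tested). Desk-scale runs in this repository use
  p_cap = 5e-3 because with ~45,000 pairs the expected number of sub-1e-4
  pairs (~4) is smaller than the patch targets used here.
- **Chromosome statistics**: p_D^max = mean over patches of each patch's
  minimum p_D; n_P = patch count. Both an arithmetic and a geometric mean
  are implemented. The arithmetic mean is the package default. For
  significance testing, however, the examples and acceptance runs use the
  geometric mean: patch minima are tail probabilities spanning many orders
  of magnitude, and an arithmetic mean is dominated by the *least* extreme
  patches — a single genuine signal among k patches shifts it by at most a
  factor (k−1)/k, which no permutation test can distinguish. The geometric
  mean averages on the log scale, where one extreme patch moves the
  statistic by many null standard deviations while remaining calibrated
  under the null (verified: 0/40 false calls at α = 0.05 on no-signal
  panels, inside the exact binomial 95% band).

## The haplotype-shift permutation null

One replicate draws a single random permutation of haplotype identifiers
for the whole chromosome. For every eligible pair (i, j), artificial
haplotype k combines the allele at i of haplotype perm[k] with the allele
at j of haplotype perm[(k+1) mod n]. Consequences, both tested:

- every haplotype contributes exactly once to each site's margin, so the
  shifted table's margins equal the real allele counts *exactly* (the wrap
  is cyclic for precisely this reason; a linear "next on the list" reading
  would perturb the margins by one haplotype);
- columns that are identical in the real data produce identical shifted
  tables, so short-range structure survives the shift and chance patches in
  the null mimic chance patches in the data;
- genuine long-range coupling between specific haplotype pairs is
  destroyed: the shifted p_D of a planted pair is statistically
  indistinguishable from that of a truly independent pair.

The patch threshold p\* is **held fixed at the observed-data value** across
replicates. Re-adapting it per replicate would pin every replicate's patch
count near n_target and make the n_P statistic vacuous; holding it fixed is
the only reading under which a patch-count test carries information.
Replicates with no sub-threshold pair record a +∞ sentinel for p_D^max
(maximally non-extreme for a lower-is-extreme statistic) and n_P = 0.

Empirical p-values count ties as extreme and are reported two ways: the
add-one estimator (r+1)/(n_reps+1), which is never exactly zero, and the
raw fraction r/n_reps, which supports "< 1/n_reps"-style statements when no
replicate reaches the observation. Because the observed threshold is chosen
adaptively on the observed data, the observed statistic is slightly
"typical" by construction and the test errs conservative — visible in the
calibration runs, where the null p-value distribution is shifted away from
small values rather than uniform. This costs some power but never inflates
type-I error.

## Catalogue overlap and distance trends

Overlap tests take each patch's extreme pair (the member attaining the
patch minimum, ties broken lexicographically) and count pairs with one or
both sites inside catalogue intervals; "both" means each site in *some*
interval, not necessarily the same one. Sites are 1-based bp, intervals are
BED half-open; the conversion happens once, at the membership test. The
null drops intervals of the same number and lengths uniformly at random on
the chromosome (placed intervals may overlap; a rejection-sampling
non-overlapping mode exists). Observed and null counts share one counting
path. Breakpoint windows (±w cM around given positions, converted through
the inverse genetic map) turn inversion-breakpoint lists into catalogues
for the same test.

Distance diagnostics: Spearman rank correlation (average ranks for ties;
large-sample p) between per-patch extremeness and extreme-pair distance —
invariant up to sign under monotone transforms, so −ln p_D vs p_D is
immaterial; patch density per eligible SNP pair in 20 equal-width distance
bins (pair counts exact below a configurable total, else estimated from a
flagged uniform subsample); and block-heterozygosity correlations: cut the
chromosome into non-overlapping blocks of 50 SNPs, pair haplotypes
(2k, 2k+1) into individuals in input order, compute each individual's mean
heterozygosity per block, and correlate block pairs across individuals as a
function of midpoint distance. Zero-variance blocks are skipped with a log
note. The focal-window comparison (`region_vs_genome_sved`) contrasts a
window's mean block-pair correlation with the same statistic over random
equal-width windows; this randomization design is this package's own
construction and is labeled as such.

## Synthetic panels

`generate_founder_mosaic` draws n_founders founder haplotypes site-wise
from per-site frequencies ~ Uniform(founder_freq_range), then builds each
sample haplotype as a piecewise founder copy, switching to a uniformly
chosen founder between adjacent sites with probability
1 − exp(−switch_rate·Δcm). Defaults: 120 haplotypes (the size of the
phased panels this scan targets), 300 sites over 50 cM, 20 founders,
switch rate 2/cM, frequencies in (0.1, 0.9), and a fixed 1 cM/Mb physical
scale (bp = round(cm·10⁶)). At these settings short-range LD decays within
~1–2 cM and pairs beyond 10 cM test as independent (fraction of p_D < 0.05
within binomial bounds of 0.05). Degenerate corners are documented rather
than hidden: switch rate 0 copies founders verbatim; a single founder
yields an all-monomorphic panel that the filter empties.

`plant_association` creates ground truth by permuting whole rows of the
block of columns within ±0.4 cM of the target site: marginal allele
frequencies at every site and all within-block LD are preserved *exactly*
(a row permutation of a sub-block changes only cross-block association),
which also leaves the permutation null's margins untouched. The
permutation is chosen to reach a requested allele correlation; infeasible
requests (given realized frequencies) raise with advice rather than
silently under-delivering. `feasible_planted_pair` picks a suitable distant
pair, restricted to sites with minor allele count ≥ n/4 because a planted
association between near-fixed sites carries almost no exact-test evidence
(a perfectly coupled pair at allele count n−1 has p_D = 1/n).

`generate_admixed` mixes two populations whose per-site frequencies sit
±divergence/2 around a common uniform draw (clipped to (0.02, 0.98)), each
haplotype drawn wholly from one source, sites independent within a source —
the textbook mechanism by which admixture generates LD between all
frequency-differentiated pairs at any distance.

What the generator does *not* emulate: coalescent genealogies (no variance
in ancestry depth along the chromosome), mutation models, gene conversion,
variable recombination rate along the map, and genotyping error. Passing
tests therefore demonstrate the scan's statistical machinery — calibration,
power against planted coupling and admixture, exactness of the null — not
robustness to the full texture of real panels.

## Problem sizes and reproducibility

Test and example runs use 60×300 (scan properties, calibration, planting)
and 120×100 (admixture) panels with 200 permutation replicates, and 40
independent panels for type-I calibration — sizes at which the full
pipeline runs in seconds per panel while leaving the binomial test
non-trivial. Production-scale defaults (r_min = 0.25 cM, n_1 = 250,
1,000 replicates) remain the CLI defaults.

All randomness flows through `numpy.random.Generator` objects seeded
explicitly; permutation replicates draw from one master generator, so any
(input, seed) pair reproduces bit-identical statistics, tables and files
(tested end-to-end through the CLI).

## Known limitations

- The tail-table cube caps panel size at n = 400 haplotypes; beyond that
  the scalar path works but whole-chromosome scans would need a chunked
  batch path not implemented here.
- Patch spans can touch when merges chain near the r_min boundary; flagged,
  not resolved.
- The adaptive-threshold/fixed-null design is conservative for p_D^max (see
  above); exact exchangeability would require re-choosing the threshold per
  replicate, which destroys the n_P test.
- Missing or unphased genotypes are rejected, not imputed: the exact test
  needs complete 2×2 tables, and the intended inputs are complete phased
  panels.
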