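"""Distance-decay diagnostics for long-range LD.

Three views of how association strength relates to map distance:

* rank correlation between per-patch extreme −ln p_D and the distance of the
  extreme pair (Spearman, so any strictly monotone transform of either axis
  changes nothing but the sign);
* patch density versus distance: patches grouped into equal-width distance
  bins, each bin normalized by the number of eligible SNP pairs it contains;
* block-heterozygosity correlations: chromosomes cut into non-overlapping
  blocks of SNPs, each individual's heterozygosity averaged per block, and
  the across-individual correlation of every block pair plotted against the
  map distance between block midpoints — a classical whole-genome signature
  of admixture or structure.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .ld_core import kosambi_r_from_cM
from .null_model import NullDistribution, empirical_p
from .scan import Patch, eligible_pair_mask

logger = logging.getLogger(__name__)

__all__ = [
    "patch_distance",
    "spearman_correlation",
    "density_by_distance",
    "sved_block_correlation",
    "region_vs_genome_sved",
]


def patch_distance(patch: Patch, cm: np.ndarray, metric: str = "kosambi_r") -> float:
    """Map separation of the patch's extreme pair, in cM or as Kosambi r."""
    d = float(cm[patch.extreme_pair.right] - cm[patch.extreme_pair.left])
    if metric == "cm":
        return d
    if metric == "kosambi_r":
        return kosambi_r_from_cM(d)
    raise ValueError(f"unknown metric {metric!r}")


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value from the standard large-sample approximation.  Invariant (up to
    sign) under strictly monotone transforms of either argument, so
    correlating distance with p_D or with −ln p_D differ only in sign.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def density_by_distance(
    patches: list[Patch],
    cm: np.ndarray,
    r_min: float,
    n_bins: int = 20,
    metric: str = "kosambi_r",
    exact_pair_limit: int = 2_000_000,
    subsample: int = 500_000,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Patch density per eligible SNP pair in equal-width distance bins.

    Bins span the range of eligible pair distances on the chosen metric;
    density(bin) = patches whose extreme pair falls in the bin / eligible
    pairs in the bin.  Bins containing no pair are dropped.  When the total
    eligible pair count exceeds ``exact_pair_limit`` the per-bin pair counts
    are estimated from a uniform subsample and scaled (logged).
    """
    if not patches:
        raise ValueError("no patches")
    cm = np.asarray(cm, dtype=float)
    mask = eligible_pair_mask(cm, r_min)
    ii, jj = np.nonzero(mask)
    total = len(ii)
    scale = 1.0
    if total > exact_pair_limit:
        rng = np.random.default_rng(seed)
        sel = rng.choice(total, size=subsample, replace=False)
        ii, jj = ii[sel], jj[sel]
        scale = total / subsample
        logger.info("pair distances subsampled (%d of %d); densities estimated", subsample, total)
    dist = cm[jj] - cm[ii]
    pdist = np.array([patch_distance(p, cm, "cm") for p in patches])
    if metric == "kosambi_r":
        dist = kosambi_r_from_cM(dist)
        pdist = kosambi_r_from_cM(pdist)
    lo, hi = float(dist.min()), float(dist.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    pair_counts = np.histogram(dist, bins=edges)[0] * scale
    patch_counts = np.histogram(np.clip(pdist, lo, hi), bins=edges)[0]
    mids = 0.5 * (edges[:-1] + edges[1:])
    return [
        (float(m), float(pc / nc))
        for m, pc, nc in zip(mids, patch_counts, pair_counts)
        if nc > 0
    ]


def _block_heterozygosity(hm, block_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual mean heterozygosity of consecutive SNP blocks.

    Haplotypes 2k and 2k+1 are paired into individual k.  Returns
    (het matrix: individuals × blocks, block midpoint cm).  The trailing
    incomplete block is dropped.
    """
    if hm.n_hap % 2:
        raise ValueError("need an even number of haplotypes to pair into individuals")
    n_blocks = hm.n_site // block_size
    if n_blocks < 2:
        raise ValueError("need at least 2 complete blocks")
    het = (hm.alleles[0::2, :] != hm.alleles[1::2, :]).astype(float)
    used = n_blocks * block_size
    het_blocks = het[:, :used].reshape(het.shape[0], n_blocks, block_size).mean(axis=2)
    cm = hm.cm[:used].reshape(n_blocks, block_size)
    mids = 0.5 * (cm[:, 0] + cm[:, -1])
    return het_blocks, mids


def sved_block_correlation(
    hm, block_size: int = 50, focal_window: tuple[float, float] | None = None
) -> list[tuple[float, float]]:
    """Correlation in block heterozygosity for every non-overlapping block pair.

    For each pair of blocks, the product-moment correlation across
    individuals of the two blocks' heterozygosities, against the cm distance
    between block midpoints.  Blocks whose heterozygosity does not vary
    across individuals are skipped (their correlation is undefined).
    ``focal_window=(lo_cm, hi_cm)`` restricts to blocks with midpoints inside
    the window.
    """
    het, mids = _block_heterozygosity(hm, block_size)
    keep = np.arange(len(mids))
    if focal_window is not None:
        lo, hi = focal_window
        keep = keep[(mids[keep] >= lo) & (mids[keep] <= hi)]
        if len(keep) < 2:
            raise ValueError("focal window contains fewer than 2 blocks")
    sd = het[:, keep].std(axis=0)
    variable = sd > 0
    if not variable.all():
        logger.info("skipping %d zero-variance block(s)", int((~variable).sum()))
    keep = keep[variable]
    out = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            i, j = keep[a], keep[b]
            r = float(np.corrcoef(het[:, i], het[:, j])[0, 1])
            out.append((float(abs(mids[j] - mids[i])), r))
    return out


def region_vs_genome_sved(
    hm,
    focal_window: tuple[float, float],
    block_size: int,
    n_random_windows: int,
    seed: int,
) -> tuple[float, float, float]:
    """Is block-heterozygosity correlation elevated in a focal map window?

    Compares the focal window's mean block-pair correlation against the same
    statistic for ``n_random_windows`` windows of equal cm width placed
    uniformly at random; one-tailed empirical p (higher mean more extreme),
    add-one convention.  Returns (focal mean, mean of null means, p).
    """
    if n_random_windows < 1:
        raise ValueError("n_random_windows must be >= 1")
    focal = sved_block_correlation(hm, block_size, focal_window)
    focal_mean = float(np.mean([r for _d, r in focal]))
    width = focal_window[1] - focal_window[0]
    cm = hm.cm
    lo_lim, hi_lim = float(cm.min()), float(cm.max()) - width
    if hi_lim <= lo_lim:
        raise ValueError("window wider than the mapped chromosome")
    rng = np.random.default_rng(seed)
    null_means = []
    for _ in range(n_random_windows):
        while True:
            start = rng.uniform(lo_lim, hi_lim)
            try:
                corrs = sved_block_correlation(hm, block_size, (start, start + width))
            except ValueError:
                continue  # window landed with < 2 blocks; redraw
            if corrs:
                null_means.append(float(np.mean([r for _d, r in corrs])))
                break
    null = NullDistribution("sved_window_mean", null_means, n_random_windows, seed)
    p, _raw = empirical_p(focal_mean, null, "higher_is_extreme")
    return focal_mean, float(np.mean(null_means)), p
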