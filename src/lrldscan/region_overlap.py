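"""Overlap of patch extreme pairs with annotation catalogues.

Tests whether the sites anchoring the strongest association in each patch
fall inside catalogued genomic intervals (e.g. selection-scan hits, or
windows around inversion breakpoints) more often than expected if intervals
of the same number and lengths were dropped at random onto the chromosome.

Coordinates: sites are 1-based bp, intervals are BED 0-based half-open;
membership converts the site to 0-based once, at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype_io import GeneticMap, RegionSet, Site
from .null_model import NullDistribution, empirical_p

__all__ = [
    "count_overlaps",
    "random_placement",
    "overlap_test",
    "breakpoint_windows",
    "OverlapResult",
]


def _membership(bps: np.ndarray, regions: RegionSet) -> np.ndarray:
    """True where site bp (1-based) lies in any interval (BED half-open)."""
    if not regions.intervals:
        return np.zeros(len(bps), dtype=bool)
    starts = np.array([iv[1] for iv in regions.intervals])
    ends = np.array([iv[2] for iv in regions.intervals])
    # merge overlapping intervals so membership is a sorted-boundary lookup
    order = np.argsort(starts)
    merged: list[list[int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([int(s), int(e)])
    ms = np.array([m[0] for m in merged])
    me = np.array([m[1] for m in merged])
    pos0 = np.asarray(bps, dtype=np.int64) - 1  # 1-based bp -> 0-based coordinate
    idx = np.searchsorted(ms, pos0, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos0[ok] < me[idx[ok]]
    return ok


def count_overlaps(
    extreme_pairs: list[tuple[Site, Site]], regions: RegionSet
) -> tuple[int, int]:
    """(pairs with >=1 site in a region, pairs with both sites in regions).

    "Both" means each site lies in *some* catalogue interval, not necessarily
    the same one.  All sites and regions must be on one chromosome; the
    caller subsets multi-chromosome catalogues first.
    """
    chroms = {iv[0] for iv in regions.intervals}
    if len(chroms) > 1:
        raise ValueError("regions span multiple chromosomes; subset first")
    if not extreme_pairs:
        return 0, 0
    lbp = np.array([p[0].bp for p in extreme_pairs])
    rbp = np.array([p[1].bp for p in extreme_pairs])
    lin = _membership(lbp, regions)
    rin = _membership(rbp, regions)
    return int(np.sum(lin | rin)), int(np.sum(lin & rin))


def random_placement(
    regions: RegionSet, chrom_length_bp: int, rng: np.random.Generator,
    non_overlapping: bool = False, max_tries: int = 1000,
) -> RegionSet:
    """Drop intervals of the same number and lengths uniformly onto [0, L).

    Placed intervals may overlap one another by default;
    ``non_overlapping=True`` rejection-samples whole layouts until none
    overlap.
    """
    lengths = [iv[2] - iv[1] for iv in regions.intervals]
    if any(ln > chrom_length_bp for ln in lengths):
        raise ValueError("region longer than chromosome")
    for _ in range(max_tries if non_overlapping else 1):
        placed = []
        for (chrom, _s, _e), ln in zip(regions.intervals, lengths):
            start = int(rng.integers(0, chrom_length_bp - ln + 1))
            placed.append((chrom, start, start + ln))
        if not non_overlapping:
            return RegionSet(placed)
        ivs = sorted((s, e) for _c, s, e in placed)
        if all(ivs[k][1] <= ivs[k + 1][0] for k in range(len(ivs) - 1)):
            return RegionSet(placed)
    raise RuntimeError("could not place non-overlapping regions")


@dataclass
class OverlapResult:
    observed_one: int
    observed_both: int
    p_one: float
    p_both: float
    raw_one: float
    raw_both: float
    null_one: NullDistribution
    null_both: NullDistribution


def overlap_test(
    extreme_pairs: list[tuple[Site, Site]],
    regions: RegionSet,
    chrom_length_bp: int,
    n_reps: int,
    seed: int,
    non_overlapping: bool = False,
) -> OverlapResult:
    """Random-placement test: are overlap counts higher than chance?

    Observed and null counts use the same counting path; one-tailed
    empirical p-values with ties extreme and the add-one convention.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    obs_one, obs_both = count_overlaps(extreme_pairs, regions)
    rng = np.random.default_rng(seed)
    ones, boths = [], []
    for _ in range(n_reps):
        placed = random_placement(regions, chrom_length_bp, rng, non_overlapping)
        c1, c2 = count_overlaps(extreme_pairs, placed)
        ones.append(float(c1))
        boths.append(float(c2))
    null_one = NullDistribution("overlap_one", ones, n_reps, seed)
    null_both = NullDistribution("overlap_both", boths, n_reps, seed)
    p_one, raw_one = empirical_p(obs_one, null_one, "higher_is_extreme")
    p_both, raw_both = empirical_p(obs_both, null_both, "higher_is_extreme")
    return OverlapResult(
        obs_one, obs_both, p_one, p_both, raw_one, raw_both, null_one, null_both
    )


def breakpoint_windows(
    breakpoints: list[tuple[str, int]], half_width_cm: float, gm: GeneticMap
) -> RegionSet:
    """Map-distance windows around breakpoints, as BED intervals.

    Each breakpoint becomes the physical interval spanning ± half_width_cm,
    obtained by inverting the genetic map.  A zero half-width degenerates to
    the single base covering the breakpoint.
    """
    intervals = []
    for chrom, bp in breakpoints:
        c = float(gm.interpolate([bp])[0])
        lo = float(gm.invert([max(0.0, c - half_width_cm)])[0])
        hi = float(gm.invert([c + half_width_cm])[0])
        start = max(0, int(np.floor(lo)) - 1)  # 1-based bp -> 0-based BED
        end = max(start + 1, int(np.ceil(hi)))
        intervals.append((chrom, start, end))
    return RegionSet(intervals)
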