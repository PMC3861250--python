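"""Haplotype-shift permutation null for the chromosome LD statistics.

A replicate randomly permutes the haplotype identifiers once for the whole
chromosome, then scores every long-range pair on artificial haplotypes that
combine the left-site allele of one haplotype with the right-site allele of
the *next* haplotype on the permuted list (cyclic, so every haplotype
contributes exactly once to each site's margin).  This preserves the allele
frequencies at every site exactly and keeps the short-range haplotype
structure intact — nearby sites still travel together on the left and on the
right — while destroying any genuine association between the two distant
blocks.  Patches built from a replicate therefore mimic chance patches in the
real data.

The patch threshold is held fixed at the observed-data p* across replicates:
re-adapting it per replicate would pin every replicate's patch count at the
target and make the patch-count statistic vacuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import math

import numpy as np

from .ld_core import HaplotypeTable2x2
from .scan import PairScore, build_patches, eligible_pair_mask, statistic_pd_max
from .scan import _pair_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "shift_pair_table",
    "null_replicate",
    "null_distributions",
    "empirical_p",
]

#: recorded for replicates that produce no patch: never extreme for pd_max
NO_PATCH_SENTINEL = math.inf


@dataclass
class NullDistribution:
    statistic_name: str
    values: list[float]
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n_reps:
            raise ValueError("one value per replicate required")


def _check_permutation(perm: np.ndarray, n: int) -> np.ndarray:
    perm = np.asarray(perm)
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("perm must be a bijection on 0..n_hap-1")
    return perm


def shift_pair_table(hm, perm, i: int, j: int) -> HaplotypeTable2x2:
    """2×2 table of the shifted artificial haplotypes for one pair.

    Artificial haplotype k carries the allele at site ``i`` of haplotype
    perm[k] and the allele at site ``j`` of haplotype perm[(k+1) mod n].
    Both margins equal the real panel's single-site allele counts exactly.
    """
    if not i < j:
        raise ValueError("left site index must precede right site index")
    perm = _check_permutation(perm, hm.n_hap)
    a = hm.alleles[perm, i]
    b = hm.alleles[np.roll(perm, -1), j]
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return HaplotypeTable2x2(n11, n10, n01, n00)


def _replicate_stats(hm, mask, perm, r_min, threshold, mean_mode):
    left = hm.alleles[perm, :]
    right = hm.alleles[np.roll(perm, -1), :]
    pmat = _pair_pvalues(left, right)
    ii, jj = np.nonzero(mask)
    pv = pmat[ii, jj]
    keep = pv <= threshold
    pairs = [
        PairScore(int(i), int(j), float(p))
        for i, j, p in zip(ii[keep], jj[keep], pv[keep])
    ]
    patches = build_patches(pairs, threshold, r_min, cm=hm.cm)
    if not patches:
        return None, 0
    return statistic_pd_max(patches, mean_mode), len(patches)


def null_replicate(
    hm,
    r_min: float,
    threshold: float,
    rng_seed: int,
    mean_mode: str = "arithmetic",
):
    """One shift-permutation replicate of (pd_max, n_p).

    ``pd_max`` is None when no pair passes the (fixed, observed-data)
    threshold; a patch count of 0 is a legitimate outcome.
    """
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(hm.n_hap)
    mask = eligible_pair_mask(hm.cm, r_min)
    return _replicate_stats(hm, mask, perm, r_min, threshold, mean_mode)


def null_distributions(
    hm,
    r_min: float,
    threshold: float,
    n_reps: int,
    seed: int,
    mean_mode: str = "arithmetic",
) -> tuple[NullDistribution, NullDistribution]:
    """n_reps independent replicates from one seeded generator.

    Replicate generators are spawned deterministically from the master seed.
    Patch-free replicates record the pd_max sentinel (+inf: maximally
    non-extreme for a lower-is-extreme statistic) and n_p = 0.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mask = eligible_pair_mask(hm.cm, r_min)
    master = np.random.default_rng(seed)
    pd_vals: list[float] = []
    np_vals: list[float] = []
    n_empty = 0
    for _ in range(n_reps):
        perm = master.permutation(hm.n_hap)
        pd_max, n_p = _replicate_stats(hm, mask, perm, r_min, threshold, mean_mode)
        if pd_max is None:
            pd_max = NO_PATCH_SENTINEL
            n_empty += 1
        pd_vals.append(pd_max)
        np_vals.append(float(n_p))
    if n_empty:
        logger.info("%d/%d null replicate(s) produced no patch", n_empty, n_reps)
    return (
        NullDistribution("pd_max", pd_vals, n_reps, seed),
        NullDistribution("n_p", np_vals, n_reps, seed),
    )


def empirical_p(
    observed: float, null: NullDistribution, direction: str
) -> tuple[float, float]:
    """Empirical one-tailed p-value against a permutation null.

    Returns ``(p_plus_one, raw_fraction)`` where ``p_plus_one`` is the
    add-one estimator (r+1)/(n_reps+1) — never exactly zero — and
    ``raw_fraction`` is r/n_reps, which supports "< 1/n_reps"-style
    reporting when no replicate reaches the observed value.  Ties count as
    extreme.  Use ``lower_is_extreme`` for pd_max and ``higher_is_extreme``
    for the patch count.
    """
    vals = np.asarray(null.values, dtype=float)
    if direction == "lower_is_extreme":
        r = int(np.sum(vals <= observed))
    elif direction == "higher_is_extreme":
        r = int(np.sum(vals >= observed))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return (r + 1) / (null.n_reps + 1), r / null.n_reps
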