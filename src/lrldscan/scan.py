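"""Chromosome scan: score long-range site pairs, cluster extremes into patches.

The scan enumerates every pair of sites separated by more than ``r_min`` on
the genetic map (default 0.25 cM, beyond which recombination in a population
of the intended size is expected to have largely erased ancestry LD), scores
each pair with the exact-test statistic ``p_D``, chooses a threshold p* such
that clustering the sub-threshold pairs yields approximately ``n_target``
patches, and summarizes the chromosome with two statistics:

* ``pd_max`` — the mean over patches of each patch's smallest ``p_D``;
* ``n_p``   — the number of patches at the chosen threshold.

Two extreme pairs (A,B) and (A',B') merge into one patch when the map
distances |A−A'| and |B−B'| are both below ``r_min``; patches are the
connected components of the transitive closure of this relation
(single-linkage, via a disjoint-set structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ld_core import shared_tail_table

logger = logging.getLogger(__name__)

__all__ = [
    "PairScore",
    "Patch",
    "ScanResult",
    "ScanConfig",
    "eligible_pairs",
    "eligible_pair_mask",
    "score_pairs",
    "build_patches",
    "patch_count_trajectory",
    "choose_threshold",
    "patch_target",
    "statistic_pd_max",
    "scan_chromosome",
]


@dataclass(frozen=True)
class PairScore:
    """An ordered long-range site pair with its exact-test value."""

    left: int
    right: int
    p: float


@dataclass
class Patch:
    """A single-linkage cluster of extreme pairs: LD between two blocks."""

    members: list[PairScore]
    min_p: float
    extreme_pair: PairScore
    left_span_cm: tuple[float, float]
    right_span_cm: tuple[float, float]
    left_span_bp: tuple[int, int] = (0, 0)
    right_span_bp: tuple[int, int] = (0, 0)
    extreme_left_id: str = ""
    extreme_right_id: str = ""
    self_overlapping: bool = False

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ScanConfig:
    """Scan parameters.

    r_min: minimum map separation (cM) for a pair to count as long-range and
        the merge radius for patch clustering.
    n_1: patch-count anchor for the reference chromosome; the adaptive
        threshold aims for a SNP-pair-density-matched target on others.
    p_cap: retention cap on scored pairs (memory bound; transparent whenever
        the chosen threshold falls below it).
    """

    r_min: float = 0.25
    n_1: int = 250
    n_snps_ref: int | None = None  # None: this chromosome is the reference
    p_cap: float = 1e-4
    mean_mode: str = "arithmetic"


@dataclass
class ScanResult:
    threshold: float
    patches: list[Patch]
    pd_max: float
    n_p: int
    r_min: float
    n_target: int
    n_pairs_scored: int = 0
    n_pairs_retained: int = 0
    config: ScanConfig = field(default_factory=ScanConfig)


def eligible_pair_mask(cm: np.ndarray, r_min: float) -> np.ndarray:
    """Boolean upper-triangular mask of pairs with cm distance strictly > r_min."""
    if r_min < 0:
        raise ValueError("r_min must be non-negative")
    cm = np.asarray(cm, dtype=float)
    dist = cm[None, :] - cm[:, None]
    return dist > r_min  # left-major upper triangle; lower triangle negative


def eligible_pairs(cm, r_min: float):
    """Yield (left, right) index pairs with map distance strictly > r_min.

    ``cm`` may be a Site list or an array of map positions (sorted ascending).
    Deterministic left-major order.
    """
    seq = list(cm)
    if seq and hasattr(seq[0], "cm"):
        seq = [s.cm for s in seq]
    arr = np.asarray(seq, dtype=float)
    mask = eligible_pair_mask(arr, r_min)
    for i, j in zip(*np.nonzero(mask)):
        yield int(i), int(j)


def score_pairs(hm, r_min: float = 0.25, p_cap: float = 1e-4) -> list[PairScore]:
    """Score every eligible pair with p_D; keep those with p <= p_cap.

    The n11 counts for all pairs come from one integer matrix product; p_D is
    then an array lookup in the precomputed tail table for this panel size.
    """
    if not (0 < p_cap <= 1):
        raise ValueError("p_cap must be in (0, 1]")
    cm = hm.cm
    if np.isnan(cm).any():
        raise ValueError("sites have no map coordinates; call attach_map first")
    mask = eligible_pair_mask(cm, r_min)
    pmat = _pair_pvalues(hm.alleles, hm.alleles)
    ii, jj = np.nonzero(mask)
    pv = pmat[ii, jj]
    keep = pv <= p_cap
    logger.info("scored %d pairs, retained %d at p_cap=%g", len(ii), int(keep.sum()), p_cap)
    pairs = [
        PairScore(int(i), int(j), float(p))
        for i, j, p in zip(ii[keep], jj[keep], pv[keep])
    ]
    return pairs


def _pair_pvalues(left_alleles: np.ndarray, right_alleles: np.ndarray) -> np.ndarray:
    """Matrix of p_D for all (left site, right site) pairs.

    Left margins come from ``left_alleles`` columns, right margins from
    ``right_alleles`` columns; both matrices must have the same rows
    (haplotypes).  For the observed data the two are the same matrix; the
    permutation null passes row-shuffled copies.
    """
    n = left_alleles.shape[0]
    table = shared_tail_table(n)
    n11 = left_alleles.T.astype(np.int64) @ right_alleles.astype(np.int64)
    m1 = left_alleles.sum(axis=0, dtype=np.int64)
    m2 = right_alleles.sum(axis=0, dtype=np.int64)
    return table.lookup(m1[:, None], m2[None, :], n11)


class _DisjointSet:
    def __init__(self) -> None:
        self.parent: list[int] = []
        self.n_components = 0

    def add(self) -> int:
        self.parent.append(len(self.parent))
        self.n_components += 1
        return len(self.parent) - 1

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
            self.n_components -= 1


def _mergeable_matrix(lcm: np.ndarray, rcm: np.ndarray, r_min: float) -> np.ndarray:
    """Pairwise direct-merge relation: both endpoint gaps strictly < r_min."""
    dl = np.abs(lcm[:, None] - lcm[None, :])
    dr = np.abs(rcm[:, None] - rcm[None, :])
    return (dl < r_min) & (dr < r_min)


def build_patches(
    pairs: list[PairScore],
    threshold: float,
    r_min: float,
    cm: np.ndarray | None = None,
    hm=None,
) -> list[Patch]:
    """Cluster pairs with p <= threshold into patches (single linkage).

    ``cm`` maps site index → map position; it may be omitted when ``hm`` is
    given.  When ``hm`` is given, patch spans and extreme-pair ids are filled
    from its sites.
    """
    if hm is not None and cm is None:
        cm = hm.cm
    if cm is None:
        raise ValueError("need site cm coordinates (pass cm= or hm=)")
    cm = np.asarray(cm, dtype=float)
    kept = [p for p in pairs if p.p <= threshold]
    if not kept:
        return []
    lcm = cm[[p.left for p in kept]]
    rcm = cm[[p.right for p in kept]]
    adj = _mergeable_matrix(lcm, rcm, r_min)
    ds = _DisjointSet()
    for _ in kept:
        ds.add()
    ii, jj = np.nonzero(np.triu(adj, k=1))
    for a, b in zip(ii, jj):
        ds.union(int(a), int(b))
    groups: dict[int, list[int]] = {}
    for k in range(len(kept)):
        groups.setdefault(ds.find(k), []).append(k)
    patches = [
        _make_patch([kept[k] for k in members], cm, hm, r_min)
        for members in groups.values()
    ]
    # deterministic report order: by leftmost member position, then min_p
    patches.sort(key=lambda p: (p.left_span_cm[0], p.right_span_cm[0], p.min_p))
    return patches


def _make_patch(members: list[PairScore], cm: np.ndarray, hm, r_min: float) -> Patch:
    min_p = min(m.p for m in members)
    # deterministic tie-break: lexicographically smallest (left, right) minimizer
    extreme = min((m for m in members if m.p == min_p), key=lambda m: (m.left, m.right))
    li = [m.left for m in members]
    ri = [m.right for m in members]
    lspan = (float(np.min(cm[li])), float(np.max(cm[li])))
    rspan = (float(np.min(cm[ri])), float(np.max(cm[ri])))
    overlapping = lspan[1] >= rspan[0]
    if overlapping:
        logger.warning("patch spans overlap near the r_min boundary; flagged")
    patch = Patch(
        members=sorted(members, key=lambda m: (m.left, m.right)),
        min_p=min_p,
        extreme_pair=extreme,
        left_span_cm=lspan,
        right_span_cm=rspan,
        self_overlapping=overlapping,
    )
    if hm is not None:
        bp = hm.bp
        patch.left_span_bp = (int(np.min(bp[li])), int(np.max(bp[li])))
        patch.right_span_bp = (int(np.min(bp[ri])), int(np.max(bp[ri])))
        patch.extreme_left_id = hm.sites[extreme.left].id
        patch.extreme_right_id = hm.sites[extreme.right].id
    return patch


def patch_count_trajectory(
    pairs: list[PairScore], r_min: float, cm: np.ndarray
) -> list[tuple[float, int]]:
    """Patch count at each distinct p value, built incrementally.

    Pairs are added in ascending p to a disjoint-set structure; after all
    pairs sharing a p value are in, the component count equals
    ``len(build_patches(pairs, threshold=p, r_min))``.
    """
    cm = np.asarray(cm, dtype=float)
    order = sorted(range(len(pairs)), key=lambda k: pairs[k].p)
    ds = _DisjointSet()
    lcm = np.empty(len(pairs))
    rcm = np.empty(len(pairs))
    out: list[tuple[float, int]] = []
    added = 0
    for pos, k in enumerate(order):
        pr = pairs[k]
        idx = ds.add()
        lcm[idx] = cm[pr.left]
        rcm[idx] = cm[pr.right]
        if added:
            hit = np.nonzero(
                (np.abs(lcm[:added] - lcm[idx]) < r_min)
                & (np.abs(rcm[:added] - rcm[idx]) < r_min)
            )[0]
            for h in hit:
                ds.union(int(h), idx)
        added += 1
        is_last_of_value = pos + 1 == len(order) or pairs[order[pos + 1]].p != pr.p
        if is_last_of_value:
            out.append((pr.p, ds.n_components))
    return out


def choose_threshold(
    pairs: list[PairScore], r_min: float, n_target: int, cm: np.ndarray
) -> float:
    """Adaptive threshold p*: the candidate whose patch count is closest to
    ``n_target``; ties broken toward the smaller (more conservative) value.

    Candidates are the distinct p values present.  The count is not monotone
    in the threshold (adding pairs can merge patches), so the full incremental
    trajectory is scanned.
    """
    if not pairs:
        raise ValueError(
            "no scored pairs below p_cap; re-run the scan with a larger p_cap"
        )
    traj = patch_count_trajectory(pairs, r_min, cm)
    best_p, best_gap = None, None
    for p, count in traj:
        gap = abs(count - n_target)
        if best_gap is None or gap < best_gap:  # ties keep the earlier (smaller) p
            best_p, best_gap = p, gap
    return float(best_p)


def patch_target(n_snps: int, n_snps_ref: int, n_1: int) -> int:
    """Patch-count target preserving patch density per SNP pair.

    The number of site pairs grows quadratically in the SNP count, so the
    target scales as n_1 · (n_snps / n_snps_ref)², anchored at n_1 for the
    reference chromosome, floored at 1.  Round half away from zero.
    """
    if min(n_snps, n_snps_ref, n_1) <= 0:
        raise ValueError("all arguments must be positive")
    return max(1, int(n_1 * (n_snps / n_snps_ref) ** 2 + 0.5))


def statistic_pd_max(patches: list[Patch], mode: str = "arithmetic") -> float:
    """Mean over patches of each patch's smallest p_D.

    ``mode='geometric'`` returns exp(mean ln min_p) instead; patch minima span
    many orders of magnitude, and the geometric mean weights them evenly on
    the log scale.
    """
    if not patches:
        raise ValueError("no patches")
    minima = np.array([p.min_p for p in patches])
    if mode == "arithmetic":
        return float(minima.mean())
    if mode == "geometric":
        return float(np.exp(np.mean(np.log(minima))))
    raise ValueError(f"unknown mode {mode!r}")


def scan_chromosome(hm, config: ScanConfig | None = None) -> ScanResult:
    """Full deterministic scan: score → target → threshold → patches → stats."""
    cfg = config or ScanConfig()
    cm = hm.cm
    mask = eligible_pair_mask(cm, cfg.r_min)
    n_scored = int(mask.sum())
    pairs = score_pairs(hm, cfg.r_min, cfg.p_cap)
    n_ref = cfg.n_snps_ref if cfg.n_snps_ref is not None else hm.n_site
    n_target = patch_target(hm.n_site, n_ref, cfg.n_1)
    threshold = choose_threshold(pairs, cfg.r_min, n_target, cm)
    patches = build_patches(pairs, threshold, cfg.r_min, hm=hm)
    return ScanResult(
        threshold=threshold,
        patches=patches,
        pd_max=statistic_pd_max(patches, cfg.mean_mode),
        n_p=len(patches),
        r_min=cfg.r_min,
        n_target=n_target,
        n_pairs_scored=n_scored,
        n_pairs_retained=len(pairs),
        config=cfg,
    )
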