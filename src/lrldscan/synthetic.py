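"""Synthetic phased haplotype panels with controllable LD structure.

Three ingredients, all seeded and reproducible:

* a **founder mosaic** background: every sample haplotype is a piecewise copy
  of a small founder set, switching founders between adjacent sites with
  probability 1 − exp(−switch_rate·Δcm).  Short-range LD decays with map
  distance at a tunable rate while widely separated sites are asymptotically
  independent — the background a long-range LD scan should call negative;
* **planted associations**: the contents of a block of columns around one
  site are re-ordered among haplotypes so that two distant sites reach a
  target allele correlation.  Because planting is a row permutation of a
  sub-block, every single-site allele frequency and all within-block LD are
  preserved exactly — only the cross-block association changes;
* an **admixture mode**: haplotypes drawn from one of two populations whose
  per-site frequencies differ by a divergence parameter, producing the
  genome-wide LD between all frequency-differentiated pairs that population
  mixing generates.

Default panel dimensions follow the kind of reference panel the method is
aimed at: 120 phased haplotypes; the synthetic map uses a fixed 1 cM/Mb
physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotype_io import HaplotypeMatrix, Site

__all__ = [
    "SimConfig",
    "PlantedAssociation",
    "feasible_planted_pair",
    "generate_map_sites",
    "generate_founder_mosaic",
    "plant_association",
    "generate_admixed",
    "simulate",
]


@dataclass(frozen=True)
class PlantedAssociation:
    """Ground-truth long-range association between two site indices."""

    site_a: int
    site_b: int
    strength: float  # target allele correlation in [0, 1]

    def __post_init__(self) -> None:
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must be in [0, 1]")


@dataclass
class SimConfig:
    """Panel-generation parameters.

    switch_rate_per_cm controls LD decay: the expected number of founder
    switches per cM along a haplotype.  At the default rate of 2/cM the
    background correlation between sites is negligible beyond a few cM,
    comfortably inside the 0.25 cM long-range cutoff.
    """

    n_hap: int = 120
    n_snp: int = 300
    map_length_cm: float = 50.0
    n_founders: int = 20
    switch_rate_per_cm: float = 2.0
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    spacing: str = "uniform"
    planted: list[PlantedAssociation] = field(default_factory=list)
    plant_block_half_width_cm: float = 0.4
    admixture: tuple[float, float] | None = None  # (proportion, divergence)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.founder_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("founder_freq_range must satisfy 0 < low <= high < 1")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")
        if self.switch_rate_per_cm < 0:
            raise ValueError("switch rate must be non-negative")


_BP_PER_CM = 1_000_000  # fixed 1 cM/Mb synthetic physical scale


def generate_map_sites(
    n_snp: int,
    map_length_cm: float,
    spacing: str = "uniform",
    rng: np.random.Generator | None = None,
) -> list[Site]:
    """Sites spanning [0, map_length_cm]; bp = round(cm · 1e6), 1-based."""
    if n_snp < 2:
        raise ValueError("need at least 2 sites")
    if spacing == "uniform":
        cms = np.linspace(0.0, map_length_cm, n_snp)
    elif spacing == "random":
        if rng is None:
            raise ValueError("random spacing needs an rng")
        inner = np.sort(rng.uniform(0.0, map_length_cm, size=n_snp - 2))
        cms = np.concatenate([[0.0], inner, [map_length_cm]])
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    bps = np.maximum(1, np.rint(cms * _BP_PER_CM).astype(np.int64))
    for k in range(1, n_snp):  # enforce strictly increasing bp

        if bps[k] <= bps[k - 1]:
            bps[k] = bps[k - 1] + 1
    return [Site(f"s{k + 1:05d}", int(bps[k]), float(cms[k])) for k in range(n_snp)]


def generate_founder_mosaic(cfg: SimConfig) -> HaplotypeMatrix:
    """Founder-mosaic panel: short-range LD decaying with map distance."""
    rng = np.random.default_rng(cfg.seed)
    sites = generate_map_sites(cfg.n_snp, cfg.map_length_cm, cfg.spacing, rng)
    cms = np.array([s.cm for s in sites])
    freqs = rng.uniform(*cfg.founder_freq_range, size=cfg.n_snp)
    founders = (rng.random((cfg.n_founders, cfg.n_snp)) < freqs).astype(np.int8)
    switch_p = 1.0 - np.exp(-cfg.switch_rate_per_cm * np.diff(cms))
    alleles = np.empty((cfg.n_hap, cfg.n_snp), dtype=np.int8)
    for h in range(cfg.n_hap):
        f = rng.integers(cfg.n_founders)
        for k in range(cfg.n_snp):
            if k and rng.random() < switch_p[k - 1]:
                f = rng.integers(cfg.n_founders)
            alleles[h, k] = founders[f, k]
    hm = HaplotypeMatrix(
        alleles, sites, [f"H{k + 1:04d}" for k in range(cfg.n_hap)], "chrS"
    )
    return hm.drop_monomorphic()


def _achievable_n11(a: np.ndarray, b: np.ndarray, strength: float) -> int:
    """Smallest 1–1 count giving corr(a, b) >= strength, or raise."""
    n = len(a)
    ka, kb = int(a.sum()), int(b.sum())
    denom = np.sqrt(ka * (n - ka) * kb * (n - kb))
    lo = max(0, ka + kb - n)
    for n11 in range(lo, min(ka, kb) + 1):
        corr = (n * n11 - ka * kb) / denom
        if corr >= strength:
            return n11
    raise ValueError(
        "target strength infeasible for the realized allele frequencies; "
        "lower the strength or regenerate the panel"
    )


def feasible_planted_pair(
    hm: HaplotypeMatrix, min_gap_cm: float, strength: float
) -> tuple[int, int]:
    """Deterministically pick a site pair separated by more than ``min_gap_cm``
    whose allele frequencies can support a planted correlation >= strength.

    Only pairs where both minor allele counts are at least n/4 are
    considered: a planted correlation between near-fixed sites carries almost
    no exact-test evidence (a perfectly coupled pair at allele count n−1 has
    p_D = 1/n), so power requires intermediate frequencies.  Among qualifying
    pairs the one with the largest achievable correlation wins (ties:
    smallest indices).
    """
    n = hm.n_hap
    k = hm.allele_counts().astype(float)
    cm = hm.cm
    gap_ok = (cm[None, :] - cm[:, None]) > min_gap_cm
    balanced = (k >= n / 4) & (k <= 3 * n / 4)
    kmin = np.minimum(k[:, None], k[None, :])
    denom = np.sqrt(k * (n - k))
    with np.errstate(invalid="ignore"):
        max_corr = (n * kmin - k[:, None] * k[None, :]) / (denom[:, None] * denom[None, :])
    max_corr[~(gap_ok & balanced[:, None] & balanced[None, :])] = -np.inf
    i, j = np.unravel_index(int(np.argmax(max_corr)), max_corr.shape)
    if max_corr[i, j] < strength:
        raise ValueError("no site pair supports the requested strength at this gap")
    return int(i), int(j)


def plant_association(
    hm: HaplotypeMatrix,
    pa: PlantedAssociation,
    block_half_width_cm: float = 0.4,
    rng: np.random.Generator | None = None,
) -> HaplotypeMatrix:
    """Re-order the block around site_b so corr(site_a, site_b) >= strength.

    The permutation moves whole rows of the sub-block of columns within
    ``block_half_width_cm`` of site_b, so allele frequencies everywhere and
    LD within the block are untouched; the blocks around the two sites must
    be disjoint.  ``strength=0`` is the identity (panel returned unchanged).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    cm = hm.cm
    gap = abs(cm[pa.site_b] - cm[pa.site_a])
    if gap <= 2 * block_half_width_cm:
        raise ValueError("blocks around the two sites overlap; reduce half width")
    if pa.strength == 0:
        return HaplotypeMatrix(
            hm.alleles.copy(), list(hm.sites), list(hm.haplotype_ids), hm.chromosome
        )
    a = hm.alleles[:, pa.site_a]
    b = hm.alleles[:, pa.site_b]
    n11 = _achievable_n11(a, b, pa.strength)
    # assign source rows (by their b allele) to target rows (by their a allele)
    src_b1 = np.flatnonzero(b == 1)
    src_b0 = np.flatnonzero(b == 0)
    tgt_a1 = np.flatnonzero(a == 1)
    tgt_a0 = np.flatnonzero(a == 0)
    rng.shuffle(src_b1)
    rng.shuffle(src_b0)
    rng.shuffle(tgt_a1)
    rng.shuffle(tgt_a0)
    perm = np.empty(hm.n_hap, dtype=np.int64)
    perm[tgt_a1[:n11]] = src_b1[:n11]
    perm[tgt_a0[: len(src_b1) - n11]] = src_b1[n11:]
    rest = np.concatenate([tgt_a1[n11:], tgt_a0[len(src_b1) - n11 :]])
    perm[rest] = src_b0
    block = np.flatnonzero(np.abs(cm - cm[pa.site_b]) <= block_half_width_cm)
    alleles = hm.alleles.copy()
    alleles[:, block] = hm.alleles[perm][:, block]
    return HaplotypeMatrix(alleles, list(hm.sites), list(hm.haplotype_ids), hm.chromosome)


def generate_admixed(cfg: SimConfig) -> HaplotypeMatrix:
    """Two-population admixture panel: genome-wide LD from frequency contrast.

    Per-site frequencies for the two sources sit ±divergence/2 around a
    common uniform draw (clipped to (0.02, 0.98)); each haplotype comes
    entirely from source 1 with the given proportion, sites independent
    within a source.
    """
    if cfg.admixture is None:
        raise ValueError("cfg.admixture must be set")
    proportion, divergence = cfg.admixture
    if not 0 <= proportion <= 1:
        raise ValueError("admixture proportion must be in [0, 1]")
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(cfg.seed)
    sites = generate_map_sites(cfg.n_snp, cfg.map_length_cm, cfg.spacing, rng)
    base = rng.uniform(*cfg.founder_freq_range, size=cfg.n_snp)
    p1 = np.clip(base - divergence / 2, 0.02, 0.98)
    p2 = np.clip(base + divergence / 2, 0.02, 0.98)
    src = rng.random(cfg.n_hap) < proportion
    freqs = np.where(src[:, None], p1[None, :], p2[None, :])
    alleles = (rng.random((cfg.n_hap, cfg.n_snp)) < freqs).astype(np.int8)
    hm = HaplotypeMatrix(
        alleles, sites, [f"H{k + 1:04d}" for k in range(cfg.n_hap)], "chrS"
    )
    return hm.drop_monomorphic()


def simulate(cfg: SimConfig) -> HaplotypeMatrix:
    """Generate a panel per the config: admixed or founder-mosaic background,
    then any planted associations (site indices refer to the filtered panel)."""
    hm = generate_admixed(cfg) if cfg.admixture is not None else generate_founder_mosaic(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    for pa in cfg.planted:
        hm = plant_association(hm, pa, cfg.plant_block_half_width_cm, rng)
    return hm
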