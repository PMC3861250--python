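"""Phased-haplotype, genetic-map and interval I/O.

Supported inputs are phased biallelic VCF, IMPUTE-style ``.hap``/``.legend``
pairs, HapMap-format genetic maps (position, rate in cM/Mb, cumulative cM)
and BED interval files.  The in-memory containers are deliberately small:
a binary allele matrix with per-site physical (bp, 1-based) and genetic
(cumulative cM) coordinates, a monotone physical→genetic interpolation table,
and a list of half-open intervals.

Panels must be complete (no missing genotypes) and phased: the exact test at
the core of the method operates on fully observed 2×2 haplotype tables, and
the intended inputs (reference phased panels) satisfy both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "HaplotypeMatrix",
    "GeneticMap",
    "RegionSet",
    "read_phased_vcf",
    "read_hap_legend",
    "read_genetic_map",
    "attach_map",
    "subset_haplotypes",
    "read_regions",
    "write_patches",
    "read_patches",
    "write_hap_legend",
    "write_genetic_map",
]


@dataclass(frozen=True)
class Site:
    """One biallelic site: text id, 1-based physical bp, cumulative cM."""

    id: str
    bp: int
    cm: float = np.nan

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError(f"site {self.id}: bp must be >= 1")


@dataclass
class HaplotypeMatrix:
    """Binary allele matrix, haplotypes × sites, with site coordinates.

    Every retained column is polymorphic (both alleles observed) and columns
    are ordered by physical position.  Allele 0 is the reference / first
    legend allele; the exact-test statistic is invariant to that labeling.
    """

    alleles: np.ndarray
    sites: list[Site]
    haplotype_ids: list[str]
    chromosome: str = "chr"

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape != (len(self.haplotype_ids), len(self.sites)):
            raise ValueError("allele matrix shape does not match ids/sites")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        bp = self.bp
        if np.any(np.diff(bp) < 0):
            raise ValueError("sites must be ordered by physical position")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_site(self) -> int:
        return self.alleles.shape[1]

    @property
    def bp(self) -> np.ndarray:
        return np.array([s.bp for s in self.sites], dtype=np.int64)

    @property
    def cm(self) -> np.ndarray:
        return np.array([s.cm for s in self.sites], dtype=float)

    def allele_counts(self) -> np.ndarray:
        """Allele-1 count per site."""
        return self.alleles.sum(axis=0, dtype=np.int64)

    def drop_monomorphic(self) -> "HaplotypeMatrix":
        counts = self.allele_counts()
        keep = (counts >= 1) & (counts <= self.n_hap - 1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d monomorphic site(s)", dropped)
        return HaplotypeMatrix(
            self.alleles[:, keep],
            [s for s, k in zip(self.sites, keep) if k],
            list(self.haplotype_ids),
            self.chromosome,
        )


@dataclass(frozen=True)
class GeneticMap:
    """Monotone physical→genetic interpolation table.

    ``anchors`` is an ordered list of (bp, cumulative cM) pairs with strictly
    increasing bp and non-decreasing cM.
    """

    anchors: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("genetic map needs at least two anchors")
        bp = np.array([a[0] for a in self.anchors])
        cm = np.array([a[1] for a in self.anchors])
        if np.any(np.diff(bp) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    @property
    def bp(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors], dtype=np.int64)

    @property
    def cm(self) -> np.ndarray:
        return np.array([a[1] for a in self.anchors], dtype=float)

    def interpolate(self, positions) -> np.ndarray:
        """cM at physical positions; linear between anchors, terminal-rate
        extrapolation outside the anchor range, floored at 0 cM."""
        pos = np.asarray(positions, dtype=float)
        bp, cm = self.bp.astype(float), self.cm
        out = np.interp(pos, bp, cm)
        lo_rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
        hi_rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        left = pos < bp[0]
        right = pos > bp[-1]
        out = np.where(left, cm[0] + (pos - bp[0]) * lo_rate, out)
        out = np.where(right, cm[-1] + (pos - bp[-1]) * hi_rate, out)
        return np.maximum(out, 0.0)

    def invert(self, cms) -> np.ndarray:
        """Physical position at cumulative cM (piecewise-linear inverse;
        within flat map segments the leftmost bp is returned)."""
        c = np.asarray(cms, dtype=float)
        bp, cm = self.bp.astype(float), self.cm
        out = np.interp(c, cm, bp)
        lo_rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
        hi_rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        if lo_rate > 0:
            out = np.where(c < cm[0], bp[0] + (c - cm[0]) / lo_rate, out)
        if hi_rate > 0:
            out = np.where(c > cm[-1], bp[-1] + (c - cm[-1]) / hi_rate, out)
        return out


@dataclass
class RegionSet:
    """Genomic intervals in BED convention: 0-based, half-open; may overlap."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def for_chromosome(self, chrom: str) -> "RegionSet":
        return RegionSet([iv for iv in self.intervals if iv[0] == chrom])


def read_phased_vcf(path: str, chromosome: str) -> HaplotypeMatrix:
    """Read phased biallelic SNVs for one chromosome from a VCF.

    Unphased or missing genotypes are hard errors: the method requires a
    complete phased panel.  Monomorphic and multiallelic records are dropped
    (count logged).  cm coordinates are left unset; use :func:`attach_map`.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    hap_ids = [f"{s}_{k}" for s in samples for k in (0, 1)]
    cols: list[np.ndarray] = []
    sites: list[Site] = []
    dropped = 0
    for rec in vcf:
        if rec.CHROM != chromosome:
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            dropped += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for si, g in enumerate(rec.genotypes):
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype at {rec.CHROM}:{rec.POS} sample {samples[si]}"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype at {rec.CHROM}:{rec.POS} sample {samples[si]}"
                )
            col[2 * si] = a0
            col[2 * si + 1] = a1
        s = int(col.sum())
        if s == 0 or s == len(col):
            dropped += 1
            continue
        sites.append(Site(rec.ID or f"{rec.CHROM}:{rec.POS}", rec.POS))
        cols.append(col)
    if dropped:
        logger.info("dropped %d monomorphic/multiallelic record(s)", dropped)
    alleles = np.stack(cols, axis=1) if cols else np.empty((len(hap_ids), 0), np.int8)
    order = np.argsort([s.bp for s in sites], kind="stable")
    return HaplotypeMatrix(
        alleles[:, order], [sites[k] for k in order], hap_ids, chromosome
    )


def read_hap_legend(
    hap_path: str, legend_path: str, chromosome: str = "chr"
) -> HaplotypeMatrix:
    """Read an IMPUTE-style .hap (0/1 matrix, sites × haplotypes) + .legend pair.

    The legend has a header line and columns ``id position allele0 allele1``.
    Haplotype ids are synthesized as H0001, H0002, …
    """
    sites: list[Site] = []
    with open(legend_path) as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{legend_path}: empty legend")
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{legend_path}:{ln}: expected id and position")
            sites.append(Site(parts[0], int(parts[1])))
    rows: list[np.ndarray] = []
    with open(hap_path) as fh:
        for ln, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if any(t not in ("0", "1") for t in toks):
                raise ValueError(f"{hap_path}:{ln}: non-binary haplotype token")
            rows.append(np.array(toks, dtype=np.int8))
    if len(rows) != len(sites):
        raise ValueError(
            f"legend has {len(sites)} site(s) but hap file has {len(rows)} row(s)"
        )
    if rows and any(len(r) != len(rows[0]) for r in rows):
        raise ValueError(f"{hap_path}: ragged rows")
    mat = np.stack(rows, axis=1) if rows else np.empty((0, 0), np.int8)
    hap_ids = [f"H{k + 1:04d}" for k in range(mat.shape[0])]
    order = np.argsort([s.bp for s in sites], kind="stable")
    hm = HaplotypeMatrix(mat[:, order], [sites[k] for k in order], hap_ids, chromosome)
    return hm.drop_monomorphic()


def write_hap_legend(hm: HaplotypeMatrix, hap_path: str, legend_path: str) -> None:
    with open(legend_path, "w") as fh:
        fh.write("id position a0 a1\n")
        for s in hm.sites:
            fh.write(f"{s.id} {s.bp} A G\n")
    with open(hap_path, "w") as fh:
        for col in hm.alleles.T:
            fh.write(" ".join(map(str, col)) + "\n")


def read_genetic_map(path: str) -> GeneticMap:
    """Read a HapMap-format map: header line, then position, cM/Mb, cumulative cM."""
    anchors: list[tuple[int, float]] = []
    with open(path) as fh:
        fh.readline()  # header
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            anchors.append((int(parts[0]), float(parts[2])))
    return GeneticMap(tuple(anchors))


def write_genetic_map(gm: GeneticMap, path: str) -> None:
    bp, cm = gm.bp, gm.cm
    with open(path, "w") as fh:
        fh.write("position\trate(cM/Mb)\tcM\n")
        for k in range(len(bp)):
            if k + 1 < len(bp):
                rate = (cm[k + 1] - cm[k]) / (bp[k + 1] - bp[k]) * 1e6
            fh.write(f"{bp[k]}\t{rate:.6f}\t{cm[k]:.6f}\n")


def attach_map(hm: HaplotypeMatrix, gm: GeneticMap) -> HaplotypeMatrix:
    """Return a copy of ``hm`` with site cm set by map interpolation."""
    cms = gm.interpolate(hm.bp)
    sites = [replace(s, cm=float(c)) for s, c in zip(hm.sites, cms)]
    return HaplotypeMatrix(hm.alleles.copy(), sites, list(hm.haplotype_ids), hm.chromosome)


def subset_haplotypes(hm: HaplotypeMatrix, keep: list[str]) -> HaplotypeMatrix:
    """Restrict to the named haplotypes, re-filtering monomorphic sites.

    Used e.g. to drop one individual from each known relative pair before
    re-running a scan.
    """
    index = {h: k for k, h in enumerate(hm.haplotype_ids)}
    unknown = [h for h in keep if h not in index]
    if unknown:
        raise ValueError(f"unknown haplotype id(s): {unknown}")
    if len(keep) < 4:
        raise ValueError("need at least 4 haplotypes")
    rows = [index[h] for h in keep]
    sub = HaplotypeMatrix(
        hm.alleles[rows, :], list(hm.sites), list(keep), hm.chromosome
    )
    return sub.drop_monomorphic()


def read_regions(path: str) -> RegionSet:
    """Read BED (3+ columns); malformed lines error with their line number."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            intervals.append((parts[0], start, end))
    return RegionSet(intervals)


_PATCH_COLUMNS = [
    "chromosome",
    "left_bp_min", "left_bp_max", "right_bp_min", "right_bp_max",
    "left_cm_min", "left_cm_max", "right_cm_min", "right_cm_max",
    "n_pairs", "min_p", "extreme_left_id", "extreme_right_id",
]


def write_patches(patches, path: str, chromosome: str = "chr") -> None:
    """Write a tab-delimited patch table with a commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_PATCH_COLUMNS) + "\n")
        for p in patches:
            row = [
                chromosome,
                *map(str, [*p.left_span_bp, *p.right_span_bp]),
                *(f"{v:.10g}" for v in [*p.left_span_cm, *p.right_span_cm]),
                str(len(p.members)),
                f"{p.min_p:.12e}",
                p.extreme_left_id,
                p.extreme_right_id,
            ]
            fh.write("\t".join(row) + "\n")


def read_patches(path: str):
    """Read a patch table back as a pandas DataFrame (round-trip of write_patches)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment=None, header=0)
    df.columns = _PATCH_COLUMNS
    return df
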