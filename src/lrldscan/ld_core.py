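"""Exact-test linkage disequilibrium measure ``p_D`` and map-function utilities.

The central statistic is ``p_D``: the probability, under the hypergeometric
(Fisher exact) sampling distribution that conditions on the observed allele
counts at two sites, of a disequilibrium ``D`` at least as large as the one in
the sample, in the direction of the observed ``D``.  Smaller values of ``p_D``
are stronger evidence of association.  For widely separated sites the two-locus
haplotype sampling distribution converges on this conditional distribution,
which makes ``p_D`` an appropriate long-range LD statistic.

All map-distance conversions use the Kosambi mapping function, which allows
for crossover interference:  r = tanh(2d)/2 with d in Morgans.  Public
interfaces take centimorgans.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "HaplotypeTable2x2",
    "LogFactorialTable",
    "contingency_table",
    "disequilibrium_D",
    "p_D",
    "PDTailTable",
    "kosambi_r_from_cM",
    "kosambi_cM_from_r",
    "scaled_recombination_rho",
]


@dataclass(frozen=True)
class HaplotypeTable2x2:
    """Counts of the four two-site haplotype classes.

    ``n11`` counts haplotypes carrying allele 1 at both sites, ``n10`` allele 1
    at the left site only, and so on.  The row margins (n11+n10, n01+n00) and
    column margins (n11+n01, n10+n00) are the single-site allele counts.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("haplotype counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def margin_left(self) -> int:
        """Allele-1 count at the left site."""
        return self.n11 + self.n10

    @property
    def margin_right(self) -> int:
        """Allele-1 count at the right site."""
        return self.n11 + self.n01


class LogFactorialTable:
    """Lookup table of ln(k!) for k = 0 … n_max.

    A shared table lets every hypergeometric term be assembled purely by
    addition of six precomputed entries, which is what makes scoring billions
    of site pairs feasible.
    """

    def __init__(self, n_max: int):
        if n_max < 0:
            raise ValueError("n_max must be non-negative")
        self.n_max = n_max
        # cumulative sum of ln k; values[0] = ln 0! = 0
        self.values = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n_max + 1)))])

    def __call__(self, k):
        return self.values[k]

    def log_hypergeom_pmf(self, k, m1: int, m2: int, n: int):
        """ln P(X = k) for X hypergeometric with both margins fixed.

        ``m1``/``m2`` are the allele-1 counts at the two sites, ``n`` the
        number of haplotypes; ``k`` is the 1–1 haplotype count (array ok).
        """
        v = self.values
        k = np.asarray(k)
        return (
            v[m1] + v[n - m1] + v[m2] + v[n - m2] - v[n]
            - v[k] - v[m1 - k] - v[m2 - k] - v[n - m1 - m2 + k]
        )


def contingency_table(hm, i: int, j: int) -> HaplotypeTable2x2:
    """Tally the 2×2 haplotype table for map-ordered site indices ``i < j``."""
    if i == j:
        raise ValueError("site indices must differ")
    if i > j:
        raise ValueError("left site index must precede right site index")
    a = hm.alleles[:, i]
    b = hm.alleles[:, j]
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return HaplotypeTable2x2(n11, n10, n01, n00)


def disequilibrium_D(t: HaplotypeTable2x2) -> float:
    """Classical D = freq(11) − freq(1·)·freq(·1); lies in [−0.25, 0.25]."""
    n = t.n
    return t.n11 / n - (t.margin_left / n) * (t.margin_right / n)


def _support(m1: int, m2: int, n: int) -> tuple[int, int]:
    """Range [lo, hi] of feasible 1–1 counts at fixed margins."""
    return max(0, m1 + m2 - n), min(m1, m2)


def p_D(
    t: HaplotypeTable2x2,
    lft: LogFactorialTable | None = None,
    *,
    two_sided: bool = False,
) -> float:
    """Tail probability of Fisher's exact test in the direction of observed D.

    With X the 1–1 haplotype count under the hypergeometric distribution that
    fixes both margins: ``p_D = P(X >= n11)`` when D >= 0, else
    ``P(X <= n11)``.  The observed table is always included, so the result is
    in (0, 1].  The directional tail is invariant to flipping the 0/1 labels
    at both sites simultaneously; flipping at one site reverses D's sign and
    yields the opposite tail.

    ``two_sided=True`` instead sums the probability of every table whose
    point probability does not exceed the observed one (the conventional
    two-sided Fisher rule); it is provided for comparison and is not used by
    the scan.

    Terms are accumulated in log space starting from the most extreme table so
    that very small tails lose no precision.
    """
    n = t.n
    m1, m2 = t.margin_left, t.margin_right
    if m1 == 0 or m1 == n or m2 == 0 or m2 == n:
        raise ValueError("monomorphic site: exact test undefined for degenerate margin")
    if lft is None:
        lft = _shared_lft(n)
    if lft.n_max < n:
        raise ValueError("log-factorial table too small for this sample size")
    lo, hi = _support(m1, m2, n)
    if two_sided:
        ks = np.arange(lo, hi + 1)
        logp = lft.log_hypergeom_pmf(ks, m1, m2, n)
        obs = logp[t.n11 - lo]
        keep = logp <= obs + 1e-7
        return float(min(1.0, np.exp(logsumexp(logp[keep]))))
    # D >= 0 exactly when n*n11 >= m1*m2 (same sign as n11 - E[X])
    if n * t.n11 >= m1 * m2:
        ks = np.arange(hi, t.n11 - 1, -1)  # most extreme first
    else:
        ks = np.arange(lo, t.n11 + 1)
    logp = lft.log_hypergeom_pmf(ks, m1, m2, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


@lru_cache(maxsize=8)
def _shared_lft(n: int) -> LogFactorialTable:
    return LogFactorialTable(max(n, 128))


class PDTailTable:
    """Precomputed ``p_D`` for every table configuration at fixed sample size.

    For a panel of ``n`` haplotypes the value of ``p_D`` depends only on the
    triple (left margin, right margin, n11).  This table stores the
    directional tail for all feasible triples, so a whole-chromosome scan (or
    a permutation replicate) reduces to one integer matrix product for the
    n11 counts followed by an array lookup.

    Memory is (n+1)^3 doubles — about 14 MB at n = 120 — so this path is used
    for panel sizes up to ``max_cube_n``; infeasible triples hold NaN.
    """

    max_cube_n = 400

    def __init__(self, n: int, lft: LogFactorialTable | None = None):
        if n > self.max_cube_n:
            raise ValueError(
                f"tail cube limited to n <= {self.max_cube_n}; use p_D directly"
            )
        self.n = n
        lft = lft if lft is not None else _shared_lft(n)
        cube = np.full((n + 1, n + 1, n + 1), np.nan)
        for m1 in range(1, n):
            for m2 in range(1, n):
                lo, hi = _support(m1, m2, n)
                ks = np.arange(lo, hi + 1)
                logp = lft.log_hypergeom_pmf(ks, m1, m2, n)
                # log-space cumulative tails accumulated from each extreme
                upper = np.logaddexp.accumulate(logp[::-1])[::-1]
                lower = np.logaddexp.accumulate(logp)
                tail = np.where(n * ks >= m1 * m2, upper, lower)
                cube[m1, m2, lo : hi + 1] = np.minimum(1.0, np.exp(tail))
        self.cube = cube

    def lookup(self, m1, m2, n11):
        """Vectorized ``p_D`` lookup; arguments broadcast together."""
        return self.cube[m1, m2, n11]


@lru_cache(maxsize=4)
def shared_tail_table(n: int) -> PDTailTable:
    """Process-wide cache of tail tables keyed by panel size."""
    return PDTailTable(n)


def kosambi_r_from_cM(d) -> float:
    """Map distance (cM) → recombination fraction, Kosambi: r = tanh(2d)/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(out) if out.ndim == 0 else out

def kosambi_cM_from_r(r) -> float:
    """Recombination fraction → map distance (cM), inverse Kosambi."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


def scaled_recombination_rho(n_e: float, r: float) -> float:
    """Population-scaled recombination rate ρ = 4·N_e·r."""
    if n_e <= 0:
        raise ValueError("effective population size must be positive")
    if r < 0:
        raise ValueError("recombination fraction must be non-negative")
    return 4.0 * n_e * r
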