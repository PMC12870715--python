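"""Gene-set overlap and clinical-table group comparisons.

Three procedures:

* hypergeometric overlap enrichment between two gene sets drawn from a
  common background universe (upper-tail or two-sided Fisher), with
  expected overlap K*n/N and fold k*N/(K*n);
* Fisher's exact test on a 2x2 contingency table (solved vs unsolved by
  a binary clinical feature), two-sided by the "tables at most as
  probable" convention;
* a tie-corrected Mann–Whitney U on grouped ordinal severity scales
  (GMFCS/CFCS/EDACS-style I–V classifications stored as per-level counts),
  with median/IQR summaries of the expanded coded values.

The hypergeometric kernel is computed in log space so that extreme
overlaps (p ~ 1e-16 and far beyond) keep full relative precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, ndtr

__all__ = [
    "OverlapSpec",
    "TwoByTwoTable",
    "GroupedOrdinalSample",
    "MwuResult",
    "hypergeom_pmf",
    "overlap_enrichment",
    "fisher_exact_2x2",
    "mwu_grouped",
    "median_iqr_grouped",
]


@dataclass(frozen=True)
class OverlapSpec:
    """Margins of a gene-set overlap: |A| = set_a_n, |B| = set_b_n out of
    universe_n background genes, intersecting in overlap_k."""

    universe_n: int
    set_a_n: int
    set_b_n: int
    overlap_k: int

    def __post_init__(self) -> None:
        if min(self.universe_n, self.set_a_n, self.set_b_n, self.overlap_k) < 0:
            raise ValueError("all overlap counts must be non-negative")
        if self.set_a_n > self.universe_n or self.set_b_n > self.universe_n:
            raise ValueError("set sizes cannot exceed the universe")
        if self.overlap_k > min(self.set_a_n, self.set_b_n):
            raise ValueError("overlap cannot exceed either set size")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts [[a, b], [c, d]]; rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class GroupedOrdinalSample:
    """Two groups over ordered severity levels, stored as per-level counts.

    ``levels`` are the numeric codes (e.g. I–V as 1..5); counts are
    parallel per-level tallies for the two groups.
    """

    levels: tuple[float, ...]
    counts_group1: tuple[int, ...]
    counts_group2: tuple[int, ...]

    def __post_init__(self) -> None:
        if not len(self.levels) == len(self.counts_group1) == len(self.counts_group2):
            raise ValueError("levels and both count vectors must have equal length")
        if min(self.counts_group1 + self.counts_group2, default=0) < 0:
            raise ValueError("counts must be non-negative")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be sorted ascending")

    @property
    def n1(self) -> int:
        return int(sum(self.counts_group1))

    @property
    def n2(self) -> int:
        return int(sum(self.counts_group2))


@dataclass(frozen=True)
class MwuResult:
    u_stat: float
    z_score: float
    p_two_sided: float
    median_iqr_group1: tuple[float, float, float]
    median_iqr_group2: tuple[float, float, float]


def _log_choose(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P(X = k) drawing n from N with K marked: C(K,k) C(N-K,n-k) / C(N,n).

    Returns 0 for infeasible k rather than raising.
    """
    if K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError("invalid hypergeometric margins")
    if k > min(K, n) or k < max(0, n - (N - K)):
        return 0.0
    return float(
        math.exp(_log_choose(K, k) + _log_choose(N - K, n - k) - _log_choose(N, n))
    )


def _hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    if k <= max(0, n - (N - K)):
        return 1.0  # whole feasible range
    hi = min(K, n)
    return min(1.0, sum(hypergeom_pmf(j, K, n, N) for j in range(k, hi + 1)))


def _fisher_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Sum of pmf over tables at most as probable as the observed one.

    A 1e-7 relative tolerance absorbs floating-point ties, the dominant
    software convention for this test.
    """
    observed = hypergeom_pmf(k, K, n, N)
    lo, hi = max(0, n - (N - K)), min(K, n)
    cutoff = observed * (1.0 + 1e-7)
    return min(
        1.0,
        sum(
            pmf
            for j in range(lo, hi + 1)
            if (pmf := hypergeom_pmf(j, K, n, N)) <= cutoff
        ),
    )


def overlap_enrichment(
    spec: OverlapSpec, sidedness: str = "two-sided"
) -> tuple[float, float, float]:
    """Overlap p-value, fold enrichment, and expected chance overlap.

    fold = k * N / (K * n); p is the upper-tail hypergeometric for
    ``"upper"`` or the two-sided Fisher probability for ``"two-sided"``.
    """
    N, K, n, k = spec.universe_n, spec.set_a_n, spec.set_b_n, spec.overlap_k
    if K == 0 or n == 0:
        raise ValueError("both gene sets must be non-empty")
    expected = K * n / N
    fold = k / expected
    if sidedness == "upper":
        p = _hypergeom_upper_tail(k, K, n, N)
    elif sidedness == "two-sided":
        p = _fisher_two_sided(k, K, n, N)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return p, fold, expected


def fisher_exact_2x2(
    table: TwoByTwoTable, sidedness: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test conditioned on both margins.

    Returns (p, sample odds ratio a*d/(b*c)). ``sidedness`` is
    ``"two-sided"`` (tables at most as probable) or ``"upper"``
    (P(X >= a) for the top-left cell).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    K, n = a + b, a + c  # row-1 margin, column-1 margin
    if sidedness == "upper":
        p = _hypergeom_upper_tail(a, K, n, N)
    elif sidedness == "two-sided":
        p = _fisher_two_sided(a, K, n, N)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return p, table.odds_ratio


def median_iqr_grouped(
    levels: Sequence[float], counts: Sequence[int]
) -> tuple[float, float, float]:
    """(median, q1, q3) of grouped ordinal data, by linear interpolation
    of order statistics (position (g - 1) q + 1 in the sorted sample)."""
    counts = np.asarray(counts, dtype=int)
    if counts.sum() == 0:
        raise ValueError("cannot summarise an empty group")
    values = np.repeat(np.asarray(levels, dtype=float), counts)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def mwu_grouped(sample: GroupedOrdinalSample) -> MwuResult:
    """Two-sided Mann–Whitney U on grouped ordinal data with tie correction.

    Midranks are assigned per level over the pooled sample; the rank sum
    of group 1 gives U = R1 - n1(n1+1)/2. The normal approximation uses
    the tie-corrected variance

        sigma^2 = (n1 n2 / 12) [ (N + 1) - sum(t^3 - t) / (N (N - 1)) ]

    over level tie-blocks of size t, with no continuity correction.
    """
    c1 = np.asarray(sample.counts_group1, dtype=float)
    c2 = np.asarray(sample.counts_group2, dtype=float)
    n1, n2 = c1.sum(), c2.sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    t = c1 + c2
    N = n1 + n2
    cumulative = np.cumsum(t)
    midranks = cumulative - t / 2.0 + 0.5
    r1 = float((c1 * midranks).sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    tie_term = float(((t**3 - t)).sum()) / (N * (N - 1))
    variance = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if variance <= 0:  # all observations tied on one level
        z, p = 0.0, 1.0
    else:
        z = (u - n1 * n2 / 2.0) / math.sqrt(variance)
        p = float(min(1.0, 2.0 * (1.0 - ndtr(abs(z)))))
    return MwuResult(
        u_stat=float(u),
        z_score=float(z),
        p_two_sided=p,
        median_iqr_group1=median_iqr_grouped(sample.levels, sample.counts_group1),
        median_iqr_group2=median_iqr_grouped(sample.levels, sample.counts_group2),
    )
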