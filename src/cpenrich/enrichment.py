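"""Enrichment tests for gene–cerebral-palsy association.

Two complementary tests form the core of the framework:

* **Poisson test over pooled diagnostic cohorts.** Under the null, each of
  the S solved individuals is equally likely to carry a causal variant in
  any of the G candidate genes, so a gene's pooled count k is Poisson with
  rate lambda = S / G, and the evidence for enrichment is the upper tail
  P(X >= k) = 1 - F(k - 1; lambda). Benjamini–Hochberg adjustment is
  applied across the tested genes.

* **Binomial test over gene-specific literature cohorts.** For a gene with
  n published individuals carrying causal variants, x of whom have CP, the
  null is x ~ Binomial(n, p0) with p0 the population prevalence of CP
  (default 0.003). The headline statistic is the point probability of the
  observed count (the R ``dbinom`` value); the upper tail P(X >= x) is
  computed alongside it.

Effect size is reported as fold-change fc = observed / expected and
percent enrichment (fc - 1) * 100.

All tail and pmf computations run in log space (log-gamma), so counts like
55/405 at p0 = 0.003 (pmf ~ 1e-71) are exact to double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .cohorts import GeneLitCohort, NgsAggregate
from .ontology import CandidateUniverse

__all__ = [
    "PoissonNull",
    "BinomialNull",
    "EnrichmentResult",
    "poisson_upper_tail",
    "log_binomial_pmf",
    "binomial_upper_tail",
    "bh_adjust",
    "bonferroni_adjust",
    "fold_and_enrichment",
    "run_ngs_enrichment",
    "run_gene_lit_enrichment",
]


@dataclass(frozen=True)
class PoissonNull:
    """Per-gene expected count under equal assignment of solved cases.

    lambda = n_solved / universe_size.
    """

    n_solved: int
    universe_size: int

    def __post_init__(self) -> None:
        if self.n_solved <= 0 or self.universe_size <= 0:
            raise ValueError("n_solved and universe_size must be positive")

    @property
    def lam(self) -> float:
        return self.n_solved / self.universe_size


@dataclass(frozen=True)
class BinomialNull:
    """Background phenotype prevalence p0 for the literature-cohort test."""

    p0: float = 0.003

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-gene statistic bundle.

    ``observed`` is the pooled count k on the Poisson side, or the pair
    (n_cp, n_total) on the binomial side. ``p_point`` is the binomial point
    probability (None on the Poisson side); ``p_raw`` is the upper-tail
    p-value there and the headline statistic otherwise.
    """

    gene: str
    observed: int | tuple[int, int]
    p_raw: float
    p_adj: float | None
    fc: float
    enrichment_pct: float
    p_point: float | None = None
    p_uppertail: float | None = None
    significant: bool | None = None


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct log-space tail summation.

    Summing the upper tail term by term (rather than 1 - CDF) keeps full
    relative precision for extreme counts; terms are accumulated until
    they fall below 1e-18 of the running sum.
    """
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if k == 0:
        return 1.0
    # P(X >= k) <= 0.5 once k exceeds the median (~lam); sum the tail
    # directly there. For k at or below the mode, 1 - lower sum is stable.
    if k <= lam:
        lower = sum(
            math.exp(j * math.log(lam) - lam - gammaln(j + 1)) for j in range(k)
        )
        return min(1.0, max(0.0, 1.0 - lower))
    log_term = k * math.log(lam) - lam - gammaln(k + 1)
    term = math.exp(log_term)
    total = 0.0
    j = k
    while term > 0.0 and (total == 0.0 or term / total > 1e-18):
        total += term
        j += 1
        term *= lam / j
    return min(1.0, total)


def log_binomial_pmf(k: int, n: int, p0: float) -> float:
    """ln of the binomial pmf C(n,k) p0^k (1-p0)^(n-k), via log-gamma.

    The exponentiated value is the gene-specific cohort test's point
    statistic (``dbinom`` in R).
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n]; got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(log_choose + k * math.log(p0) + (n - k) * math.log1p(-p0))


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), accumulated in log space."""
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n]; got k={k}, n={n}")
    if k == 0:
        return 1.0
    log_terms = np.array([log_binomial_pmf(j, n, p0) for j in range(k, n + 1)])
    m = log_terms.max()
    return float(min(1.0, math.exp(m) * np.exp(log_terms - m).sum()))


def _check_unit_interval(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = _check_unit_interval(p_values)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """min(1, m * p) elementwise."""
    p = _check_unit_interval(p_values)
    return np.minimum(1.0, p * p.size)


def fold_and_enrichment(observed: float, expected: float) -> tuple[float, float]:
    """Fold-change observed/expected and percent enrichment (fc - 1) * 100."""
    if expected <= 0:
        raise ValueError(f"expected must be positive, got {expected}")
    fc = observed / expected
    return fc, (fc - 1.0) * 100.0


def run_ngs_enrichment(
    aggregate: NgsAggregate,
    universe: CandidateUniverse | int,
    lambda_numerator: int | None = None,
    alpha: float = 0.05,
    require_membership: bool = False,
) -> list[EnrichmentResult]:
    """Poisson enrichment test for every gene pooled from the cohorts.

    Parameters
    ----------
    aggregate
        Pooled per-gene counts.
    universe
        The candidate universe (or its size) — the Poisson denominator.
    lambda_numerator
        Numerator of lambda; defaults to the aggregate's solved total.
    alpha
        BH-adjusted significance level for the ``significant`` flag.
    require_membership
        When True, a pooled gene missing from the universe is an error;
        otherwise it is still tested (a warning is logged).

    Results carry BH-adjusted p-values over exactly the tested genes and
    are sorted by raw p then gene symbol.
    """
    import logging

    size = len(universe.genes) if isinstance(universe, CandidateUniverse) else int(universe)
    if size <= 0:
        raise ValueError("candidate universe must not be empty")
    numerator = aggregate.n_solved if lambda_numerator is None else lambda_numerator
    null = PoissonNull(n_solved=numerator, universe_size=size)
    if isinstance(universe, CandidateUniverse):
        outside = sorted(set(aggregate.gene_counts) - set(universe.genes))
        if outside:
            msg = f"{len(outside)} pooled genes outside the universe: {outside[:5]}"
            if require_membership:
                raise ValueError(msg)
            logging.getLogger(__name__).warning(msg)

    genes = sorted(aggregate.gene_counts)
    raw = np.array([poisson_upper_tail(aggregate.gene_counts[g], null.lam) for g in genes])
    adjusted = bh_adjust(raw)
    results = []
    for gene, p_raw, p_adj in zip(genes, raw, adjusted):
        k = aggregate.gene_counts[gene]
        fc, pct = fold_and_enrichment(k, null.lam)
        results.append(
            EnrichmentResult(
                gene=gene,
                observed=k,
                p_raw=float(p_raw),
                p_adj=float(p_adj),
                fc=fc,
                enrichment_pct=pct,
                p_uppertail=float(p_raw),
                significant=bool(p_adj <= alpha),
            )
        )
    return sorted(results, key=lambda r: (r.p_raw, r.gene))


def run_gene_lit_enrichment(
    records: Sequence[GeneLitCohort],
    null: BinomialNull = BinomialNull(),
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Binomial enrichment test for each gene-specific literature cohort.

    ``p_point`` (the dbinom statistic) is the headline p reported in
    ``p_raw``; ``p_uppertail`` is computed alongside. Fold-change is the
    observed CP fraction over p0. The ``significant`` flag applies
    ``correction`` ("bonferroni" over the tested records, or "none") to
    the point statistic at level ``alpha``. Results sorted by p then gene.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    points = np.array(
        [math.exp(log_binomial_pmf(r.n_cp, r.n_total, null.p0)) for r in records]
    )
    thresh = alpha / len(records) if (correction == "bonferroni" and records) else alpha
    results = []
    for record, p_point in zip(records, points):
        fc, pct = fold_and_enrichment(record.n_cp / record.n_total, null.p0)
        results.append(
            EnrichmentResult(
                gene=record.gene,
                observed=(record.n_cp, record.n_total),
                p_raw=float(p_point),
                p_adj=None,
                fc=fc,
                enrichment_pct=pct,
                p_point=float(p_point),
                p_uppertail=binomial_upper_tail(record.n_cp, record.n_total, null.p0),
                significant=bool(p_point <= thresh),
            )
        )
    return sorted(results, key=lambda r: (r.p_raw, r.gene))
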