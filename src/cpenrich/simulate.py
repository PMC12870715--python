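"""Seeded generators for every input the pipeline consumes.

The generators emulate the study's data shapes so that calibration, power
and recovery properties are testable without any download:

* a fixture phenotype ontology (a small is_a DAG with recorded
  ground-truth descendant closures), disease annotations with controlled
  phenotype/onset assignments, and a disease->gene map with a known
  candidate-universe answer;
* diagnostic-cohort count tables in which each solved individual draws a
  causal gene from the candidate universe — uniformly under the null, or
  multinomially with per-gene weight multipliers under the alternative;
* gene-specific literature cohorts with CP counts drawn binomially at a
  configurable multiple of the background prevalence p0 = 0.003;
* grouped ordinal clinical tables and 2x2 contingency tables.

A single integer seed drives a named child stream per generator, so each
module can be exercised independently and reproducibly: identical configs
yield byte-identical TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohorts import GeneLitCohort, NgsCohortStudy
from .compare import GroupedOrdinalSample, TwoByTwoTable
from .ontology import (
    ONSET_ADULT,
    ONSET_INFANTILE,
    DiseaseAnnotationSet,
    Ontology,
    _from_child_parent_edges,
)

__all__ = [
    "SimConfig",
    "SimulatedTruth",
    "FixtureOntology",
    "rng_stream",
    "make_fixture_ontology",
    "simulate_ngs_cohorts",
    "simulate_gene_lit_cohorts",
    "simulate_clinical_cohort",
]

_STREAMS = {
    "ontology": 1,
    "ngs": 2,
    "lit": 3,
    "clinical": 4,
}


def rng_stream(seed: int, stream: str) -> np.random.Generator:
    """A named, independent child generator derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulators.

    Defaults mirror the pooled diagnostic data: 21 cohorts, ~5440
    individuals with a ~23.5% diagnostic yield, a candidate universe of
    1488 genes, and background CP prevalence 0.003. ``effect_map`` gives
    per-gene weight multipliers (1 = null); ``lit_design`` lists
    (gene, n_total, true_fc) triples for the literature simulator.
    """

    seed: int = 0
    universe_genes: tuple[str, ...] = tuple(f"G{i:04d}" for i in range(1488))
    n_cohorts: int = 21
    cohort_sizes: tuple[tuple[int, int], ...] = tuple((259, 61) for _ in range(21))
    effect_map: Mapping[str, float] = field(default_factory=dict)
    lit_design: tuple[tuple[str, int, float], ...] = (("GENE_A", 405, 45.0),)
    p0: float = 0.003
    reps: int = 1

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.effect_map.values()):
            raise ValueError("effect multipliers must be positive")
        for gene, n_total, true_fc in self.lit_design:
            if true_fc < 0 or true_fc * self.p0 > 1.0:
                raise ValueError(
                    f"{gene}: true_fc * p0 = {true_fc * self.p0} outside [0, 1]"
                )
            if n_total <= 0:
                raise ValueError(f"{gene}: n_total must be positive")


@dataclass(frozen=True)
class SimulatedTruth:
    """Generating parameters bundled with an emitted dataset."""

    enriched_genes: frozenset[str]
    effect_map: Mapping[str, float]
    extra: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class FixtureOntology:
    """A generated ontology plus its recorded ground truth."""

    ontology: Ontology
    annotations: tuple[DiseaseAnnotationSet, ...]
    gene_map: Mapping[str, frozenset[str]]
    expected_closures: Mapping[str, frozenset[str]]
    expected_universe: frozenset[str]
    seed_terms: frozenset[str]
    n_edges: int


def make_fixture_ontology(
    seed: int = 0,
    n_terms: int = 50,
    n_diseases: int = 40,
    n_genes: int = 120,
    pediatric_fraction: float = 0.6,
    seed_fraction: float = 0.1,
) -> FixtureOntology:
    """Build a random is_a DAG with known closures and a known universe.

    Terms ``T0001..`` are attached under a single root ``T0000``; each
    non-root term gets 1–2 parents among earlier terms, which guarantees
    acyclicity. Ground-truth descendant closures are recorded by brute
    force during construction. Diseases are annotated to random terms and
    given infantile or adult onset; the expected candidate universe is the
    union of genes of pediatric-onset diseases annotated inside the seed
    terms' closures.
    """
    rng = rng_stream(seed, "ontology")
    terms = [f"T{i:04d}" for i in range(n_terms)]
    nodes = [(t, {"name": f"term {t}"}) for t in terms]
    edges: list[tuple[str, str]] = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3 and i > 1)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((terms[i], terms[int(p)]))
    ontology = _from_child_parent_edges(nodes, edges, {}, release=f"fixture-{seed}")

    # brute-force reflexive closures over the recorded edge list
    children: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent in edges:
        children[parent].add(child)

    def closure(term: str) -> frozenset[str]:
        seen, stack = {term}, [term]
        while stack:
            for ch in children[stack.pop()]:
                if ch not in seen:
                    seen.add(ch)
                    stack.append(ch)
        return frozenset(seen)

    closures = {t: closure(t) for t in terms}
    n_seeds = max(1, int(n_terms * seed_fraction))
    seed_terms = frozenset(
        terms[int(i)] for i in rng.choice(range(1, n_terms), size=n_seeds, replace=False)
    )
    seed_closure = frozenset().union(*(closures[t] for t in seed_terms))

    genes = [f"SYN{i:04d}" for i in range(n_genes)]
    annotations: list[DiseaseAnnotationSet] = []
    gene_map: dict[str, frozenset[str]] = {}
    expected: set[str] = set()
    for d in range(n_diseases):
        disease_id = f"DIS:{d:04d}"
        pheno = frozenset(
            terms[int(i)] for i in rng.choice(n_terms, size=rng.integers(1, 4), replace=False)
        )
        pediatric = bool(rng.random() < pediatric_fraction)
        onset = frozenset({ONSET_INFANTILE if pediatric else ONSET_ADULT})
        disease_genes = frozenset(
            genes[int(i)] for i in rng.choice(n_genes, size=rng.integers(1, 5), replace=False)
        )
        annotations.append(
            DiseaseAnnotationSet(
                disease_id=disease_id,
                phenotype_term_ids=pheno,
                onset_term_ids=onset,
            )
        )
        gene_map[disease_id] = disease_genes
        if pediatric and (pheno & seed_closure):
            expected |= disease_genes
    return FixtureOntology(
        ontology=ontology,
        annotations=tuple(annotations),
        gene_map=gene_map,
        expected_closures=closures,
        expected_universe=frozenset(expected),
        seed_terms=seed_terms,
        n_edges=len(edges),
    )


def simulate_ngs_cohorts(
    config: SimConfig,
) -> tuple[list[NgsCohortStudy], SimulatedTruth]:
    """Draw per-cohort gene counts under the (possibly weighted) null.

    Each solved individual in each cohort independently draws gene g with
    probability w_g / sum(w); per-cohort counts are tallied, so the total
    of all counts equals the total solved.
    """
    if not config.universe_genes:
        raise ValueError("universe must not be empty")
    rng = rng_stream(config.seed, "ngs")
    genes = list(config.universe_genes)
    weights = np.array([config.effect_map.get(g, 1.0) for g in genes], dtype=float)
    probs = weights / weights.sum()
    cohorts = []
    sizes = list(config.cohort_sizes)[: config.n_cohorts]
    for i, (n_individuals, n_solved) in enumerate(sizes):
        draws = rng.multinomial(n_solved, probs)
        gene_counts = {g: int(k) for g, k in zip(genes, draws) if k > 0}
        cohorts.append(
            NgsCohortStudy(
                cohort_id=f"sim{i:02d}",
                n_individuals=n_individuals,
                n_solved=n_solved,
                gene_counts=gene_counts,
            )
        )
    truth = SimulatedTruth(
        enriched_genes=frozenset(g for g, w in config.effect_map.items() if w > 1),
        effect_map=dict(config.effect_map),
    )
    return cohorts, truth


def simulate_gene_lit_cohorts(
    config: SimConfig,
) -> tuple[list[GeneLitCohort], SimulatedTruth]:
    """Draw CP counts for gene-specific cohorts: n_cp ~ Bin(n_total, fc * p0).

    Publication counts are emitted as plausible plumbing values (one
    publication per ~8 individuals, at least 1).
    """
    rng = rng_stream(config.seed, "lit")
    records = []
    for gene, n_total, true_fc in config.lit_design:
        n_cp = int(rng.binomial(n_total, true_fc * config.p0))
        n_pubs = max(1, n_total // 8)
        records.append(
            GeneLitCohort(
                gene=gene,
                n_total=n_total,
                n_cp=n_cp,
                n_pubs=n_pubs,
                n_pubs_cp=min(n_pubs, n_cp),
            )
        )
    truth = SimulatedTruth(
        enriched_genes=frozenset(g for g, _, fc in config.lit_design if fc > 1),
        effect_map={g: fc for g, _, fc in config.lit_design},
    )
    return records, truth


def simulate_clinical_cohort(
    seed: int,
    n1: int = 72,
    n2: int = 388,
    probs_group1: Sequence[float] = (0.11, 0.39, 0.17, 0.19, 0.14),
    probs_group2: Sequence[float] | None = None,
    odds_ratio: float = 1.0,
    feature_prob: float = 0.5,
) -> tuple[GroupedOrdinalSample, TwoByTwoTable, SimulatedTruth]:
    """Draw a grouped ordinal severity table and a 2x2 feature table.

    Group sizes default to the solved/unsolved split of the clinical
    cohort (72 vs 388) with group-1 level probabilities matching its
    severity profile. ``probs_group2`` defaults to ``probs_group1``
    (the null of no group difference). The 2x2 draws the feature with
    probability ``feature_prob`` in group 2 and the odds-ratio-shifted
    probability in group 1.
    """
    rng = rng_stream(seed, "clinical")
    p1 = np.asarray(probs_group1, dtype=float)
    p1 = p1 / p1.sum()
    p2 = p1 if probs_group2 is None else np.asarray(probs_group2, dtype=float)
    p2 = p2 / p2.sum()
    if len(p1) != len(p2):
        raise ValueError("both groups need the same number of levels")
    levels = tuple(float(i + 1) for i in range(len(p1)))
    c1 = tuple(int(x) for x in rng.multinomial(n1, p1))
    c2 = tuple(int(x) for x in rng.multinomial(n2, p2))
    sample = GroupedOrdinalSample(levels=levels, counts_group1=c1, counts_group2=c2)

    odds2 = feature_prob / (1.0 - feature_prob)
    odds1 = odds2 * odds_ratio
    prob1 = odds1 / (1.0 + odds1)
    a = int(rng.binomial(n1, prob1))
    c = int(rng.binomial(n2, feature_prob))
    table = TwoByTwoTable(a=a, b=n1 - a, c=c, d=n2 - c)
    truth = SimulatedTruth(
        enriched_genes=frozenset(),
        effect_map={},
        extra={
            "probs_group1": tuple(float(x) for x in p1),
            "probs_group2": tuple(float(x) for x in p2),
            "odds_ratio": odds_ratio,
        },
    )
    return sample, table, truth
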