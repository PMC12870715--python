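"""Published summary counts used by the worked examples and acceptance checks.

These are the desk-scale inputs of the analysis: pooled per-gene counts
from 21 diagnostic sequencing cohorts of individuals with cerebral palsy,
literature-curated gene-specific cohort records for the most enriched
genes, the gene-set overlap margins, and the clinical severity tables of
the 460-participant cohort. They are counts printed in summary tables —
no individual-level data.
"""

from __future__ import annotations

from .cohorts import GeneLitCohort, NgsAggregate
from .compare import GroupedOrdinalSample, OverlapSpec, TwoByTwoTable

__all__ = [
    "POOLED_N_INDIVIDUALS",
    "POOLED_N_SOLVED",
    "CANDIDATE_UNIVERSE_SIZE",
    "N_TESTED_GENES",
    "TOP_POOLED_COUNTS",
    "pooled_ngs_aggregate",
    "LIT_COHORT_RECORDS",
    "OVERLAP_SPEC",
    "GMFCS",
    "CFCS",
    "EDACS",
    "SEIZURES",
]

# Pooled diagnostic-cohort totals: 5440 individuals across 21 cohorts,
# 1281 solved, causal variants reported in 515 distinct genes out of a
# 1488-gene candidate universe.
POOLED_N_INDIVIDUALS = 5440
POOLED_N_SOLVED = 1281
CANDIDATE_UNIVERSE_SIZE = 1488
N_TESTED_GENES = 515

# The ten most frequently reported genes and their pooled counts.
TOP_POOLED_COUNTS: dict[str, int] = {
    "SPAST": 14,
    "GNAO1": 10,
    "COL4A1": 9,
    "TUBA1A": 9,
    "CTNNB1": 8,
    "ATL1": 8,
    "CACNA1A": 7,
    "L1CAM": 7,
    "TUBB4A": 6,
    "MECP2": 6,
}


def pooled_ngs_aggregate() -> NgsAggregate:
    """The pooled aggregate with the top-10 counts plus single-count filler.

    Only the ten largest pooled counts are published; the remaining 505
    tested genes are filled in with count 1 (the most common value — most
    genes were reported in a single individual). The Benjamini–Hochberg
    adjustment of the top ranks is insensitive to this filler because
    step-up adjustment at rank r depends only on ranks >= r, and every
    filler p-value is far larger than the top ten.
    """
    counts = dict(TOP_POOLED_COUNTS)
    for i in range(N_TESTED_GENES - len(TOP_POOLED_COUNTS)):
        counts[f"FILLER{i:04d}"] = 1
    return NgsAggregate(
        gene_counts=counts,
        gene_cohorts={g: 1 for g in counts},
        n_individuals=POOLED_N_INDIVIDUALS,
        n_solved=POOLED_N_SOLVED,
    )


# Gene-specific literature cohorts for the twenty most enriched genes:
# (total curated individuals, individuals with CP, publications curated,
# publications reporting at least one CP case).
LIT_COHORT_RECORDS: tuple[GeneLitCohort, ...] = (
    GeneLitCohort("CTNNB1", 405, 55, 54, 8),
    GeneLitCohort("ATM", 198, 33, 6, 4),
    GeneLitCohort("SPR", 55, 20, 7, 2),
    GeneLitCohort("AP4M1", 27, 15, 12, 4),
    GeneLitCohort("PLP1", 280, 24, 44, 11),
    GeneLitCohort("KANK1", 42, 14, 7, 5),
    GeneLitCohort("PDHX", 52, 14, 14, 1),
    GeneLitCohort("STXBP1", 95, 15, 4, 2),
    GeneLitCohort("COL4A1", 508, 23, 108, 13),
    GeneLitCohort("SLC6A3", 28, 10, 8, 3),
    GeneLitCohort("SLC16A2", 112, 14, 26, 7),
    GeneLitCohort("GNAO1", 279, 18, 64, 13),
    GeneLitCohort("DYRK1A", 220, 14, 35, 3),
    GeneLitCohort("AUTS2", 142, 12, 27, 4),
    GeneLitCohort("NT5C2", 31, 7, 8, 3),
    GeneLitCohort("RAB3GAP1", 91, 9, 23, 2),
    GeneLitCohort("KAT6A", 167, 10, 29, 1),
    GeneLitCohort("CACNA1A", 1064, 19, 191, 6),
    GeneLitCohort("ATP1A3", 220, 10, 11, 2),
    GeneLitCohort("GCDH", 290, 11, 27, 3),
)

# Overlap of the 89 enriched genes (union of both enrichment analyses)
# with the 60 genes carrying P/LP variants in the clinical cohort, out of
# 5441 Mendelian disease genes: 16 genes in common.
OVERLAP_SPEC = OverlapSpec(universe_n=5441, set_a_n=89, set_b_n=60, overlap_k=16)

# Clinical severity classifications (levels I-V coded 1-5), solved vs
# unsolved participants.
GMFCS = GroupedOrdinalSample(
    levels=(1, 2, 3, 4, 5),
    counts_group1=(8, 27, 12, 13, 10),
    counts_group2=(89, 155, 52, 56, 30),
)
CFCS = GroupedOrdinalSample(
    levels=(1, 2, 3, 4, 5),
    counts_group1=(31, 5, 8, 14, 8),
    counts_group2=(243, 49, 26, 34, 22),
)
EDACS = GroupedOrdinalSample(
    levels=(1, 2, 3, 4, 5),
    counts_group1=(40, 12, 2, 3, 9),
    counts_group2=(264, 50, 24, 11, 19),
)

# Seizures among participants with seizure status recorded:
# solved 20 yes / 7 no, unsolved 15 yes / 32 no.
SEIZURES = TwoByTwoTable(a=20, b=7, c=15, d=32)
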