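"""Data model and TSV I/O for the two curated inputs.

Two table shapes feed the enrichment tests:

* diagnostic ("CP NGS") cohort counts — for each published sequencing
  cohort of individuals with cerebral palsy, how many individuals were
  solved by each gene; and
* gene-specific literature cohorts — for each gene, all published
  individuals with reportedly causal variants in it, and how many of those
  were diagnosed with CP.

Both are plain UTF-8 TSV with a header row; ``#``-prefixed comment lines
are permitted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NgsCohortStudy",
    "NgsAggregate",
    "GeneLitCohort",
    "TableValidationError",
    "read_ngs_cohorts",
    "write_ngs_cohorts",
    "aggregate_ngs",
    "occurrence_histogram",
    "diagnostic_yield",
    "read_gene_lit_cohorts",
    "write_gene_lit_cohorts",
    "write_provenance_sidecar",
]


class TableValidationError(ValueError):
    """A row of an input table violates the schema; the message carries context."""


@dataclass(frozen=True)
class NgsCohortStudy:
    """One published diagnostic-sequencing cohort.

    ``gene_counts`` maps gene symbol to the number of individuals the
    original authors deemed solved by that gene. The per-gene counts may
    sum to more or less than ``n_solved`` (dual diagnoses, partial gene
    lists); a mismatch is logged, not rejected.
    """

    cohort_id: str
    n_individuals: int
    n_solved: int
    gene_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_individuals < 0 or self.n_solved < 0:
            raise ValueError(f"{self.cohort_id}: negative totals")
        if self.n_solved > self.n_individuals:
            raise ValueError(
                f"{self.cohort_id}: n_solved {self.n_solved} exceeds "
                f"n_individuals {self.n_individuals}"
            )
        for gene, count in self.gene_counts.items():
            if count < 1:
                raise ValueError(f"{self.cohort_id}: count for {gene} must be >= 1")
        total = sum(self.gene_counts.values())
        if self.gene_counts and total != self.n_solved:
            logger.warning(
                "cohort %s: gene counts sum to %d but n_solved is %d",
                self.cohort_id,
                total,
                self.n_solved,
            )


@dataclass(frozen=True)
class NgsAggregate:
    """Pooled counts across diagnostic cohorts.

    ``gene_counts[g]`` is k_g, the total number of individuals solved by
    gene g across all cohorts; ``gene_cohorts[g]`` is the number of cohorts
    reporting g at least once.
    """

    gene_counts: Mapping[str, int]
    gene_cohorts: Mapping[str, int]
    n_individuals: int
    n_solved: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_counts)


@dataclass(frozen=True)
class GeneLitCohort:
    """Literature-curated cohort for one gene.

    ``n_total`` individuals published with reportedly causal variants in
    the gene; ``n_cp`` of them diagnosed with cerebral palsy; ``n_pubs``
    publications curated, ``n_pubs_cp`` of which report at least one CP case.
    """

    gene: str
    n_total: int
    n_cp: int
    n_pubs: int = 0
    n_pubs_cp: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_cp <= self.n_total:
            raise ValueError(
                f"{self.gene}: n_cp {self.n_cp} outside [0, n_total={self.n_total}]"
            )
        if self.n_pubs_cp > self.n_pubs:
            raise ValueError(f"{self.gene}: n_pubs_cp exceeds n_pubs")


NGS_COLUMNS = ["cohort_id", "n_individuals", "n_solved", "gene", "count"]
LIT_COLUMNS = ["gene", "n_total", "n_cp", "n_pubs", "n_pubs_cp"]


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")
    return df


def _int_field(value: str, what: str, line: int, path: Path) -> int:
    try:
        return int(value)
    except ValueError:
        raise TableValidationError(
            f"{path}:{line}: {what} must be an integer, got {value!r}"
        ) from None


def read_ngs_cohorts(path: str | Path) -> list[NgsCohortStudy]:
    """Read diagnostic-cohort gene counts, one row per (cohort, gene).

    Rows of one cohort must agree on its totals; duplicate (cohort, gene)
    pairs and counts below 1 are rejected with the offending line number.
    """
    path = Path(path)
    df = _read_tsv(path, NGS_COLUMNS)
    per_cohort: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cohort = row.cohort_id.strip()
        gene = row.gene.strip().upper()
        n_ind = _int_field(row.n_individuals, "n_individuals", i, path)
        n_sol = _int_field(row.n_solved, "n_solved", i, path)
        count = _int_field(row.count, "count", i, path)
        if count < 1:
            raise TableValidationError(f"{path}:{i}: count must be >= 1, got {count}")
        if n_sol > n_ind:
            raise TableValidationError(
                f"{path}:{i}: n_solved {n_sol} exceeds n_individuals {n_ind}"
            )
        entry = per_cohort.setdefault(
            cohort, {"n_individuals": n_ind, "n_solved": n_sol, "genes": {}}
        )
        if (entry["n_individuals"], entry["n_solved"]) != (n_ind, n_sol):
            raise TableValidationError(
                f"{path}:{i}: cohort {cohort} totals disagree with earlier rows"
            )
        if gene in entry["genes"]:
            raise TableValidationError(
                f"{path}:{i}: duplicate gene {gene} for cohort {cohort}"
            )
        entry["genes"][gene] = count
    return [
        NgsCohortStudy(
            cohort_id=c,
            n_individuals=e["n_individuals"],
            n_solved=e["n_solved"],
            gene_counts=e["genes"],
        )
        for c, e in per_cohort.items()
    ]


def write_ngs_cohorts(cohorts: Iterable[NgsCohortStudy], path: str | Path) -> None:
    rows = [
        {
            "cohort_id": c.cohort_id,
            "n_individuals": c.n_individuals,
            "n_solved": c.n_solved,
            "gene": g,
            "count": k,
        }
        for c in cohorts
        for g, k in sorted(c.gene_counts.items())
    ]
    pd.DataFrame(rows, columns=NGS_COLUMNS).to_csv(path, sep="\t", index=False)


def aggregate_ngs(cohorts: Sequence[NgsCohortStudy]) -> NgsAggregate:
    """Pool per-gene counts and totals across cohorts."""
    ids = [c.cohort_id for c in cohorts]
    if len(ids) != len(set(ids)):
        dup = [c for c, n in Counter(ids).items() if n > 1]
        raise ValueError(f"duplicate cohort ids: {dup}")
    counts: Counter[str] = Counter()
    n_cohorts: Counter[str] = Counter()
    for cohort in cohorts:
        for gene, k in cohort.gene_counts.items():
            counts[gene] += k
            n_cohorts[gene] += 1
    return NgsAggregate(
        gene_counts=dict(counts),
        gene_cohorts=dict(n_cohorts),
        n_individuals=sum(c.n_individuals for c in cohorts),
        n_solved=sum(c.n_solved for c in cohorts),
    )


def occurrence_histogram(aggregate: NgsAggregate) -> dict[int, int]:
    """How many genes were seen in exactly m cohorts; values sum to n_genes."""
    hist = Counter(aggregate.gene_cohorts.values())
    return dict(sorted(hist.items()))


def diagnostic_yield(aggregate: NgsAggregate) -> float:
    """Percentage of pooled individuals who received a molecular diagnosis."""
    if aggregate.n_individuals == 0:
        raise ValueError("diagnostic yield undefined for zero individuals")
    return 100.0 * aggregate.n_solved / aggregate.n_individuals


def read_gene_lit_cohorts(path: str | Path) -> list[GeneLitCohort]:
    """Read gene-specific literature cohorts, one validated row per gene."""
    path = Path(path)
    df = _read_tsv(path, LIT_COLUMNS)
    seen: set[str] = set()
    records: list[GeneLitCohort] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = row.gene.strip().upper()
        if gene in seen:
            raise TableValidationError(f"{path}:{i}: duplicate gene {gene}")
        seen.add(gene)
        try:
            records.append(
                GeneLitCohort(
                    gene=gene,
                    n_total=_int_field(row.n_total, "n_total", i, path),
                    n_cp=_int_field(row.n_cp, "n_cp", i, path),
                    n_pubs=_int_field(row.n_pubs, "n_pubs", i, path),
                    n_pubs_cp=_int_field(row.n_pubs_cp, "n_pubs_cp", i, path),
                )
            )
        except ValueError as exc:
            raise TableValidationError(f"{path}:{i}: {exc}") from None
    return records


def write_gene_lit_cohorts(records: Iterable[GeneLitCohort], path: str | Path) -> None:
    rows = [
        {
            "gene": r.gene,
            "n_total": r.n_total,
            "n_cp": r.n_cp,
            "n_pubs": r.n_pubs,
            "n_pubs_cp": r.n_pubs_cp,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=LIT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_provenance_sidecar(table_path: str | Path, **extra) -> Path:
    """Write a JSON sidecar with the table's SHA-256 hash and row count."""
    table_path = Path(table_path)
    data = table_path.read_bytes()
    n_rows = sum(
        1
        for line in data.decode("utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ) - 1  # header
    sidecar = table_path.with_suffix(table_path.suffix + ".prov.json")
    sidecar.write_text(
        json.dumps(
            {
                "file": table_path.name,
                "sha256": hashlib.sha256(data).hexdigest(),
                "n_rows": n_rows,
                **extra,
            },
            indent=2,
        )
        + "\n"
    )
    return sidecar
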