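"""Candidate-gene universes from a phenotype ontology.

A candidate universe is the denominator of the Poisson null model: the set
of genes that could plausibly have been reported as causal in a diagnostic
cohort of children with cerebral palsy. It is built by (i) taking a set of
seed phenotype terms (spasticity, dystonia, ataxia, ...), (ii) collecting
every disease annotated to a seed term or to any is_a descendant of one,
(iii) restricting to diseases with a pediatric onset, (iv) taking the union
of the genes linked to those diseases, and (v) merging in any extra genes
(e.g. the genes actually reported by the cohorts themselves).

Ontologies are handled as directed acyclic graphs over ``is_a`` edges only;
no other relation types are traversed.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "DiseaseAnnotationSet",
    "CandidateUniverse",
    "OnsetPolicy",
    "OntologyError",
    "load_ontology",
    "descendants",
    "select_diseases",
    "genes_for_diseases",
    "build_candidate_universe",
    "mendelian_universe",
    "read_hpoa",
    "read_gene_map",
]

# Canonical HPO onset branch roots. Terms in the descendant closure of an
# accepted root satisfy the pediatric-onset filter.
ONSET_ANTENATAL = "HP:0030674"
ONSET_CONGENITAL = "HP:0003577"
ONSET_NEONATAL = "HP:0003623"
ONSET_INFANTILE = "HP:0003593"
ONSET_CHILDHOOD = "HP:0011463"
ONSET_JUVENILE = "HP:0003621"
ONSET_ADULT = "HP:0003581"


class OntologyError(ValueError):
    """Structural problem in an ontology file (cycle, dangling parent)."""


class OnsetPolicy(enum.Enum):
    """Which disease-onset annotations count as pediatric.

    PEDIATRIC
        congenital, neonatal, infantile or childhood onset (or any
        descendant of those terms); juvenile and adult onset excluded.
    STRICT_INFANTILE_CHILDHOOD
        only infantile or childhood onset (and descendants).
    ANY
        no onset filtering; every annotated onset qualifies.
    """

    PEDIATRIC = "pediatric"
    STRICT_INFANTILE_CHILDHOOD = "strict_infantile_childhood"
    ANY = "any"

    def accepted_roots(self) -> frozenset[str]:
        if self is OnsetPolicy.PEDIATRIC:
            return frozenset(
                {ONSET_CONGENITAL, ONSET_NEONATAL, ONSET_INFANTILE, ONSET_CHILDHOOD}
            )
        if self is OnsetPolicy.STRICT_INFANTILE_CHILDHOOD:
            return frozenset({ONSET_INFANTILE, ONSET_CHILDHOOD})
        return frozenset()


@dataclass(frozen=True)
class Ontology:
    """An is_a DAG over CURIE-identified terms.

    ``graph`` holds one directed edge parent -> child for every is_a
    relation, so descendant queries are plain graph reachability.
    ``obsolete_replacements`` maps retired term ids to their replacement.
    """

    graph: nx.DiGraph
    obsolete_replacements: Mapping[str, str] = field(default_factory=dict)
    release: str = "unspecified"

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def term_ids(self) -> set[str]:
        return set(self.graph.nodes)

    def label(self, term_id: str) -> str | None:
        return self.graph.nodes[term_id].get("name")

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _validate_dag(graph: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        edge = nx.find_cycle(graph)[0]
        raise OntologyError(f"is_a cycle detected involving edge {edge[0]} -> {edge[1]}")


def _from_child_parent_edges(
    nodes: Iterable[tuple[str, dict]],
    edges: Iterable[tuple[str, str]],
    obsolete: Mapping[str, str],
    release: str,
) -> Ontology:
    graph = nx.DiGraph()
    for term_id, attrs in nodes:
        graph.add_node(term_id, **attrs)
    for child, parent in edges:
        if parent not in graph:
            raise OntologyError(
                f"term {child} references unknown parent {parent}"
            )
        if child not in graph:
            raise OntologyError(f"edge references unknown term {child}")
        graph.add_edge(parent, child)
    _validate_dag(graph)
    return Ontology(graph=graph, obsolete_replacements=dict(obsolete), release=release)


def _load_obo(path: Path) -> Ontology:
    # obonet returns a MultiDiGraph with child -> parent edges keyed by
    # relation; obsolete terms are dropped by the parser already.
    raw = obonet.read_obo(path, ignore_obsolete=False)
    release = str(raw.graph.get("data-version", "unspecified"))
    obsolete: dict[str, str] = {}
    nodes: list[tuple[str, dict]] = []
    for term_id, data in raw.nodes(data=True):
        if not data:
            # node created only by an is_a edge target, never declared
            raise OntologyError(f"dangling parent reference to undeclared term {term_id}")
        if data.get("is_obsolete") == "true":
            repl = data.get("replaced_by") or []
            obsolete[term_id] = repl[0] if repl else ""
            continue
        nodes.append((term_id, {"name": data.get("name", "")}))
    live = {t for t, _ in nodes}
    edges = [
        (child, parent)
        for child, parent, key in raw.edges(keys=True)
        if key == "is_a" and child in live and parent in live
    ]
    return _from_child_parent_edges(nodes, edges, obsolete, release)


def _load_obographs(path: Path) -> Ontology:
    with open(path) as fh:
        doc = json.load(fh)
    graphs = doc.get("graphs") or []
    if not graphs:
        raise OntologyError(f"{path}: no graphs in obographs document")
    g = graphs[0]
    release = str((g.get("meta") or {}).get("version", "unspecified"))
    nodes: list[tuple[str, dict]] = []
    obsolete: dict[str, str] = {}

    def _curie(iri: str) -> str:
        # obographs ids are IRIs like http://purl.obolibrary.org/obo/HP_0001257
        tail = iri.rsplit("/", 1)[-1]
        return tail.replace("_", ":", 1) if "_" in tail else tail

    for node in g.get("nodes", []):
        if node.get("type") not in (None, "CLASS"):
            continue
        term_id = _curie(node["id"])
        meta = node.get("meta") or {}
        if meta.get("deprecated"):
            obsolete[term_id] = ""
            continue
        nodes.append((term_id, {"name": node.get("lbl", "")}))
    live = {t for t, _ in nodes}
    edges = []
    for edge in g.get("edges", []):
        if edge.get("pred") != "is_a":
            continue
        child, parent = _curie(edge["sub"]), _curie(edge["obj"])
        if child in live and parent in live:
            edges.append((child, parent))
    return _from_child_parent_edges(nodes, edges, obsolete, release)


def load_ontology(path: str | Path, fmt: str | None = None) -> Ontology:
    """Load an is_a ontology from an OBO flat file or obographs JSON.

    Parameters
    ----------
    path
        File to read.
    fmt
        ``"obo"`` or ``"obographs-json"``; inferred from the suffix when
        omitted (``.json`` -> obographs, anything else -> OBO).

    Raises
    ------
    OntologyError
        On an is_a cycle (the message names one edge on the cycle) or a
        parent reference to a term that does not exist.
    """
    path = Path(path)
    if fmt is None:
        fmt = "obographs-json" if path.suffix.lower() == ".json" else "obo"
    if fmt == "obo":
        return _load_obo(path)
    if fmt == "obographs-json":
        return _load_obographs(path)
    raise ValueError(f"unknown ontology format {fmt!r}")


def descendants(ontology: Ontology, term_id: str) -> set[str]:
    """Reflexive descendant closure of ``term_id`` under is_a.

    Returns the term itself plus every term reachable from it by following
    is_a edges toward more specific terms.
    """
    if term_id not in ontology:
        raise KeyError(f"unknown term {term_id}")
    return nx.descendants(ontology.graph, term_id) | {term_id}


@dataclass(frozen=True)
class DiseaseAnnotationSet:
    """Phenotype annotations for one disease.

    ``negated_term_ids`` holds terms explicitly annotated as absent; they
    never satisfy a phenotype-membership query. ``onset_term_ids`` holds
    onset-branch terms (empty when the corpus records no onset).
    """

    disease_id: str
    phenotype_term_ids: frozenset[str]
    onset_term_ids: frozenset[str] = frozenset()
    negated_term_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.phenotype_term_ids & self.negated_term_ids:
            raise ValueError(
                f"{self.disease_id}: phenotype and negated term sets overlap"
            )


@dataclass(frozen=True)
class CandidateUniverse:
    """A deduplicated gene set with provenance.

    ``genes`` is the Poisson-null denominator; ``extra_genes_merged``
    records genes unioned in from outside the ontology (e.g. the cohorts'
    own reported genes).
    """

    genes: frozenset[str]
    seed_term_ids: frozenset[str]
    onset_policy: OnsetPolicy
    extra_genes_merged: frozenset[str] = frozenset()
    ontology_release: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.genes >= self.extra_genes_merged:
            raise ValueError("universe must contain every merged extra gene")

    def __len__(self) -> int:
        return len(self.genes)


def _accepted_onsets(ontology: Ontology, policy: OnsetPolicy) -> frozenset[str] | None:
    """Closure of accepted onset roots, or None when the policy accepts all."""
    if policy is OnsetPolicy.ANY:
        return None
    accepted: set[str] = set()
    for root in policy.accepted_roots():
        if root in ontology:
            accepted |= descendants(ontology, root)
        else:
            # fixture ontologies may omit the onset branch; fall back to an
            # exact-id match so the policy still means something
            accepted.add(root)
    return frozenset(accepted)


def select_diseases(
    annotations: Iterable[DiseaseAnnotationSet],
    ontology: Ontology,
    seed_terms: Iterable[str],
    onset_policy: OnsetPolicy = OnsetPolicy.PEDIATRIC,
    include_missing_onset: bool = False,
) -> set[str]:
    """Select diseases annotated (directly or via a descendant) to a seed term.

    A disease qualifies iff at least one phenotype annotation lies in the
    union of the seed terms' descendant closures, and at least one onset
    annotation satisfies ``onset_policy``. Negated annotations never count.
    Diseases without any onset annotation are excluded unless
    ``include_missing_onset`` is set (or the policy is ``ANY``).
    """
    seed_terms = set(seed_terms)
    if not seed_terms:
        raise ValueError("seed term set must not be empty")
    closure: set[str] = set()
    for term in seed_terms:
        closure |= descendants(ontology, term)

    accepted_onsets = _accepted_onsets(ontology, onset_policy)
    selected: set[str] = set()
    for ann in annotations:
        if not (ann.phenotype_term_ids & closure):
            continue
        if accepted_onsets is None:
            selected.add(ann.disease_id)
            continue
        if not ann.onset_term_ids:
            if include_missing_onset:
                selected.add(ann.disease_id)
            continue
        if ann.onset_term_ids & accepted_onsets:
            selected.add(ann.disease_id)
    return selected


def _normalize_gene(symbol: str) -> str:
    symbol = symbol.strip().upper()
    if not symbol:
        raise ValueError("empty gene symbol")
    return symbol


def genes_for_diseases(
    disease_ids: Iterable[str], gene_map: Mapping[str, Iterable[str]]
) -> set[str]:
    """Union of gene sets over the selected diseases.

    Diseases absent from the map contribute nothing (logged at debug level).
    """
    genes: set[str] = set()
    for disease_id in disease_ids:
        if disease_id not in gene_map:
            logger.debug("disease %s has no gene links; skipped", disease_id)
            continue
        genes.update(_normalize_gene(g) for g in gene_map[disease_id])
    return genes


def build_candidate_universe(
    ontology: Ontology,
    annotations: Iterable[DiseaseAnnotationSet],
    gene_map: Mapping[str, Iterable[str]],
    seed_terms: Iterable[str],
    onset_policy: OnsetPolicy = OnsetPolicy.PEDIATRIC,
    extra_genes: Iterable[str] = (),
    include_missing_onset: bool = False,
) -> CandidateUniverse:
    """Ontology-derived genes for the seed terms, unioned with ``extra_genes``."""
    seed_terms = frozenset(seed_terms)
    diseases = select_diseases(
        annotations, ontology, seed_terms, onset_policy, include_missing_onset
    )
    genes = genes_for_diseases(diseases, gene_map)
    extra = frozenset(_normalize_gene(g) for g in extra_genes)
    return CandidateUniverse(
        genes=frozenset(genes) | extra,
        seed_term_ids=seed_terms,
        onset_policy=onset_policy,
        extra_genes_merged=extra,
        ontology_release=ontology.release,
    )


def mendelian_universe(gene_map: Mapping[str, Iterable[str]]) -> set[str]:
    """All genes linked to any disease — the overlap test's background."""
    genes: set[str] = set()
    for disease_genes in gene_map.values():
        genes.update(_normalize_gene(g) for g in disease_genes)
    return genes


# ---------------------------------------------------------------------------
# Flat-file readers for the annotation corpus and gene links


def read_hpoa(path: str | Path) -> list[DiseaseAnnotationSet]:
    """Read a disease-annotation table in the HPOA tab-separated dialect.

    Expected columns (case-insensitive, ``#`` comment lines skipped):
    ``database_id``, ``qualifier``, ``hpo_id``, ``onset``; other columns are
    ignored. A qualifier of ``NOT`` routes the term to the negated set.
    Onset CURIEs may appear either in the ``onset`` column or as phenotype
    rows whose ``aspect`` is ``C`` (clinical course).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    df.columns = [c.lower().lstrip("#").strip() for c in df.columns]
    required = {"database_id", "hpo_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    records: dict[str, dict[str, set[str]]] = {}
    for row in df.itertuples(index=False):
        disease = getattr(row, "database_id").strip()
        term = getattr(row, "hpo_id").strip()
        qualifier = getattr(row, "qualifier", "").strip().upper()
        onset = getattr(row, "onset", "").strip()
        aspect = getattr(row, "aspect", "").strip().upper()
        slot = records.setdefault(
            disease, {"phenotype": set(), "onset": set(), "negated": set()}
        )
        if onset:
            slot["onset"].add(onset)
        if not term:
            continue
        if qualifier == "NOT":
            slot["negated"].add(term)
        elif aspect == "C":
            slot["onset"].add(term)
        else:
            slot["phenotype"].add(term)
    return [
        DiseaseAnnotationSet(
            disease_id=d,
            phenotype_term_ids=frozenset(s["phenotype"] - s["negated"]),
            onset_term_ids=frozenset(s["onset"]),
            negated_term_ids=frozenset(s["negated"]),
        )
        for d, s in sorted(records.items())
    ]


def read_gene_map(path: str | Path) -> dict[str, set[str]]:
    """Read disease -> gene links from a two-column TSV (disease_id, gene_symbol)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    df.columns = [c.lower().lstrip("#").strip() for c in df.columns]
    if not {"disease_id", "gene_symbol"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns disease_id, gene_symbol")
    gene_map: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        disease = row.disease_id.strip()
        gene_map.setdefault(disease, set()).add(_normalize_gene(row.gene_symbol))
    return gene_map
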