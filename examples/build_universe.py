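"""Build a candidate-gene universe from a fixture ontology.

The candidate universe — the Poisson null's denominator — is every gene
linked to a pediatric-onset disease annotated to a seed phenotype term or
to any is_a descendant of one, unioned with the cohorts' own genes. Here a
seeded synthetic ontology with known ground truth stands in for a full
phenotype ontology download.
"""

from cpenrich.ontology import OnsetPolicy, build_candidate_universe
from cpenrich.simulate import make_fixture_ontology

fixture = make_fixture_ontology(seed=42, n_terms=60, n_diseases=40, n_genes=120)

universe = build_candidate_universe(
    fixture.ontology,
    fixture.annotations,
    fixture.gene_map,
    seed_terms=fixture.seed_terms,
    onset_policy=OnsetPolicy.PEDIATRIC,
    extra_genes={"EXTRA1", "EXTRA2"},
)

print(f"seed terms: {sorted(fixture.seed_terms)}")
print(f"ontology-derived genes: {len(fixture.expected_universe)}")
print(f"universe with 2 extra cohort genes merged: {len(universe)} genes")
print(f"matches generator ground truth: {universe.genes - {'EXTRA1', 'EXTRA2'} == fixture.expected_universe}")
print()
print(
    "The universe size is what the Poisson rate divides by; unions remove "
    "duplicate\ngenes shared between seed terms, so the total is smaller "
    "than the per-term sum."
)
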