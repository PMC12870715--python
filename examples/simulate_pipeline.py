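"""Simulate the full pipeline under null and alternative conditions.

The generator draws each solved individual's causal gene from the
candidate universe (uniformly under the null; weighted under the
alternative) at the pooled study scale: 1488 genes, 1281 solved cases.
A 16-fold-weighted gene mimics the strongest published signal.
"""

from cpenrich.cohorts import aggregate_ngs
from cpenrich.enrichment import run_ngs_enrichment
from cpenrich.simulate import SimConfig, simulate_ngs_cohorts

genes = tuple(f"G{i:04d}" for i in range(1488))

for label, effects in (("null", {}), ("alternative (G0000 x16)", {"G0000": 16.0})):
    config = SimConfig(
        seed=7,
        universe_genes=genes,
        n_cohorts=21,
        cohort_sizes=tuple((259, 61) for _ in range(21)),
        effect_map=effects,
    )
    cohorts, truth = simulate_ngs_cohorts(config)
    results = run_ngs_enrichment(aggregate_ngs(cohorts), len(genes))
    significant = [r.gene for r in results if r.significant]
    print(f"{label}: {len(significant)} BH-significant genes -> {significant[:5]}")

print()
print(
    "Under the null no gene should survive BH correction; with a 16-fold "
    "weight the\nplanted gene is recovered. Identical seeds reproduce "
    "identical tables."
)
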