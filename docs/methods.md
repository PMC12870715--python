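# Methods

## Models

### Pooled diagnostic-cohort (Poisson) test

Published next-generation-sequencing cohorts of individuals diagnosed with
cerebral palsy report, per gene, how many individuals the original authors
deemed solved by that gene. Pooling the cohorts gives per-gene counts k_g,
a solved total S, and a candidate universe of G genes. The null model says
a causal finding is equally likely in any candidate gene, so
k_g ~ Poisson(λ) with λ = S/G, and enrichment evidence is the upper tail
P(X ≥ k) = 1 − F(k − 1; λ). One test per pooled gene,
Benjamini–Hochberg step-up adjustment across exactly the tested set.

The pooled inputs report two solved totals (1281 in the per-cohort yield
accounting, 1402 in the per-gene count accounting, a consequence of dual
diagnoses and inconsistent per-gene listings upstream). The library uses
the aggregate's own solved total by default and exposes
`lambda_numerator` as an explicit override; with the bundled summary
counts, 1281 — giving λ = 1281/1488 = 0.861 — is the value that
reproduces the published p-values (e.g. P(X ≥ 14) = 6.32e-13, whereas
λ = 1402/1488 gives ≈ 2e-12), so that is what the examples and the
acceptance script pass.

Assumptions worth keeping in mind: cohorts are ascertainment-biased by
design (everyone has CP), counts across cohorts are treated as
independent, and the equal-probability null ignores gene length, disease
prevalence and diagnostic tractability. The test ranks genes against a
deliberately simple chance model; it does not estimate penetrance.

### Gene-specific literature-cohort (binomial) test

For one gene, the curated cohort is every published individual with
reportedly causal variants in it, regardless of phenotype: n_total
individuals, n_cp of them with CP. Under no association,
n_cp ~ Binomial(n_total, p₀) with p₀ = 0.003, a deliberately high value
within the published CP-prevalence range (0.16–0.36%); a high p₀ is
conservative for enrichment claims. The headline statistic is the point
probability of the observed count (the R `dbinom` convention, which the
published tables use); the more orthodox upper tail P(X ≥ x) is always
computed alongside and reported in machine-readable output. Significance
flags default to Bonferroni over the tested records at α = 0.05;
`correction="none"` reproduces the uncorrected convention. Both
conventions appear in the source analyses, so both are first-class here.

### Overlap and clinical comparisons

Overlap between a set of K literature-enriched genes and n
cohort-detected genes in an N-gene background is tested with the
hypergeometric distribution: expected overlap Kn/N, fold kN/(Kn), p
either upper-tail or two-sided Fisher ("tables at most as probable", with
a 1e-7 relative tolerance for floating-point ties — the dominant software
convention). At the bundled margins (16 of 60 vs 89 in 5441) the two
sidedness choices agree to printed precision; two-sided is the default.

Severity scales (I–V, coded 1–5) arrive as per-level counts. The
Mann–Whitney U uses midranks per level, U = R₁ − n₁(n₁+1)/2, and the
tie-corrected normal approximation

    σ² = (n₁n₂/12)·[(N+1) − Σ(t³−t)/(N(N−1))]

with **no continuity correction**, a choice verified to reproduce the
published p-values (0.0068, 0.00073, 0.046) and equal to a naive
per-individual expansion (checked against an independent implementation
up to totals of 500). An exact permutation U is out of scope. Median and
IQR come from linear interpolation of order statistics (position
(g−1)q + 1), the convention that reproduces the published summaries on
grouped data. One published comparison (gestational age, p = 0.033) is
*not* reproduced by this procedure on the printed bins (which give
≈ 0.05); it was likely computed on unbinned weeks, and the package does
not attempt to reverse-engineer it.

## Candidate universes

A candidate universe is built from three inputs: an is_a ontology (OBO or
obographs JSON; only is_a edges are traversed, cycles and dangling parents
are hard errors, obsolete terms are dropped but kept in a replacement
map), a disease-annotation corpus (HPOA-dialect TSV; negated annotations
never satisfy membership, frequency qualifiers are ignored), and a
disease→gene TSV. A disease qualifies when any non-negated phenotype
annotation falls in the descendant closure of a seed term and its onset
satisfies the policy. The default `OnsetPolicy.PEDIATRIC` accepts
congenital, neonatal, infantile and childhood onset branches (descendant
closure of those four roots), excluding juvenile/adult — onsets earlier
than infantile satisfy the clinical intent of "infantile or childhood
onset"; `STRICT_INFANTILE_CHILDHOOD` and `ANY` are selectable, and
diseases without onset annotations are excluded unless
`include_missing_onset` is set (conservative default). Gene symbols are
upper-cased and trimmed; no alias resolution. Universe sizes are
release-dependent, so the provenance record carries the ontology release
tag and no test asserts a release-specific size.

## Numerical choices

* All extreme-tail quantities are computed in log space with log-gamma:
  the binomial pmf agrees with exact rational arithmetic to 12 significant
  digits down to ~1e-71, and the hypergeometric kernel normalizes to
  ~1e-10 at the overlap margins (the precision double log-gamma delivers).
* The Poisson upper tail is summed term-by-term from k upward (ratio
  recurrence, stop at 1e-18 relative), avoiding 1 − CDF cancellation for
  small tails; for k ≤ λ the complement of the lower sum is stable.
* BH adjustment is the min-over-suffix formulation; ties in ranking are
  broken by gene symbol so output order is deterministic.
* Published-style rendering: p to 3 significant figures ("a.bc × 10^−n"
  below 1e-4), fold and percentages to 1 decimal; TSV output always keeps
  full precision.
* Two printed point probabilities in the source tables (2.69e-71 for
  55/405 and 1.45e-46 for 33/198) differ from the exact dbinom values
  (2.64e-71, 1.42e-46, confirmed by exact rational arithmetic and an
  independent R computation) by ~1.7% — a printing slip upstream. The
  package reports the exact values.

## Synthetic data

The generators emit exactly the TSV schemas the readers consume, each
from a named child stream of one master seed (identical configs give
byte-identical files, plus a JSON truth sidecar).

* **Fixture ontology**: ~30–100 terms attached under a single root, 1–2
  parents per term drawn among earlier terms (acyclic by construction),
  with brute-force descendant closures recorded at build time; diseases
  get random phenotype terms and infantile or adult onset (default 60%
  pediatric), genes are assigned 1–4 per disease from a 120-symbol pool.
* **Diagnostic cohorts**: each solved individual draws its gene
  multinomially with weights w_g (all 1 under the null — the study's
  stated chance model; the weighted alternative is the simplest departure
  that preserves the solved total). Default scale matches the pooled
  study: 21 cohorts of 259 individuals / 61 solved (≈ 5440 and 1281
  pooled, 23.5% yield) over 1488 genes.
* **Literature cohorts**: n_cp ~ Binomial(n_total, fc·p₀) per record at
  p₀ = 0.003; publication counts are plausible plumbing (one per ~8
  individuals), not a model of publication practice.
* **Clinical tables**: two multinomial groups over five severity levels
  (defaults: 72 vs 388 participants with the solved group's published
  severity profile) and a 2×2 with a configurable odds ratio.

What the simulations do *not* emulate — and therefore what passing tests
cannot show about real data: ascertainment and publication bias, dual
molecular diagnoses, correlated findings across cohorts, variable
diagnostic practice for CP, and gene-level covariates (length,
mutability). Calibration and power results are statements about the
stated chance models only.

## Problem sizes in the checks

The null-calibration and power simulations run at the pooled study scale
(1488 genes, 1281 solved per run; 200 replicates in the test suite, 100
in the acceptance script) — small enough to complete in seconds, large
enough that the BH false-call rate and the 16-fold-gene power are sharp.
Literature-side calibration and fold-change recovery use 1000 simulated
records across true fold-changes 1–50 and cohort sizes 50–500.

## Known limitations

* Statistical association is not causation: enrichment can reflect
  referral patterns or literature volume as much as biology.
* The point-probability convention on the binomial side is kept for
  fidelity to the source tables, but it is not a tail test; consumers who
  want a p-value in the Neyman–Pearson sense should read `p_uppertail`.
* No ontology reasoning beyond is_a closure; no gene-symbol alias
  resolution; no per-variant or per-individual modelling.
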