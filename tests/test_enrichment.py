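"""Poisson and binomial enrichment statistics against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cpenrich.cohorts import GeneLitCohort, NgsAggregate
from cpenrich.datasets import (
    CANDIDATE_UNIVERSE_SIZE,
    POOLED_N_SOLVED,
)
from cpenrich.enrichment import (
    BinomialNull,
    PoissonNull,
    bh_adjust,
    binomial_upper_tail,
    bonferroni_adjust,
    fold_and_enrichment,
    log_binomial_pmf,
    poisson_upper_tail,
    run_gene_lit_enrichment,
    run_ngs_enrichment,
)

from .conftest import exact_binom_pmf

LAM = POOLED_N_SOLVED / CANDIDATE_UNIVERSE_SIZE


class TestPoissonUpperTail:
    def test_k_zero_is_one(self):
        assert poisson_upper_tail(0, 5.0) == 1.0

    def test_k_one_closed_form(self):
        assert poisson_upper_tail(1, LAM) == pytest.approx(
            1 - math.exp(-LAM), rel=1e-14
        )

    @pytest.mark.parametrize("k, lam", [(3, 0.5), (7, 2.0), (20, 5.0), (40, 10.0)])
    def test_equals_one_minus_pmf_sum(self, k, lam):
        lower = sum(stats.poisson.pmf(j, lam) for j in range(k))
        assert poisson_upper_tail(k, lam) == pytest.approx(1 - lower, abs=1e-14)

    @pytest.mark.parametrize("k", range(1, 30))
    def test_matches_scipy_survival(self, k):
        assert poisson_upper_tail(k, LAM) == pytest.approx(
            stats.poisson.sf(k - 1, LAM), rel=1e-12
        )

    def test_strictly_decreasing_in_k(self):
        values = [poisson_upper_tail(k, LAM) for k in range(0, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_upper_tail(1, 0.0)


class TestLogBinomialPmf:
    def test_k_zero_closed_form(self):
        assert log_binomial_pmf(0, 100, 0.003) == pytest.approx(
            100 * math.log1p(-0.003), rel=1e-14
        )

    @pytest.mark.parametrize(
        "k, n", [(55, 405), (33, 198), (15, 27), (0, 10), (10, 10), (1, 1064)]
    )
    def test_matches_exact_rational_oracle_to_12_digits(self, k, n):
        exact = float(exact_binom_pmf(k, n, 3, 1000))
        ours = math.exp(log_binomial_pmf(k, n, 0.003))
        assert ours == pytest.approx(exact, rel=1e-12)

    @pytest.mark.parametrize("p_num, p_den", [(3, 1000), (1, 10), (1, 2)])
    def test_normalization_sums_to_one(self, p_num, p_den):
        for n in (1, 7, 23, 50):
            total = sum(
                math.exp(log_binomial_pmf(k, n, p_num / p_den)) for k in range(n + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            log_binomial_pmf(5, 4, 0.1)
        with pytest.raises(ValueError):
            log_binomial_pmf(-1, 4, 0.1)


class TestBinomialUpperTail:
    def test_k_zero_is_one(self):
        assert binomial_upper_tail(0, 10, 0.3) == 1.0

    def test_k_equals_n_equals_one(self):
        assert binomial_upper_tail(1, 1, 0.25) == pytest.approx(0.25, rel=1e-14)

    def test_matches_exact_rational_sum(self):
        exact = float(sum(exact_binom_pmf(j, 50, 1, 10) for j in range(5, 51)))
        assert binomial_upper_tail(5, 50, 0.1) == pytest.approx(exact, rel=1e-12)

    @pytest.mark.parametrize("k, n, p0", [(55, 405, 0.003), (3, 20, 0.5)])
    def test_matches_scipy_survival(self, k, n, p0):
        assert binomial_upper_tail(k, n, p0) == pytest.approx(
            stats.binom.sf(k - 1, n, p0), rel=1e-10
        )


class TestAdjustments:
    def test_all_equal_unchanged(self):
        p = [0.2] * 6
        assert bh_adjust(p) == pytest.approx(p)

    def test_single_element_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_matches_min_over_suffix_oracle(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(size=20)
        expected = [
            min(
                min(
                    len(p) * pj / (rank + 1)
                    for rank, pj in enumerate(sorted(p))
                    if pj >= pi or math.isclose(pj, pi)
                ),
                1.0,
            )
            for pi in p
        ]
        # direct formula oracle: adj_i = min_{p_(j) >= p_i} m p_(j) / j
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(adj)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_bh_permutation_invariant_and_dominates_raw(self, p, rnd):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = list(range(len(p)))
        rnd.shuffle(order)
        shuffled_adj = bh_adjust([p[i] for i in order])
        restored = np.empty(len(p))
        restored[order] = shuffled_adj
        assert restored == pytest.approx(adj)

    @pytest.mark.parametrize("p, m, expected", [(0.01, 5, 0.05), (0.5, 10, 1.0)])
    def test_bonferroni(self, p, m, expected):
        values = [p] + [0.9] * (m - 1)
        assert bonferroni_adjust(values)[0] == pytest.approx(expected)

    def test_bonferroni_pointwise_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=15)
        assert bonferroni_adjust(p) == pytest.approx(np.minimum(1, p * 15))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])


class TestFoldAndEnrichment:
    def test_observed_equals_expected(self):
        assert fold_and_enrichment(2.0, 2.0) == (1.0, 0.0)

    def test_published_poisson_row(self):
        fc, pct = fold_and_enrichment(14, LAM)
        assert round(pct, 1) == 1526.2

    def test_published_binomial_row(self):
        fc, pct = fold_and_enrichment(55 / 405, 0.003)
        assert round(fc, 1) == 45.3
        assert round(pct, 1) == 4426.7

    def test_strictly_increasing_in_observed(self):
        pcts = [fold_and_enrichment(k, LAM)[1] for k in range(20)]
        assert all(a < b for a, b in zip(pcts, pcts[1:]))

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            fold_and_enrichment(1.0, 0.0)


class TestRunNgsEnrichment:
    def test_single_gene_near_expected_count(self):
        agg = NgsAggregate({"A": 1}, {"A": 1}, 100, 1)
        (res,) = run_ngs_enrichment(agg, 1, lambda_numerator=1)
        assert abs(res.enrichment_pct) < 1e-9

    def test_empty_universe_rejected(self):
        agg = NgsAggregate({"A": 1}, {"A": 1}, 10, 1)
        with pytest.raises(ValueError):
            run_ngs_enrichment(agg, 0)

    def test_results_sorted_and_bh_over_tested_set(self):
        agg = NgsAggregate(
            {"A": 5, "B": 1, "C": 3}, {"A": 1, "B": 1, "C": 1}, 100, 9
        )
        results = run_ngs_enrichment(agg, 50)
        assert [r.gene for r in results] == ["A", "C", "B"]
        raw = [r.p_raw for r in results]
        assert [r.p_adj for r in results] == pytest.approx(list(bh_adjust(raw)))

    def test_lambda_numerator_override(self):
        agg = NgsAggregate({"A": 4}, {"A": 1}, 100, 20)
        (default,) = run_ngs_enrichment(agg, 40)
        (overridden,) = run_ngs_enrichment(agg, 40, lambda_numerator=10)
        assert default.fc == pytest.approx(4 / (20 / 40))
        assert overridden.fc == pytest.approx(4 / (10 / 40))


class TestRunGeneLitEnrichment:
    def test_zero_cp_record(self):
        (res,) = run_gene_lit_enrichment(
            [GeneLitCohort("X", 50, 0, 5, 0)], correction="none"
        )
        assert res.fc == 0.0
        assert res.enrichment_pct == -100.0
        assert not res.significant

    def test_point_and_tail_both_reported(self):
        (res,) = run_gene_lit_enrichment([GeneLitCohort("X", 100, 3, 5, 2)])
        assert res.p_point == pytest.approx(
            math.exp(log_binomial_pmf(3, 100, 0.003)), rel=1e-12
        )
        assert res.p_uppertail == pytest.approx(
            binomial_upper_tail(3, 100, 0.003), rel=1e-12
        )
        assert res.p_uppertail >= res.p_point

    def test_bonferroni_flag_stricter_than_uncorrected(self):
        records = [GeneLitCohort(f"G{i}", 200, 3, 5, 1) for i in range(50)]
        bonf = run_gene_lit_enrichment(records, correction="bonferroni")
        none = run_gene_lit_enrichment(records, correction="none")
        assert sum(r.significant for r in bonf) <= sum(r.significant for r in none)

    def test_null_uppertail_calibration(self):
        """At true fc = 1 the upper-tail test rejects at ~nominal rate."""
        rng = np.random.default_rng(1234)
        p0, reps, n_total = 0.003, 1000, 400
        draws = rng.binomial(n_total, p0, size=reps)
        rej = np.mean(
            [binomial_upper_tail(int(x), n_total, p0) < 0.05 for x in draws]
        )
        assert rej <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)

    def test_estimator_unbiased_on_simulated_cohorts(self):
        """x/(n p0) recovers true fold-changes 5/20/50 within MC error."""
        rng = np.random.default_rng(99)
        p0, reps = 0.003, 1000
        for true_fc in (5.0, 20.0, 50.0):
            for n_total in (50, 200, 500):
                draws = rng.binomial(n_total, true_fc * p0, size=reps)
                estimates = draws / (n_total * p0)
                se = estimates.std(ddof=1) / math.sqrt(reps)
                assert abs(estimates.mean() - true_fc) < 4 * se + 1e-9


def test_nulls_validate_parameters():
    with pytest.raises(ValueError):
        PoissonNull(0, 100)
    with pytest.raises(ValueError):
        BinomialNull(p0=1.5)
    assert PoissonNull(1281, 1488).lam == pytest.approx(0.861, abs=5e-4)
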