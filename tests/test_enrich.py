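"""Enrichment ratios, chi-squared significance, excess and occupancy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from triodnv.enrich import (
    ContingencyCounts,
    bonferroni,
    chi_squared,
    enrichment_ratio,
    enrichment_table,
    enrichment_table_from_counts,
    expected_excess,
    occupancy_expectation,
    odds_ratio_cross_product,
)

# published case/control cohort sizes used as fixture totals throughout
N_CASE, N_CONTROL = 4157, 97_942


def pearson_oracle(a, n1, b, n2):
    """Direct sum((O-E)^2/E) over the four cells of the 2x2 table."""
    obs = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


class TestEnrichmentRatio:
    @pytest.mark.parametrize("a,b,expected", [
        (87, 1442, 1.42),    # promoter chromatin state
        (46, 599, 1.81),     # promoter overlapping DHS
    ])
    def test_published_rows_reproduce(self, a, b, expected):
        r = enrichment_ratio(ContingencyCounts(a, N_CASE, b, N_CONTROL))
        assert round(r, 2) == expected

    def test_identical_proportions_give_unity(self):
        assert enrichment_ratio(ContingencyCounts(10, 100, 10, 100)) == 1.0

    def test_reciprocity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = rng.integers(10, 1000, 2)
            a, b = rng.integers(1, n1 + 1), rng.integers(1, n2 + 1)
            fwd = enrichment_ratio(ContingencyCounts(int(a), int(n1), int(b), int(n2)))
            rev = enrichment_ratio(ContingencyCounts(int(b), int(n2), int(a), int(n1)))
            assert fwd * rev == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(n1=st.integers(2, 10_000), n2=st.integers(2, 10_000),
           data=st.data())
    def test_reciprocity_and_positivity_hold_for_any_table(self, n1, n2, data):
        a = data.draw(st.integers(1, n1))
        b = data.draw(st.integers(1, n2))
        fwd = enrichment_ratio(ContingencyCounts(a, n1, b, n2))
        rev = enrichment_ratio(ContingencyCounts(b, n2, a, n1))
        assert fwd > 0
        assert fwd * rev == pytest.approx(1.0)

    def test_zero_control_count_gives_nan_with_corrected_alternative(self):
        counts = ContingencyCounts(5, 100, 0, 1000)
        assert math.isnan(enrichment_ratio(counts))
        assert enrichment_ratio(counts, continuity=True) > 0

    def test_cross_product_odds_ratio_differs_on_tfbs_row(self):
        # printed 1.61 matches the cross-product OR, not the proportion ratio
        counts = ContingencyCounts(39, N_CASE, 573, N_CONTROL)
        assert round(enrichment_ratio(counts), 2) == 1.60
        assert round(odds_ratio_cross_product(counts), 2) == 1.61


class TestChiSquared:
    def test_equal_proportions_give_zero_statistic(self):
        stat, p = chi_squared(ContingencyCounts(10, 100, 10, 100))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_pearson_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1, n2 = rng.integers(20, 2000, 2)
            a, b = rng.integers(1, n1), rng.integers(1, n2)
            counts = ContingencyCounts(int(a), int(n1), int(b), int(n2))
            stat, p = chi_squared(counts, yates=False)
            oracle = pearson_oracle(a, n1, b, n2)
            assert stat == pytest.approx(oracle, rel=1e-9)
            assert p == pytest.approx(stats.chi2.sf(oracle, 1), rel=1e-9)

    def test_yates_never_exceeds_pearson(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n1, n2 = rng.integers(20, 500, 2)
            a, b = rng.integers(1, n1), rng.integers(1, n2)
            counts = ContingencyCounts(int(a), int(n1), int(b), int(n2))
            assert chi_squared(counts, yates=True)[0] <= chi_squared(counts)[0] + 1e-12

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            chi_squared(ContingencyCounts(0, 10, 0, 10))


class TestBonferroni:
    def test_thirteen_test_correction_sets_significance(self):
        assert bonferroni(0.0019, 13) == pytest.approx(0.0247)
        assert bonferroni(0.0019, 13) < 0.05
        assert bonferroni(0.0057, 13) == pytest.approx(0.0741)
        assert bonferroni(0.0057, 13) > 0.05

    def test_capped_at_one_and_validates(self):
        assert bonferroni(1.0, 13) == 1.0
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestExpectedExcess:
    def test_published_promoter_rows(self):
        assert round(expected_excess(87, 1.42)) == 26
        assert round(expected_excess(46, 1.81)) == 21

    def test_unity_ratio_means_no_excess(self):
        assert expected_excess(123, 1.0) == 0.0

    def test_monotone_in_ratio_and_bounded_by_count(self):
        prev = -1.0
        for r in np.linspace(1.0, 50.0, 40):
            e = expected_excess(87, r)
            assert e > prev
            assert e < 87
            prev = e
        with pytest.raises(ValueError):
            expected_excess(10, 0.0)


class TestOccupancy:
    def test_published_values(self):
        occ = occupancy_expectation(21, 71)
        assert round(occ.probability, 2) == 0.26
        assert occ.probability == pytest.approx(0.2576, abs=1e-4)
        assert occ.expected_patients_reported == 18

    def test_one_third_of_cohort_from_26_excess(self):
        occ = occupancy_expectation(26, 71)
        assert occ.probability == pytest.approx(0.3084, abs=1e-4)

    @settings(derandomize=True, max_examples=100)
    @given(k=st.integers(0, 5000), t=st.integers(1, 10_000))
    def test_occupancy_bounds_for_any_inputs(self, k, t):
        occ = occupancy_expectation(k, t)
        assert 0.0 <= occ.probability <= 1.0
        if t > 1 and k > 0:
            assert occ.probability > 0.0
            assert occ.probability < 1.0 or (1 - 1 / t) ** k == 0.0
        assert occ.expected_patients <= t

    def test_limits(self):
        assert occupancy_expectation(0, 71).probability == 0.0
        probs = [occupancy_expectation(k, 71).probability for k in range(0, 500, 10)]
        assert all(b > a for a, b in zip(probs, probs[1:]))
        assert occupancy_expectation(10_000, 71).expected_patients <= 71


class TestEnrichmentTable:
    def test_empty_case_cohort_raises(self, mini_tracks, mini_cfg):
        from triodnv.synth import simulate_control_set
        control = simulate_control_set(mini_cfg, mini_tracks, size=200)
        empty = control.iloc[0:0]
        with pytest.raises(ValueError):
            enrichment_table(empty, control)

    def test_zero_control_feature_count_yields_nan_row(self):
        rows = enrichment_table_from_counts([("f", 5, 0)], 100, 1000)
        assert math.isnan(rows[0].ratio)

    def test_gc_filter_applied_symmetrically(self, mini_tracks, mini_cfg):
        from triodnv.synth import simulate_control_set
        control = simulate_control_set(mini_cfg, mini_tracks, size=2000)
        case = simulate_control_set(mini_cfg, mini_tracks, size=1000, seed=77)
        rows = enrichment_table(case, control)
        n_case = (~case["gc_excluded"]).sum()
        n_ctrl = (~control["gc_excluded"]).sum()
        assert rows[0].counts.n1 == n_case
        assert rows[0].counts.n2 == n_ctrl
        assert len(rows) == 13
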