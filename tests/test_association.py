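"""Exact association statistics: Fisher test, odds ratios, pooling, combining."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import hypergeom

from rarecnv.association import (
    AssociationResult,
    CarrierTable,
    associate,
    bonferroni,
    combine_stratified,
    fisher_two_sided,
    odds_ratio,
    pool_tables,
)

cells = st.integers(min_value=0, max_value=40)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table,expected,places",
        [
            ((5, 897, 1, 1563), 0.027, 3),
            ((6, 445, 2, 1272), 0.005, 3),
            ((4, 898, 0, 1564), 0.018, 3),
        ],
    )
    def test_published_carrier_tables(self, table, expected, places):
        p = fisher_two_sided(CarrierTable(*table))
        assert round(p, places) == expected

    def test_symmetric_two_by_two_is_one(self):
        # margins (2,2)/(2,2): table probabilities 1/6, 4/6, 1/6 — all qualify
        assert fisher_two_sided(CarrierTable(1, 1, 1, 1)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(0, 0, 0, 0), (0, 5, 0, 7), (3, 0, 4, 0)])
    def test_zero_margin_gives_one(self, table):
        assert fisher_two_sided(CarrierTable(*table)) == pytest.approx(1.0)

    @given(cells, cells, cells, cells)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        from conftest import fisher_enumeration_oracle

        p = fisher_two_sided(CarrierTable(a, b, c, d))
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), rel=1e-12)

    @given(cells, cells, cells, cells)
    def test_cross_check_against_scipy(self, a, b, c, d):
        p = fisher_two_sided(CarrierTable(a, b, c, d))
        p_scipy = scipy_fisher([[a, b], [c, d]]).pvalue
        # scipy uses a small relative tolerance when comparing tied table
        # probabilities; agreement is to numerical precision away from ties
        assert p == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)

    @given(cells, cells, cells, cells)
    def test_full_symmetry(self, a, b, c, d):
        p = fisher_two_sided(CarrierTable(a, b, c, d))
        swapped = fisher_two_sided(CarrierTable(d, c, b, a))
        assert p == pytest.approx(swapped, rel=1e-12)

    def test_one_sided_tail_anti_monotone_in_case_carriers(self):
        # moving carriers from b to a (margins fixed) shrinks the upper tail
        def upper_tail(a, b, c, d):
            m1, n1, n = a + c, a + b, a + b + c + d
            return float(hypergeom.sf(a - 1, n, m1, n1))

        tails = [upper_tail(a, 20 - a, 5, 75) for a in range(0, 10)]
        assert all(t1 >= t2 for t1, t2 in zip(tails, tails[1:]))


class TestOddsRatio:
    def test_published_discovery_or(self):
        or_, lo, hi = odds_ratio(CarrierTable(5, 897, 1, 1563))
        assert round(or_, 2) == 8.71
        assert lo < or_ < hi

    def test_no_control_carriers_gives_infinite_or_with_finite_lower_bound(self):
        or_, lo, hi = odds_ratio(CarrierTable(4, 898, 0, 1564))
        assert math.isinf(or_) and math.isinf(hi)
        assert 0 < lo < math.inf

    def test_symmetric_table_gives_one(self):
        or_, lo, hi = odds_ratio(CarrierTable(1, 1, 1, 1))
        assert or_ == pytest.approx(1.0)

    def test_no_carriers_at_all_is_undefined(self):
        or_, lo, hi = odds_ratio(CarrierTable(0, 10, 0, 20))
        assert math.isnan(or_)

    @given(
        st.integers(min_value=1, max_value=30),
        st.integers(min_value=1, max_value=30),
        st.integers(min_value=1, max_value=30),
        st.integers(min_value=1, max_value=30),
    )
    def test_column_swap_inverts_or(self, a, b, c, d):
        or_fwd, *_ = odds_ratio(CarrierTable(a, b, c, d))
        or_swap, *_ = odds_ratio(CarrierTable(b, a, d, c))
        assert or_fwd * or_swap == pytest.approx(1.0)


class TestPoolingAndBonferroni:
    def test_pooled_combined_row_counts(self):
        # per-panel deletion carrier tables; pooled case side is 19 / 4426
        panels = [
            CarrierTable(5, 897, 1, 1563, "discovery"),
            CarrierTable(6, 445, 2, 1272, "german_replication"),
            CarrierTable(5, 2391, 8, 4878, "wtccc2"),
            CarrierTable(1, 251, 0, 272, "norwegian"),
            CarrierTable(2, 442, 1, 1131, "lithuanian"),
            CarrierTable(0, 0, 5, 4500, "insilico"),
        ]
        pooled = pool_tables(panels)
        assert (pooled.a, pooled.b) == (19, 4426)
        assert pooled.case_carrier_freq == pytest.approx(19 / 4445)

    def test_pooling_identities(self):
        t = CarrierTable(3, 7, 1, 9, "x")
        assert pool_tables([t]).a == t.a
        zero = CarrierTable(0, 0, 0, 0, "z")
        p = pool_tables([t, zero])
        assert (p.a, p.b, p.c, p.d) == (3, 7, 1, 9)

    def test_bonferroni_rows(self):
        assert bonferroni(1.2e-3, 3) == pytest.approx(3.6e-3)
        assert bonferroni(0.5, 3) == 1.0
        assert bonferroni(0.123, 1) == pytest.approx(0.123)
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)


class TestCombineStratified:
    def test_zero_carriers_give_p_one_under_both_methods(self):
        tables = [CarrierTable(0, 50, 0, 70, "p1"), CarrierTable(0, 30, 0, 90, "p2")]
        for method in ("pooled_fisher", "stratified_permutation"):
            out = combine_stratified(tables, method, 1000, seed=1)
            assert out["p"] == pytest.approx(1.0)

    def test_refuses_too_few_permutations(self):
        with pytest.raises(ValueError, match="n_permutations"):
            combine_stratified([CarrierTable(1, 9, 1, 9)], "stratified_permutation", 50, 1)

    def test_single_panel_matches_exact_hypergeometric_tail(self):
        # with one panel the permutation p targets the one-sided
        # hypergeometric upper tail P(X >= a); exact tail is the oracle
        t = CarrierTable(7, 93, 2, 198, "only")
        n, m1, n1 = t.total, t.a + t.c, t.n_cases
        exact = float(hypergeom.sf(t.a - 1, n, m1, n1))
        out = combine_stratified([t], "stratified_permutation", 100_000, seed=1)
        mc_se = math.sqrt(exact * (1 - exact) / 100_000)
        assert abs(out["p"] - exact) < 4 * mc_se + 2 / 100_000

    def test_planted_enrichment_detected(self):
        # three panels with 10x case carrier frequency
        rng = np.random.default_rng(1)
        tables = []
        for i, (nc, nu) in enumerate([(400, 600), (300, 900), (500, 500)]):
            a = int(rng.binomial(nc, 0.05))
            c = int(rng.binomial(nu, 0.005))
            tables.append(CarrierTable(a, nc - a, c, nu - c, f"p{i}"))
        out = combine_stratified(tables, "stratified_permutation", 100_000, seed=1)
        assert out["p"] < 0.01

    def test_output_is_labelled_with_its_method(self):
        out = combine_stratified([CarrierTable(1, 9, 1, 9)], "pooled_fisher")
        assert out["method"] == "pooled_fisher"


def test_associate_bundles_p_or_and_bonferroni():
    res = associate(CarrierTable(5, 897, 1, 1563, "discovery"), bonferroni_m=3)
    assert isinstance(res, AssociationResult)
    assert res.p_bonferroni == pytest.approx(min(1.0, 3 * res.p_two_sided))
    assert round(res.odds_ratio, 2) == 8.71
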