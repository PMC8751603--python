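"""Fisher overlap, enrichment, BH adjustment, ortholog filtering."""

import math
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reprognet.io import GeneSetCollection, OrthologMap
from reprognet.set_statistics import (
    bh_adjust,
    enrich,
    filter_ortholog_map,
    fisher_overlap,
    significant,
)


def hypergeom_tail(k, n_a, n_b, n_universe):
    """Upper-tail P(X >= k) by direct summation of the closed-form pmf."""
    total = 0.0
    for x in range(k, min(n_a, n_b) + 1):
        total += (
            math.comb(n_a, x)
            * math.comb(n_universe - n_a, n_b - x)
            / math.comb(n_universe, n_b)
        )
    return total


def symbols(n, prefix="G"):
    return [f"{prefix}{i:03d}" for i in range(n)]


class TestFisherOverlap:
    def test_full_overlap_closed_form(self):
        uni = symbols(10)
        res = fisher_overlap(uni[:5], uni[:5], uni)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5))
        assert res.n_overlap == 5

    def test_a_equals_universe_forces_p_one(self):
        uni = symbols(10)
        res = fisher_overlap(uni, uni[:4], uni)
        assert res.p_value == pytest.approx(1.0)

    def test_members_outside_universe_dropped(self, caplog):
        uni = symbols(10)
        with caplog.at_level("INFO"):
            res = fisher_overlap(uni[:3] + ["ALIEN"], uni[:3], uni)
        assert res.n_a == 3
        assert any("outside" in r.message for r in caplog.records)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_overlap({"A"}, {"B"}, set())

    def test_matches_exhaustive_enumeration_small_universes(self):
        for n_universe in range(2, 13):
            uni = symbols(n_universe)
            for n_a, n_b in product(range(1, n_universe + 1), repeat=2):
                for k in range(max(0, n_a + n_b - n_universe), min(n_a, n_b) + 1):
                    a = set(uni[:n_a])
                    b = set(uni[:k]) | set(uni[n_a : n_a + n_b - k])
                    res = fisher_overlap(a, b, uni)
                    assert res.n_overlap == k
                    assert res.p_value == pytest.approx(
                        hypergeom_tail(k, n_a, n_b, n_universe), rel=1e-9
                    )

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=25)
    def test_relabelling_universe_leaves_p_unchanged(self, offset):
        uni = symbols(12)
        relabel = {s: f"X{offset}_{s}" for s in uni}
        a, b = uni[:5], uni[3:9]
        before = fisher_overlap(a, b, uni)
        after = fisher_overlap(
            [relabel[s] for s in a], [relabel[s] for s in b], relabel.values()
        )
        assert before.p_value == after.p_value
        assert before.odds_ratio == after.odds_ratio


class TestEnrich:
    def collection(self):
        uni = symbols(100)
        return uni, GeneSetCollection(
            sets={"hit": frozenset(uni[:10]), "miss": frozenset(uni[50:60])},
            universe=frozenset(uni),
        )

    def test_whole_set_query_closed_form(self):
        uni, coll = self.collection()
        rows = {r.set_name: r for r in enrich(set(uni[:10]), coll)}
        assert rows["hit"].fold_enrichment == pytest.approx(10.0)
        assert rows["hit"].p_value == pytest.approx(1 / math.comb(100, 10))

    def test_disjoint_query_fold_zero_p_one(self):
        uni, coll = self.collection()
        row = {r.set_name: r for r in enrich(set(uni[20:30]), coll)}["hit"]
        assert row.k == 0 and row.fold_enrichment == 0.0 and row.p_value == 1.0

    def test_identical_sets_get_identical_adjusted_p(self):
        uni = symbols(50)
        coll = GeneSetCollection(
            sets={"s1": frozenset(uni[:8]), "s2": frozenset(uni[:8])},
            universe=frozenset(uni),
        )
        rows = enrich(set(uni[:8]), coll)
        assert rows[0].p_value == rows[1].p_value
        assert rows[0].adjusted_p == rows[1].adjusted_p

    def test_collection_equal_to_universe_is_null(self):
        uni = symbols(30)
        coll = GeneSetCollection(
            sets={"all": frozenset(uni)}, universe=frozenset(uni)
        )
        (row,) = enrich(set(uni[:7]), coll)
        assert row.fold_enrichment == pytest.approx(1.0)
        assert row.p_value == pytest.approx(1.0)

    def test_empty_intersection_warns_and_returns_empty(self, caplog):
        _, coll = self.collection()
        with caplog.at_level("WARNING"):
            assert enrich({"NOT_THERE"}, coll) == []
        assert caplog.records

    def test_ease_variant_is_more_conservative(self):
        uni, coll = self.collection()
        plain = {r.set_name: r for r in enrich(set(uni[:10]), coll)}["hit"]
        ease = {r.set_name: r for r in enrich(set(uni[:10]), coll, ease=True)}["hit"]
        assert ease.p_value > plain.p_value

    def test_reporting_filter_applies_both_thresholds(self):
        uni, coll = self.collection()
        rows = enrich(set(uni[:10]), coll)
        kept = significant(rows, max_adjusted_p=0.001, min_fold=2.0)
        assert [r.set_name for r in kept] == ["hit"]


class TestBHAdjust:
    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_p_unchanged(self):
        assert bh_adjust([0.05] * 6) == pytest.approx([0.05] * 6)

    def test_adjusted_at_least_raw_and_capped(self):
        raw = [0.001, 0.5, 0.9, 0.04, 1.0]
        adj = bh_adjust(raw)
        assert all(a >= p for a, p in zip(adj, raw))
        assert all(a <= 1.0 for a in adj)


class TestOrthologFilter:
    def test_min_score_filter(self):
        omap = OrthologMap(rows=(("A", "a1", 1.0), ("B", "b1", 1.0), ("C", "c1", 0.8)))
        kept = filter_ortholog_map(omap, min_score=1.0)
        assert kept == {"A": frozenset({"a1"}), "B": frozenset({"b1"})}

    def test_empty_map(self):
        assert filter_ortholog_map(OrthologMap(rows=()), 1.0) == {}

    def test_duplicates_and_one_to_many(self):
        omap = OrthologMap(
            rows=(("A", "a1", 1.0), ("A", "a1", 1.0), ("A", "a2", 1.0))
        )
        assert filter_ortholog_map(omap, 1.0) == {"A": frozenset({"a1", "a2"})}
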