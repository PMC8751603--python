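"""Cocktail combinatorics, canonicalization and target aggregation."""

import math

import pytest

from conftest import chem_record
from reprognet import cocktail as ck
from reprognet.io import TFTargetTable


@pytest.fixture(scope="module")
def catalog():
    return ck.load_catalog()


@pytest.fixture(scope="module")
def cocktails(catalog):
    return ck.load_cocktails(catalog=catalog)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "variant,expected",
        [
            ("VPA", "Valproic acid"),
            ("RepSOX", "RepSox"),
            ("vpa", "Valproic acid"),
            ("TSA", "Trichostatin A"),
            ("6", "RepSox"),
            ("AM580", "AM 580"),
        ],
    )
    def test_variants_resolve(self, catalog, variant, expected):
        assert ck.canonicalize(variant, catalog) == expected

    def test_unknown_name_lists_near_matches(self, catalog):
        with pytest.raises(KeyError, match="Forskolin"):
            ck.canonicalize("Forskolim", catalog)

    def test_overlapping_synonym_sets_rejected(self):
        catalog = [
            ck.SMRecord("A", frozenset({"X"}), frozenset({"other"})),
            ck.SMRecord("B", frozenset({"x"}), frozenset({"other"})),
        ]
        with pytest.raises(ValueError, match="disjoint"):
            ck.canonicalize("A", catalog)


class TestCombinatorics:
    def test_packaged_cocktails_union_is_22(self, cocktails):
        assert len(ck.cocktail_union(cocktails)) == 22

    def test_union_of_identical_cocktails(self, cocktails):
        c = cocktails[2]
        assert ck.cocktail_union([c, c]) == set(c.members)

    def test_empty_input_union(self):
        assert ck.cocktail_union([]) == frozenset()

    def test_packaged_frequencies(self, cocktails):
        freq = ck.sm_frequency(cocktails)
        assert freq["RepSox"] == 7
        assert freq["Valproic acid"] == 6
        assert freq["Forskolin"] == 6
        assert freq["Parnate"] == 5
        assert freq["DZNep"] == 4
        assert freq["AM 580"] == 3
        assert freq["EPZ004777"] == 2
        # known internal discrepancy of the source listings: the Methods
        # compositions place CHIR99021 in 8 cocktails
        assert freq["CHIR99021"] == 8

    def test_frequency_sorted_desc_then_name(self, cocktails):
        freq = ck.sm_frequency(cocktails)
        items = list(freq.items())
        assert items == sorted(items, key=lambda kv: (-kv[1], kv[0]))

    def test_frequency_mass_conservation(self, cocktails):
        freq = ck.sm_frequency(cocktails)
        assert sum(freq.values()) == sum(len(c.members) for c in cocktails)

    def test_single_cocktail_counts_ones(self, cocktails):
        freq = ck.sm_frequency([cocktails[0]])
        assert set(freq.values()) == {1}

    def test_union_bounded_by_total_size(self, cocktails):
        assert len(ck.cocktail_union(cocktails)) <= sum(len(c.members) for c in cocktails)


class TestCategoryCoverage:
    def test_cocktail_2_covers_all_three(self, catalog, cocktails):
        nls = next(c for c in cocktails if "NLS" in c.name)
        counts = ck.category_coverage(nls, catalog)
        assert counts.get("epigenetic", 0) >= 1
        assert counts.get("metabolic", 0) >= 1
        assert counts.get("signaling", 0) >= 1

    def test_all_packaged_cocktails_cover_core_categories(self, catalog, cocktails):
        assert all(ck.covers_core_categories(c, catalog) for c in cocktails)

    def test_single_signaling_sm_fails_predicate(self, catalog):
        c = ck.CocktailDefinition(name="toy", members=("Forskolin",))
        assert ck.category_coverage(c, catalog) == {"signaling": 1}
        assert not ck.covers_core_categories(c, catalog)


class TestAggregateTargets:
    def test_union_of_member_targets(self):
        c = ck.CocktailDefinition(name="toy", members=("M1", "M2"))
        table = [
            chem_record("M1", "P1"), chem_record("M1", "P2"),
            chem_record("M2", "P2"), chem_record("M2", "P3"),
        ]
        assert ck.aggregate_targets(c, table) == {"P1", "P2", "P3"}

    def test_threshold_filters_and_warns_when_empty(self, caplog):
        c = ck.CocktailDefinition(name="toy", members=("M1",))
        table = [chem_record("M1", "P1", combined=0.3)]
        assert ck.aggregate_targets(c, table, threshold=0.4) == frozenset()
        with caplog.at_level("WARNING"):
            ck.aggregate_targets(c, table, threshold=0.9)
        assert caplog.records

    def test_id_map_translates_names(self):
        c = ck.CocktailDefinition(name="toy", members=("Valproic acid",))
        table = [chem_record("CID123", "P1")]
        got = ck.aggregate_targets(c, table, id_map={"Valproic acid": "CID123"})
        assert got == {"P1"}


class TestTFComparison:
    def universe(self):
        return {f"G{i:02d}" for i in range(20)}

    def test_disjoint_sets_p_one(self):
        uni = sorted(self.universe())
        tf = TFTargetTable(pairs=tuple(("SOX2", g) for g in uni[:5]))
        res = ck.compare_to_tf_targets(set(uni[10:15]), tf, {"SOX2"}, uni)
        assert res.p_value == pytest.approx(1.0)

    def test_identical_sets_closed_form(self):
        uni = [f"G{i:02d}" for i in range(10)]
        tf = TFTargetTable(pairs=tuple(("SOX2", g) for g in uni[:5]))
        res = ck.compare_to_tf_targets(set(uni[:5]), tf, {"SOX2"}, uni)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5))

    def test_empty_restricted_tf_set_errors(self):
        tf = TFTargetTable(pairs=(("SOX2", "OUTSIDE"),))
        with pytest.raises(ValueError, match="empty"):
            ck.compare_to_tf_targets({"G01"}, tf, {"SOX2"}, self.universe())


class TestFixtures:
    def test_catalog_has_22_sms_with_nonempty_categories(self, catalog):
        assert len(catalog) == 22
        assert all(sm.category for sm in catalog)

    def test_ten_cocktails_min_size_three(self, cocktails):
        assert len(cocktails) == 10
        assert min(len(c.members) for c in cocktails) == 3

    def test_human_metabolome_list_has_28_compounds(self):
        sms = ck.load_human_metabolome_sms()
        assert len(sms) == 28
        assert len(set(sms)) == 28
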