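"""Classification rules, manual fallback, and the membership table."""

import pytest

from foodscape import (
    BaseCategory,
    Classification,
    Definition,
    Method,
    automation_fraction,
    classify_systematic,
    filter_branch_codes,
    membership,
)
from foodscape.data_model import ManualAnnotation, ExclusionReason
from foodscape.taxonomy import (
    ClassificationOutcome,
    Rule,
    RuleSet,
    UNDIVIDED_CLASSIFICATIONS,
    apply_manual,
    classification_cells,
)

from conftest import make_record

import math


class TestBranchFilter:
    def test_food_retail_code_kept(self):
        kept, dropped = filter_branch_codes(
            [make_record(branch_code="DD.56.10.99")]
        )
        assert len(kept) == 1 and not dropped

    def test_non_food_code_dropped_with_count(self):
        kept, dropped = filter_branch_codes(
            [make_record(branch_code="DD.96.02.00")]
        )
        assert kept == [] and dropped["DD.96.02.00"] == 1

    def test_empty_input(self):
        kept, dropped = filter_branch_codes([])
        assert kept == [] and not dropped


class TestClassifySystematic:
    @pytest.mark.parametrize(
        "name, code, expected",
        [
            ("McDonalds", "DD.56.10.99", BaseCategory.MAJOR_FASTFOOD_CHAIN),
            ("City Pizza & Burger House", "DD.56.10.99",
             BaseCategory.NONCHAIN_FASTFOOD),
            ("7-eleven", "DD.47.10.99", BaseCategory.CONVENIENCE_CHAIN),
            ("Noma", "DD.56.10.99", BaseCategory.TRADITIONAL_RESTAURANT),
            ("Føtex", "DD.47.10.99", BaseCategory.LARGE_SUPERMARKET_CHAIN),
        ],
    )
    def test_rule_hits(self, rules, name, code, expected):
        oc = classify_systematic(make_record(name=name, branch_code=code), rules)
        assert oc.method == Method.SYSTEMATIC
        assert oc.base_category == expected
        assert oc.matched_rule is not None

    def test_no_rule_fires(self, rules):
        oc = classify_systematic(
            make_record(name="Hos Olga", branch_code="DD.56.10.99"), rules
        )
        assert oc.method == Method.UNCLASSIFIED and oc.base_category is None

    def test_wrong_branch_code_blocks_name_rule(self, rules):
        # a fast-food product word needs a food-service branch code
        oc = classify_systematic(
            make_record(name="Valby Burger", branch_code="DD.47.10.99"), rules
        )
        assert oc.method == Method.UNCLASSIFIED

    def test_longest_term_wins_conflicts(self, rules):
        # "burger king" (major chain) must beat the generic token "burger"
        oc = classify_systematic(
            make_record(name="Burger King Amager", branch_code="DD.56.10.99"),
            rules,
        )
        assert oc.base_category == BaseCategory.MAJOR_FASTFOOD_CHAIN
        # "superbrugsen" (large chain) must beat the substring "brugsen"
        oc = classify_systematic(
            make_record(name="SuperBrugsen Valby", branch_code="DD.47.10.99"),
            rules,
        )
        assert oc.base_category == BaseCategory.LARGE_SUPERMARKET_CHAIN

    def test_tie_between_categories_leaves_unclassified(self):
        rules = RuleSet(rules=[
            Rule(frozenset({"DD.56.10.99"}), "pizza", "token",
                 BaseCategory.NONCHAIN_FASTFOOD),
            Rule(frozenset({"DD.56.10.99"}), "salat", "token",
                 BaseCategory.CAFE_ALLDAY),
        ])
        oc = classify_systematic(
            make_record(name="Pizza Salat Huset", branch_code="DD.56.10.99"),
            rules,
        )
        assert oc.method == Method.UNCLASSIFIED

    def test_order_independent(self, rules):
        rec = make_record(name="Burger King", branch_code="DD.56.10.99")
        reversed_rules = RuleSet(rules=list(reversed(rules.rules)))
        assert (
            classify_systematic(rec, rules).base_category
            == classify_systematic(rec, reversed_rules).base_category
        )


class TestApplyManual:
    def test_annotation_classifies_unclassified_record(self, rules):
        rec = make_record(
            name="Hos Olga", branch_code="DD.56.10.99",
            annotation=ManualAnnotation(
                base_category=BaseCategory.TRADITIONAL_RESTAURANT.value
            ),
        )
        (oc,) = apply_manual([classify_systematic(rec, rules)], [rec])
        assert oc.method == Method.MANUAL
        assert oc.base_category == BaseCategory.TRADITIONAL_RESTAURANT

    def test_exclusion_annotation(self, rules):
        rec = make_record(
            name="Vinhandlen", branch_code="DD.47.10.99",
            annotation=ManualAnnotation(
                excluded=True, exclusion_reason=ExclusionReason.IRRELEVANT
            ),
        )
        (oc,) = apply_manual([classify_systematic(rec, rules)], [rec])
        assert oc.method == Method.EXCLUDED and oc.base_category is None

    def test_systematic_outcome_takes_precedence(self, rules):
        rec = make_record(
            name="McDonalds", branch_code="DD.56.10.99",
            annotation=ManualAnnotation(
                base_category=BaseCategory.TRADITIONAL_RESTAURANT.value
            ),
        )
        (oc,) = apply_manual([classify_systematic(rec, rules)], [rec])
        assert oc.method == Method.SYSTEMATIC
        assert oc.base_category == BaseCategory.MAJOR_FASTFOOD_CHAIN


class TestMembership:
    @pytest.mark.parametrize(
        "cat, c, d, expected",
        [
            (BaseCategory.MAJOR_FASTFOOD_CHAIN, Classification.FAST_FOOD,
             Definition.NARROW, True),
            (BaseCategory.RETAIL_BAKERY_CHAIN, Classification.FAST_FOOD,
             Definition.NARROW, False),
            (BaseCategory.RETAIL_BAKERY_CHAIN, Classification.FAST_FOOD,
             Definition.BROAD, True),
            (BaseCategory.RETAIL_BAKERY_CHAIN, Classification.RESTAURANT,
             Definition.BROAD, True),
            (BaseCategory.GROCERY_CHAIN, Classification.SUPERMARKET,
             Definition.BROAD, True),
            (BaseCategory.PETROL_KIOSK, Classification.CONVENIENCE,
             Definition.NARROW, True),
            (BaseCategory.PETROL_KIOSK, Classification.SUPERMARKET,
             Definition.BROAD, True),
            (BaseCategory.PETROL_KIOSK, Classification.SUPERMARKET,
             Definition.MODERATE, False),
            (BaseCategory.TRADITIONAL_RESTAURANT, Classification.FAST_FOOD,
             Definition.BROAD, False),
        ],
    )
    def test_table_entries(self, cat, c, d, expected):
        assert membership(cat, c, d) is expected

    def test_nesting_narrow_moderate_broad_full_table(self):
        for cat in BaseCategory:
            for c in Classification:
                if c in UNDIVIDED_CLASSIFICATIONS:
                    continue
                narrow = membership(cat, c, Definition.NARROW)
                moderate = membership(cat, c, Definition.MODERATE)
                broad = membership(cat, c, Definition.BROAD)
                assert (not narrow or moderate) and (not moderate or broad)

    def test_undivided_classifications_ignore_definition(self):
        for d in (None, Definition.NARROW, Definition.BROAD):
            assert membership(
                BaseCategory.FRUIT_VEGETABLE_STORE,
                Classification.FRUIT_AND_VEGETABLE, d,
            )
            assert membership(BaseCategory.BUTCHER,
                              Classification.MISCELLANEOUS, d)

    def test_every_category_has_a_home(self):
        cells = classification_cells()
        for cat in BaseCategory:
            assert any(membership(cat, c, d) for c, d in cells)


class TestAutomationFraction:
    def _oc(self, rid, cat, method, rules):
        if method == Method.SYSTEMATIC:
            rule = next(r for r in rules.rules if r.base_category == cat)
            return ClassificationOutcome(rid, cat, method, rule)
        return ClassificationOutcome(rid, cat, method)

    def test_all_systematic_is_one(self, rules):
        ocs = [
            self._oc(f"r{i}", BaseCategory.DISCOUNT_SUPERMARKET,
                     Method.SYSTEMATIC, rules)
            for i in range(5)
        ]
        assert automation_fraction(
            ocs, Classification.SUPERMARKET, Definition.MODERATE
        ) == 1.0

    def test_mixed_fraction(self, rules):
        ocs = [
            self._oc(f"s{i}", BaseCategory.LARGE_SUPERMARKET_CHAIN,
                     Method.SYSTEMATIC, rules)
            for i in range(96)
        ] + [
            self._oc(f"m{i}", BaseCategory.DISCOUNT_SUPERMARKET, Method.MANUAL,
                     rules)
            for i in range(4)
        ]
        assert automation_fraction(
            ocs, Classification.SUPERMARKET, Definition.MODERATE
        ) == pytest.approx(0.96)

    def test_empty_cell_is_undefined(self):
        assert math.isnan(automation_fraction(
            [], Classification.FAST_FOOD, Definition.NARROW
        ))
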