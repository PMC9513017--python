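"""Outlet classification: branch-code filter, name-rule engine, membership table.

The register's branch codes are too coarse to tell outlet types apart, so
classification combines a branch code with name rules (chain names matched
as substrings, generic product words matched as whole tokens).  Records the
rules cannot place fall through to a manual-annotation file.  Classified
outlets are then mapped into six classifications, four of which are split
into nested narrow ⊆ moderate ⊆ broad definitions.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .data_model import (
    ExclusionReason,
    NormalizedName,
    OutletRecord,
    normalize_name,
)

log = logging.getLogger("foodscape")

#: DB07 branch codes for food retail kept by the study filter.
FOOD_RETAIL_BRANCH_CODES = frozenset({
    "DD.10.71.20",  # bakeries etc.
    "DD.47.10.99",  # food stores
    "DD.47.20.99",  # other retail of food in specialised stores
    "DD.47.22.00",  # butcheries / fish retailers (shared code)
    "DD.56.10.99",  # restaurants, cantinas etc.
    "DD.56.30.99",  # catering businesses
})


class BaseCategory(str, Enum):
    MAJOR_FASTFOOD_CHAIN = "major_fastfood_chain"
    NONCHAIN_FASTFOOD = "nonchain_fastfood"
    TAKEAWAY_LIMITED_SEATING = "takeaway_limited_seating"
    RETAIL_BAKERY_CHAIN = "retail_bakery_chain"
    CHAIN_COFFEE_SHOP = "chain_coffee_shop"
    PETROL_KIOSK = "petrol_kiosk"
    CONVENIENCE_CHAIN = "convenience_chain"
    GROCERY_CHAIN = "grocery_chain"
    LARGE_SUPERMARKET_CHAIN = "large_supermarket_chain"
    DISCOUNT_SUPERMARKET = "discount_supermarket"
    TRADITIONAL_RESTAURANT = "traditional_restaurant"
    CAFE_ALLDAY = "cafe_allday"
    FRUIT_VEGETABLE_STORE = "fruit_vegetable_store"
    BAKERY = "bakery"
    BUTCHER = "butcher"
    FISHMONGER = "fishmonger"


class Classification(str, Enum):
    FAST_FOOD = "fast_food"
    CONVENIENCE = "convenience"
    SUPERMARKET = "supermarket"
    RESTAURANT = "restaurant"
    FRUIT_AND_VEGETABLE = "fruit_and_vegetable"
    MISCELLANEOUS = "miscellaneous"


class Definition(str, Enum):
    NARROW = "narrow"
    MODERATE = "moderate"
    BROAD = "broad"


_DEF_RANK = {Definition.NARROW: 0, Definition.MODERATE: 1, Definition.BROAD: 2}

#: Classifications with a single, definition-free membership set.
UNDIVIDED_CLASSIFICATIONS = frozenset(
    {Classification.FRUIT_AND_VEGETABLE, Classification.MISCELLANEOUS}
)

# Minimal definition at which each base category enters a classification.
# Nesting (narrow ⊆ moderate ⊆ broad) is by construction: membership at a
# definition means the category's minimal definition is at most that wide.
_MINIMAL_DEFINITION: dict[Classification, dict[BaseCategory, Definition]] = {
    Classification.FAST_FOOD: {
        BaseCategory.MAJOR_FASTFOOD_CHAIN: Definition.NARROW,
        BaseCategory.NONCHAIN_FASTFOOD: Definition.MODERATE,
        BaseCategory.TAKEAWAY_LIMITED_SEATING: Definition.MODERATE,
        BaseCategory.RETAIL_BAKERY_CHAIN: Definition.BROAD,
        BaseCategory.BAKERY: Definition.BROAD,
        BaseCategory.CHAIN_COFFEE_SHOP: Definition.BROAD,
    },
    Classification.CONVENIENCE: {
        BaseCategory.PETROL_KIOSK: Definition.NARROW,
        BaseCategory.CONVENIENCE_CHAIN: Definition.MODERATE,
        BaseCategory.GROCERY_CHAIN: Definition.BROAD,
    },
    Classification.SUPERMARKET: {
        BaseCategory.LARGE_SUPERMARKET_CHAIN: Definition.NARROW,
        BaseCategory.DISCOUNT_SUPERMARKET: Definition.MODERATE,
        BaseCategory.PETROL_KIOSK: Definition.BROAD,
        BaseCategory.CONVENIENCE_CHAIN: Definition.BROAD,
        BaseCategory.GROCERY_CHAIN: Definition.BROAD,
    },
    Classification.RESTAURANT: {
        BaseCategory.TRADITIONAL_RESTAURANT: Definition.NARROW,
        BaseCategory.CAFE_ALLDAY: Definition.MODERATE,
        BaseCategory.CHAIN_COFFEE_SHOP: Definition.BROAD,
        BaseCategory.RETAIL_BAKERY_CHAIN: Definition.BROAD,
    },
}

_UNDIVIDED_MEMBERS: dict[Classification, frozenset[BaseCategory]] = {
    Classification.FRUIT_AND_VEGETABLE: frozenset(
        {BaseCategory.FRUIT_VEGETABLE_STORE}
    ),
    Classification.MISCELLANEOUS: frozenset(
        {BaseCategory.BAKERY, BaseCategory.BUTCHER, BaseCategory.FISHMONGER}
    ),
}


def membership(
    category: BaseCategory,
    classification: Classification,
    definition: Optional[Definition] = None,
) -> bool:
    """Whether ``category`` belongs to (classification, definition).

    Fruit-and-vegetable and miscellaneous carry a single membership set and
    ignore ``definition``; for the other four classifications the sets nest:
    narrow ⊆ moderate ⊆ broad.
    """
    category = BaseCategory(category)
    classification = Classification(classification)
    if classification in UNDIVIDED_CLASSIFICATIONS:
        return category in _UNDIVIDED_MEMBERS[classification]
    if definition is None:
        raise ValueError(f"{classification.value} requires a definition")
    minimal = _MINIMAL_DEFINITION[classification].get(category)
    return minimal is not None and _DEF_RANK[minimal] <= _DEF_RANK[Definition(definition)]


def classification_cells() -> list[tuple[Classification, Optional[Definition]]]:
    """All (classification, definition) cells of the taxonomy table."""
    cells: list[tuple[Classification, Optional[Definition]]] = []
    for c in Classification:
        if c in UNDIVIDED_CLASSIFICATIONS:
            cells.append((c, None))
        else:
            cells.extend((c, d) for d in Definition)
    return cells


# ---------------------------------------------------------------------------
# Rule engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    branch_codes: frozenset[str]
    term: str                      # normalized
    match_mode: str                # "token" or "substring"
    base_category: BaseCategory

    def matches(self, name: NormalizedName, branch_code: Optional[str]) -> bool:
        if branch_code not in self.branch_codes:
            return False
        if self.match_mode == "substring":
            return self.term in name.joined
        term_tokens = tuple(self.term.split())
        n = len(term_tokens)
        return any(
            name.tokens[i:i + n] == term_tokens
            for i in range(len(name.tokens) - n + 1)
        )


@dataclass
class RuleSet:
    rules: list[Rule]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple[frozenset, str], BaseCategory] = {}
        for r in self.rules:
            key = (r.branch_codes, r.term)
            if not r.term:
                raise ValueError("empty rule term")
            if seen.get(key, r.base_category) != r.base_category:
                raise ValueError(f"conflicting rules for term {r.term!r}")
            seen[key] = r.base_category


def load_rules(path: Union[str, Path, None] = None) -> RuleSet:
    """Load classification rules from a TSV file (default: packaged rules).

    Columns: branch_codes (semicolon-separated), term, match_mode
    {token, substring}, base_category.
    """
    if path is None:
        ref = resources.files("foodscape").joinpath("data/rules.tsv")
        text = ref.read_text(encoding="utf-8")
        provenance = "foodscape packaged rules"
    else:
        text = Path(path).read_text(encoding="utf-8")
        provenance = str(path)
    rules = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        rules.append(Rule(
            branch_codes=frozenset(
                c.strip() for c in row["branch_codes"].split(";") if c.strip()
            ),
            term=normalize_name(row["term"]).joined,
            match_mode=row["match_mode"].strip(),
            base_category=BaseCategory(row["base_category"].strip()),
        ))
    return RuleSet(rules=rules, provenance=provenance)


class Method(str, Enum):
    SYSTEMATIC = "systematic"
    MANUAL = "manual"
    UNCLASSIFIED = "unclassified"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class ClassificationOutcome:
    record_id: str
    base_category: Optional[BaseCategory]
    method: Method
    matched_rule: Optional[Rule] = None

    def __post_init__(self) -> None:
        if self.method == Method.SYSTEMATIC and self.matched_rule is None:
            raise ValueError("systematic outcome requires a matched rule")
        if self.method == Method.EXCLUDED and self.base_category is not None:
            raise ValueError("excluded outcome carries no category")


def filter_branch_codes(
    records: Sequence[OutletRecord],
) -> tuple[list[OutletRecord], Counter]:
    """Keep register records whose branch code is a food-retail DB07 code.

    Returns the retained records and a count of dropped codes for reporting.
    """
    kept, dropped = [], Counter()
    for r in records:
        if r.branch_code in FOOD_RETAIL_BRANCH_CODES:
            kept.append(r)
        else:
            dropped[r.branch_code or "<missing>"] += 1
    if dropped:
        log.info("branch-code filter dropped %d records", sum(dropped.values()))
    return kept, dropped


def classify_systematic(
    record: OutletRecord, rules: RuleSet
) -> ClassificationOutcome:
    """Classify one record from name rules combined with its branch code.

    Every matching rule is collected; if all agree on a category the record
    is classified systematically.  Conflicts are resolved in favour of the
    longest matching term (a longer term is more specific — "burger king"
    beats "burger"); a length tie between different categories leaves the
    record unclassified.
    """
    name = normalize_name(record.raw_name)
    hits = [r for r in rules.rules if r.matches(name, record.branch_code)]
    if not hits:
        return ClassificationOutcome(record.record_id, None, Method.UNCLASSIFIED)
    categories = {r.base_category for r in hits}
    if len(categories) == 1:
        best = max(hits, key=lambda r: (len(r.term), r.term))
        return ClassificationOutcome(
            record.record_id, best.base_category, Method.SYSTEMATIC, best
        )
    best_len = max(len(r.term) for r in hits)
    longest = [r for r in hits if len(r.term) == best_len]
    if len({r.base_category for r in longest}) == 1:
        best = sorted(longest, key=lambda r: r.term)[0]
        return ClassificationOutcome(
            record.record_id, best.base_category, Method.SYSTEMATIC, best
        )
    return ClassificationOutcome(record.record_id, None, Method.UNCLASSIFIED)


def apply_manual(
    outcomes: Sequence[ClassificationOutcome],
    records: Sequence[OutletRecord],
) -> list[ClassificationOutcome]:
    """Fold manual annotations into systematic outcomes.

    Annotations only affect records the rules left unclassified; a manual
    category contradicting a systematic outcome is logged and ignored
    (systematic takes precedence, mirroring the two-stage order).  Records
    that remain unclassified are counted in the log for follow-up.
    """
    by_id = {r.record_id: r for r in records}
    out: list[ClassificationOutcome] = []
    still_unclassified = 0
    for oc in outcomes:
        rec = by_id.get(oc.record_id)
        ann = rec.annotation if rec else None
        if oc.method == Method.SYSTEMATIC:
            if ann and ann.base_category and (
                BaseCategory(ann.base_category) != oc.base_category
            ):
                log.warning(
                    "record %s: manual annotation %s contradicts systematic %s; "
                    "keeping systematic",
                    oc.record_id, ann.base_category, oc.base_category.value,
                )
            out.append(oc)
            continue
        if ann is None:
            still_unclassified += 1
            out.append(oc)
            continue
        if ann.excluded:
            out.append(ClassificationOutcome(oc.record_id, None, Method.EXCLUDED))
        elif ann.base_category:
            out.append(ClassificationOutcome(
                oc.record_id, BaseCategory(ann.base_category), Method.MANUAL
            ))
        else:
            still_unclassified += 1
            out.append(oc)
    if still_unclassified:
        log.info("%d records remain unclassified after manual step",
                 still_unclassified)
    return out


def classify_all(
    records: Sequence[OutletRecord], rules: Optional[RuleSet] = None
) -> list[ClassificationOutcome]:
    """Systematic pass over all records followed by the manual fold-in."""
    rules = rules or load_rules()
    outcomes = [classify_systematic(r, rules) for r in records]
    return apply_manual(outcomes, records)


#: Sentinel returned where a proportion has an empty denominator.
UNDEFINED = float("nan")


def automation_fraction(
    outcomes: Sequence[ClassificationOutcome],
    classification: Classification,
    definition: Optional[Definition],
) -> float:
    """Share of classified outlets in a taxonomy cell placed by the rules alone.

    Returns NaN when the cell holds no classified outlet.
    """
    member = [
        oc for oc in outcomes
        if oc.method in (Method.SYSTEMATIC, Method.MANUAL)
        and oc.base_category is not None
        and membership(oc.base_category, classification, definition)
    ]
    if not member:
        return UNDEFINED
    n_sys = sum(1 for oc in member if oc.method == Method.SYSTEMATIC)
    return n_sys / len(member)
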