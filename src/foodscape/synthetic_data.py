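"""Synthetic register/field outlet pairs with known ground truth.

The generator emulates the error structure of an administrative outlet
register validated against a field audit: outlets trading without
registration (future false negatives), stale register entries for closed
outlets (false positives), isotropic positional error with a configurable
median magnitude, and banner-name discrepancies between the registered
legal name and the storefront name.  Every stream is seeded, and the
bookkeeping (which true outlet each record derives from) yields exact
expected confusion counts independent of the matcher.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .data_model import (
    GridCell,
    ManualAnnotation,
    OpenStatus,
    OutletRecord,
    Source,
    write_geojson,
    write_outlets,
)
from .grid_sampling import LocalProjection, SamplerConfig, build_grid, \
    select_empty_grids, select_study_grids
from .taxonomy import BaseCategory, Method, RuleSet, classify_systematic, load_rules

_EARTH_RADIUS_M = 6_371_000.0

# half-normal median = sigma * Phi^-1(0.75)
_HALF_NORMAL_MEDIAN_FACTOR = 0.6744897501960817


# ---------------------------------------------------------------------------
# Name pools (chain banners plus generated non-chain names)
# ---------------------------------------------------------------------------

_WORDS = [
    "Nørrebro", "Vesterbro", "Østerbro", "Amager", "Valby", "Frederiksberg",
    "Hellerup", "Lyngby", "Gentofte", "Herlev", "Rødovre", "Glostrup",
    "Hvidovre", "Ballerup", "Søborg", "Byens", "Havnens", "Torvets",
    "Parkens", "Solsiden", "Gamle", "Golden", "Bella", "Luna", "Roma",
    "Milano", "Verona", "Istanbul", "Ankara", "Tokyo", "Saigon", "Bangkok",
]
_SURNAMES = [
    "Hansen", "Jensen", "Nielsen", "Larsen", "Olsen", "Pedersen", "Andersen",
    "Madsen", "Christensen", "Sørensen", "Mortensen", "Knudsen",
]

_CHAIN_POOLS: dict[BaseCategory, list[str]] = {
    BaseCategory.MAJOR_FASTFOOD_CHAIN: [
        "McDonalds", "Burger King", "KFC", "Subway", "Dominos",
        "Sunset Boulevard", "Max Burger",
    ],
    BaseCategory.RETAIL_BAKERY_CHAIN: [
        "Lagkagehuset", "Emmerys", "Meyers Bageri", "Bodenhoffs Bageri",
        "Farumhus", "Laglace", "City Bakery", "Grannys House",
        "Reinh van Haun",
    ],
    BaseCategory.CHAIN_COFFEE_SHOP: [
        "Espresso House", "Starbucks", "Baresso Coffee",
    ],
    BaseCategory.PETROL_KIOSK: ["Shell", "Circle K", "Uno X", "OK Plus", "Q8"],
    BaseCategory.CONVENIENCE_CHAIN: [
        "7-Eleven", "Nærkøb", "Letkøb", "Elite Købmand", "Shop N Play",
    ],
    BaseCategory.GROCERY_CHAIN: [
        "DagligBrugsen", "LokalBrugsen", "Spar", "KwikSpar", "Min Købmand",
        "Brugsen",
    ],
    BaseCategory.LARGE_SUPERMARKET_CHAIN: [
        "Bilka", "Kvickly", "SuperBrugsen", "Irma", "Føtex", "SuperBest",
        "SuperSpar", "EuroSpar", "Løvbjerg", "ABC Lavpris", "MENY",
    ],
    BaseCategory.DISCOUNT_SUPERMARKET: [
        "Fakta", "Netto", "Kiwi", "Rema 1000", "Aldi",
    ],
}

_PATTERN_POOLS: dict[BaseCategory, list[str]] = {
    BaseCategory.NONCHAIN_FASTFOOD: [
        "{w} Burger", "{w} Pizza", "Pizzeria {w}", "{w} Kebab", "{w} Grill",
        "Sushi {w}", "{w} Durum House",
    ],
    BaseCategory.TAKEAWAY_LIMITED_SEATING: [
        "{w} Takeaway", "{w} Wok", "Shawarma {w}", "{w} Take Away",
    ],
    BaseCategory.CHAIN_COFFEE_SHOP: ["{w} Coffee"],
    BaseCategory.PETROL_KIOSK: ["{w} Kiosk", "Kiosken {w}"],
    BaseCategory.TRADITIONAL_RESTAURANT: [
        "Restaurant {w}", "Ristorante {w}", "Trattoria {w}", "Bistro {w}",
        "Hos {s}",
    ],
    BaseCategory.CAFE_ALLDAY: ["Café {w}", "Cafeteria {w}", "{s}s Café"],
    BaseCategory.FRUIT_VEGETABLE_STORE: [
        "{w} Frugt & Grønt", "Minimarked {w}", "{w} Grønt",
    ],
    BaseCategory.BAKERY: ["{w} Bageri", "Bageriet {w}", "{s}s Konditori"],
    BaseCategory.BUTCHER: ["Slagter {s}", "Slagtermester {s}"],
    BaseCategory.FISHMONGER: ["{w} Fisk", "Fiskehandler {s}"],
}


def draw_name(category: BaseCategory, rng: np.random.Generator) -> str:
    """Draw a banner name for a category from the shipped pools."""
    chains = _CHAIN_POOLS.get(category)
    patterns = _PATTERN_POOLS.get(category)
    if chains and (patterns is None or rng.random() < 0.8):
        return chains[rng.integers(len(chains))]
    pat = patterns[rng.integers(len(patterns))]
    return pat.format(w=_WORDS[rng.integers(len(_WORDS))],
                      s=_SURNAMES[rng.integers(len(_SURNAMES))])


# Default category mix loosely following the register's composition:
# restaurants and fast food dominate, supermarkets/convenience follow.
DEFAULT_CATEGORY_MIX: dict[BaseCategory, float] = {
    BaseCategory.TRADITIONAL_RESTAURANT: 0.22,
    BaseCategory.CAFE_ALLDAY: 0.12,
    BaseCategory.MAJOR_FASTFOOD_CHAIN: 0.05,
    BaseCategory.NONCHAIN_FASTFOOD: 0.16,
    BaseCategory.TAKEAWAY_LIMITED_SEATING: 0.06,
    BaseCategory.RETAIL_BAKERY_CHAIN: 0.03,
    BaseCategory.CHAIN_COFFEE_SHOP: 0.03,
    BaseCategory.PETROL_KIOSK: 0.04,
    BaseCategory.CONVENIENCE_CHAIN: 0.04,
    BaseCategory.GROCERY_CHAIN: 0.03,
    BaseCategory.LARGE_SUPERMARKET_CHAIN: 0.04,
    BaseCategory.DISCOUNT_SUPERMARKET: 0.06,
    BaseCategory.FRUIT_VEGETABLE_STORE: 0.02,
    BaseCategory.BAKERY: 0.07,
    BaseCategory.BUTCHER: 0.02,
    BaseCategory.FISHMONGER: 0.01,
}

_SERVICE_CATS = {
    BaseCategory.MAJOR_FASTFOOD_CHAIN, BaseCategory.NONCHAIN_FASTFOOD,
    BaseCategory.TAKEAWAY_LIMITED_SEATING, BaseCategory.CHAIN_COFFEE_SHOP,
    BaseCategory.TRADITIONAL_RESTAURANT, BaseCategory.CAFE_ALLDAY,
}
_BAKERY_CATS = {BaseCategory.RETAIL_BAKERY_CHAIN, BaseCategory.BAKERY}
_MEATFISH_CATS = {BaseCategory.BUTCHER, BaseCategory.FISHMONGER}


def branch_code_for(category: BaseCategory, rng: np.random.Generator) -> str:
    if category in _SERVICE_CATS:
        return "DD.56.10.99" if rng.random() < 0.9 else "DD.56.30.99"
    if category in _BAKERY_CATS:
        return "DD.10.71.20" if rng.random() < 0.8 else "DD.47.10.99"
    if category in _MEATFISH_CATS:
        return "DD.47.22.00"
    return "DD.47.10.99" if rng.random() < 0.8 else "DD.47.20.99"


def default_region(
    center_lat: float = 55.68, center_lon: float = 12.57,
    side_m: float = 4750.0,
) -> Polygon:
    """A metrically square study region (default ≈361 cells of 250 m)."""
    proj = LocalProjection(center_lat, center_lon)
    h = side_m / 2
    return proj.unproject_polygon(
        Polygon([(-h, -h), (h, -h), (h, h), (-h, h)])
    )


def buffered_region(region: Polygon, margin_m: float) -> Polygon:
    """Expand a region outward by ``margin_m`` metres (square corners)."""
    proj = LocalProjection.for_region(region)
    metric = proj.project_polygon(region).buffer(margin_m, join_style=2)
    return proj.unproject_polygon(metric)


# ---------------------------------------------------------------------------
# Configuration and world generation
# ---------------------------------------------------------------------------

@dataclass
class WorldConfig:
    n_outlets: int = 1880
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    region: Polygon = field(default_factory=default_region)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outlets < 0:
            raise ValueError("n_outlets must be non-negative")
        total = sum(self.category_mix.values())
        if self.category_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"category mix sums to {total}, expected 1")


@dataclass
class ErrorConfig:
    """Register/field discrepancy processes, at the observed study regime."""

    p_unregistered: float = 0.25       # true outlet absent from the register
    p_stale: float = 0.24              # closed-outlet entries per true outlet
    position_error_median: float = 13.61   # metres
    name_noise: str = "banner"         # none | banner | heavy
    p_misclassify_register: float = 0.05
    p_field_missed: float = 0.0        # surveyor misses an open outlet
    p_closed_observed: float = 0.3     # stale entry met as a closed storefront
    inspection_cutoff: _dt.date = _dt.date(2020, 3, 13)

    def __post_init__(self) -> None:
        for name in ("p_unregistered", "p_stale", "p_misclassify_register",
                     "p_field_missed", "p_closed_observed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.position_error_median < 0:
            raise ValueError("position_error_median must be >= 0")
        if self.name_noise not in ("none", "banner", "heavy"):
            raise ValueError("name_noise must be none, banner or heavy")


@dataclass(frozen=True)
class TrueOutlet:
    uid: int
    category: BaseCategory
    name: str
    latitude: float
    longitude: float


def generate_world(cfg: WorldConfig) -> list[TrueOutlet]:
    """Place true outlets uniformly in the region with the configured mix."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_outlets == 0:
        return []
    cats = list(cfg.category_mix.keys())
    probs = np.array([cfg.category_mix[c] for c in cats])
    chosen = rng.choice(len(cats), size=cfg.n_outlets, p=probs)
    minx, miny, maxx, maxy = cfg.region.bounds
    outlets: list[TrueOutlet] = []
    uid = 0
    while len(outlets) < cfg.n_outlets:
        lon = rng.uniform(minx, maxx)
        lat = rng.uniform(miny, maxy)
        if not cfg.region.covers(Point(lon, lat)):
            continue
        cat = BaseCategory(cats[chosen[len(outlets)]])
        outlets.append(TrueOutlet(
            uid=uid, category=cat, name=draw_name(cat, rng),
            latitude=lat, longitude=lon,
        ))
        uid += 1
    return outlets


# ---------------------------------------------------------------------------
# Register view
# ---------------------------------------------------------------------------

@dataclass
class SyntheticRegister:
    records: list[OutletRecord]
    source_uid: dict[str, Optional[int]]      # record_id -> true uid (None: stale)
    register_category: dict[str, BaseCategory]
    stale_ids: list[str]


def _jitter(lat: float, lon: float, median_m: float,
            rng: np.random.Generator) -> tuple[float, float]:
    if median_m <= 0:
        return lat, lon
    sigma = median_m / _HALF_NORMAL_MEDIAN_FACTOR
    magnitude = abs(rng.normal(0.0, sigma))
    bearing = rng.uniform(0.0, 2 * math.pi)
    dlat = magnitude * math.cos(bearing) / _EARTH_RADIUS_M
    dlon = magnitude * math.sin(bearing) / (
        _EARTH_RADIUS_M * math.cos(math.radians(lat))
    )
    return lat + math.degrees(dlat), lon + math.degrees(dlon)


def _banner_noise(name: str, mode: str, rng: np.random.Generator) -> str:
    """Registered-name noise: legal suffixes, dropped descriptors, owner
    markers, and (rarely) an uninformative holding-company name."""
    if mode == "none":
        return name
    p_generic = 0.02 if mode == "banner" else 0.15
    u = rng.random()
    if u < p_generic:
        return f"{_SURNAMES[rng.integers(len(_SURNAMES))]} Holding ApS"
    op = rng.integers(5)
    tokens = name.split()
    if op == 0:
        suffix = ["ApS", "A/S", "I/S"][rng.integers(3)]
        return f"{name} {suffix}"
    if op == 1 and len(tokens) >= 2:
        return " ".join(tokens[1:])          # drop leading descriptor
    if op == 2 and len(tokens) >= 3:
        return " ".join(tokens[-2:])         # keep the distinctive tail
    if op == 3:
        return f"{name} v/ {_SURNAMES[rng.integers(len(_SURNAMES))]}"
    return name


def _uniform_date(rng: np.random.Generator, start: _dt.date,
                  end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(span + 1)))


def derive_register_view(
    world: Sequence[TrueOutlet],
    err: ErrorConfig,
    seed: int,
    region: Optional[Polygon] = None,
    rules: Optional[RuleSet] = None,
) -> SyntheticRegister:
    """Register snapshot of the world: incomplete, jittered, stale-padded.

    Each true outlet enters the register with probability 1−p_unregistered,
    at a jittered position (half-normal magnitude with the configured
    median), under a noise-corrupted legal name, with a branch code drawn
    from its register-side category (wrong with p_misclassify_register).
    Stale entries for permanently closed outlets are appended at rate
    p_stale, drawn from the same name pools and placed uniformly.  Records
    whose name the systematic rules cannot place carry a manual annotation
    with the register-side category, mirroring the two-stage workflow.
    """
    rng = np.random.default_rng([seed, 101])
    rules = rules or load_rules()
    all_cats = list(BaseCategory)
    records: list[OutletRecord] = []
    source_uid: dict[str, Optional[int]] = {}
    register_category: dict[str, BaseCategory] = {}
    stale_ids: list[str] = []

    def reg_cat(true_cat: BaseCategory) -> BaseCategory:
        if rng.random() < err.p_misclassify_register:
            others = [c for c in all_cats if c != true_cat]
            return others[rng.integers(len(others))]
        return true_cat

    def finalize(rid, name, cat, lat, lon, date) -> OutletRecord:
        rec = OutletRecord(
            record_id=rid, source=Source.REGISTER, raw_name=name,
            branch_code=branch_code_for(cat, rng), latitude=lat,
            longitude=lon, inspection_date=date,
        )
        if classify_systematic(rec, rules).method != Method.SYSTEMATIC:
            rec = OutletRecord(
                record_id=rid, source=Source.REGISTER, raw_name=name,
                branch_code=rec.branch_code, latitude=lat, longitude=lon,
                inspection_date=date,
                annotation=ManualAnnotation(base_category=cat.value),
            )
        return rec

    for outlet in world:
        if rng.random() < err.p_unregistered:
            continue
        rid = f"R{outlet.uid:05d}"
        lat, lon = _jitter(outlet.latitude, outlet.longitude,
                           err.position_error_median, rng)
        name = _banner_noise(outlet.name, err.name_noise, rng)
        cat = reg_cat(outlet.category)
        date = _uniform_date(rng, _dt.date(2019, 9, 1), _dt.date(2021, 2, 28))
        records.append(finalize(rid, name, cat, lat, lon, date))
        source_uid[rid] = outlet.uid
        register_category[rid] = cat

    if region is None and world:
        region = default_region()
    n_stale = rng.binomial(len(world), err.p_stale) if world else 0
    minx, miny, maxx, maxy = region.bounds if region is not None else (0, 0, 0, 0)
    k = 0
    while k < n_stale:
        lon = rng.uniform(minx, maxx)
        lat = rng.uniform(miny, maxy)
        if not region.covers(Point(lon, lat)):
            continue
        rid = f"S{k:05d}"
        cat = BaseCategory(all_cats[rng.integers(len(all_cats))])
        name = _banner_noise(draw_name(cat, rng), err.name_noise, rng)
        date = _uniform_date(rng, _dt.date(2019, 6, 1), _dt.date(2020, 12, 31))
        records.append(finalize(rid, name, cat, lat, lon, date))
        source_uid[rid] = None
        register_category[rid] = cat
        stale_ids.append(rid)
        k += 1

    return SyntheticRegister(records, source_uid, register_category, stale_ids)


# ---------------------------------------------------------------------------
# Field view
# ---------------------------------------------------------------------------

@dataclass
class SyntheticField:
    records: list[OutletRecord]
    source_uid: dict[str, Optional[int]]


def derive_field_view(
    world: Sequence[TrueOutlet],
    err: ErrorConfig,
    seed: int,
    register: Optional[SyntheticRegister] = None,
) -> SyntheticField:
    """Field audit of the world: true banners at true positions.

    Each open outlet is observed with probability 1−p_field_missed and
    carries its surveyed category as an annotation (the field survey
    classifies on sight).  Stale register entries are encountered as
    permanently closed storefronts with probability p_closed_observed;
    they are recorded by name and location but never classified.
    """
    rng = np.random.default_rng([seed, 202])
    records: list[OutletRecord] = []
    source_uid: dict[str, Optional[int]] = {}
    for outlet in world:
        if rng.random() < err.p_field_missed:
            continue
        rid = f"F{outlet.uid:05d}"
        records.append(OutletRecord(
            record_id=rid, source=Source.FIELD, raw_name=outlet.name,
            branch_code=None, latitude=outlet.latitude,
            longitude=outlet.longitude, open_status=OpenStatus.OPEN,
            annotation=ManualAnnotation(base_category=outlet.category.value),
        ))
        source_uid[rid] = outlet.uid
    if register is not None:
        reg_by_id = {r.record_id: r for r in register.records}
        for sid in register.stale_ids:
            if rng.random() < err.p_closed_observed:
                src = reg_by_id[sid]
                rid = f"FC{sid}"
                records.append(OutletRecord(
                    record_id=rid, source=Source.FIELD, raw_name=src.raw_name,
                    branch_code=None, latitude=src.latitude,
                    longitude=src.longitude,
                    open_status=OpenStatus.PERMANENTLY_CLOSED,
                ))
                source_uid[rid] = None
    return SyntheticField(records, source_uid)


# ---------------------------------------------------------------------------
# Bookkeeping truth
# ---------------------------------------------------------------------------

def truth_table(
    world: Sequence[TrueOutlet],
    register: SyntheticRegister,
    field: SyntheticField,
) -> dict:
    """Exact expected confusion counts from generator bookkeeping.

    Independent of the matcher: TP are register records whose source outlet
    was observed open in the field, FP those without an open field
    counterpart (stale entries and missed outlets), FN open field outlets
    absent from the register.
    """
    observed_open = {
        uid for rid, uid in field.source_uid.items() if uid is not None
    }
    registered = {
        uid for rid, uid in register.source_uid.items() if uid is not None
    }
    tp = sum(1 for uid in registered if uid in observed_open)
    fp = len(register.records) - tp
    fn = sum(1 for uid in observed_open if uid not in registered)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "n_register": len(register.records),
        "n_field_open": len(observed_open),
        "n_stale": len(register.stale_ids),
    }


# ---------------------------------------------------------------------------
# File-set simulation
# ---------------------------------------------------------------------------

def simulate(
    out_dir,
    world_cfg: Optional[WorldConfig] = None,
    err_cfg: Optional[ErrorConfig] = None,
    sampler_cfg: Optional[SamplerConfig] = None,
) -> dict:
    """Write register.csv, field.csv, truth.json and grids.geojson.

    The grid covers the outlet region plus a 750 m margin so that
    expected-empty cells exist; study cells are sampled per the coverage
    criterion and empty cells flagged ``expected_empty``.
    """
    from .taxonomy import classify_all

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world_cfg = world_cfg or WorldConfig()
    err_cfg = err_cfg or ErrorConfig()
    sampler_cfg = sampler_cfg or SamplerConfig(seed=world_cfg.seed)

    world = generate_world(world_cfg)
    register = derive_register_view(world, err_cfg, world_cfg.seed,
                                    region=world_cfg.region)
    field_view = derive_field_view(world, err_cfg, world_cfg.seed, register)

    grid_region = buffered_region(world_cfg.region, 750.0)
    cells = build_grid(grid_region, sampler_cfg)
    outcomes = classify_all(register.records)
    sample = select_study_grids(cells, register.records, outcomes, sampler_cfg)
    empty = select_empty_grids(cells, register.records, sampler_cfg.n_empty,
                               sampler_cfg.seed)

    write_outlets(register.records, out / "register.csv")
    write_outlets(field_view.records, out / "field.csv")
    write_geojson(sample.study_cells + empty, out / "grids.geojson")
    truth = truth_table(world, register, field_view)
    truth["seed"] = world_cfg.seed
    (out / "truth.json").write_text(json.dumps(truth, indent=2),
                                    encoding="utf-8")
    return truth
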