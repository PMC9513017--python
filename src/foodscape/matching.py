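"""Strict name + location matching between register and field outlets.

A register/field pair is a candidate when the names are at least
"tolerable" and the pair satisfies the spatial rule: both records inside
the study grid at any separation, or, when one lies outside the grid,
a great-circle separation strictly below 50 m.  Candidates are assigned
one-to-one greedily by descending name tier, then ascending distance,
then ascending ids; on small instances this equals the exhaustive
lexicographic optimum (see the property tests).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field as dc_field
from difflib import SequenceMatcher
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from shapely.geometry import Point
from shapely.prepared import prep

from .data_model import (
    GridCell,
    NormalizedName,
    OpenStatus,
    OutletRecord,
    normalize_name,
)

log = logging.getLogger("foodscape")

_EARTH_RADIUS_M = 6_371_000.0


def haversine(p1, p2) -> float:
    """Great-circle distance in metres between (lat, lon) points, sphere R=6371 km."""
    lat1, lon1 = math.radians(p1[0]), math.radians(p1[1])
    lat2, lon2 = math.radians(p2[0]), math.radians(p2[1])
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


class NameTier(str, Enum):
    SAME = "same"
    SIMILAR = "similar"
    TOLERABLE = "tolerable"
    NONE = "none"


TIER_RANK = {NameTier.SAME: 3, NameTier.SIMILAR: 2, NameTier.TOLERABLE: 1,
             NameTier.NONE: 0}


def load_lexicon(path: Union[str, Path, None] = None) -> dict[str, frozenset[str]]:
    """Load the product-keyword lexicon (normalized term → keyword set)."""
    if path is None:
        text = resources.files("foodscape").joinpath("data/lexicon.tsv").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    lex: dict[str, frozenset[str]] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        term = normalize_name(row["term"]).joined
        lex[term] = frozenset(
            k.strip() for k in row["keywords"].split(";") if k.strip()
        )
    return lex


@dataclass
class MatcherConfig:
    max_outside_distance: float = 50.0   # metres, strict "<"
    similar_threshold: float = 0.6       # character-similarity ratio
    keyword_lexicon: dict = dc_field(default_factory=load_lexicon)

    def __post_init__(self) -> None:
        if self.max_outside_distance < 0:
            raise ValueError("max_outside_distance must be >= 0")
        if not (0 < self.similar_threshold < 1):
            raise ValueError("similar_threshold must lie in (0, 1)")


def _char_similarity(a: str, b: str) -> float:
    """SequenceMatcher ratio, boosted by the best same-length window of the
    longer string so a name embedded in a longer banner still scores high."""
    if len(a) > len(b):
        a, b = b, a
    best = SequenceMatcher(None, a, b).ratio()
    if len(b) > len(a):
        for i in range(len(b) - len(a) + 1):
            r = SequenceMatcher(None, a, b[i:i + len(a)]).ratio()
            if r > best:
                best = r
    return best


def _keywords(name: NormalizedName, lexicon: dict[str, frozenset[str]]) -> frozenset[str]:
    found: set[str] = set()
    for term, kws in lexicon.items():
        tt = tuple(term.split())
        n = len(tt)
        if any(name.tokens[i:i + n] == tt for i in range(len(name.tokens) - n + 1)):
            found |= kws
    return frozenset(found)


def name_tier(
    a: NormalizedName, b: NormalizedName, cfg: Optional[MatcherConfig] = None
) -> NameTier:
    """Grade the agreement of two normalized names.

    same: identical after normalization.  similar: one token set contains
    the other, or the character-similarity ratio reaches the threshold.
    tolerable: the keyword lexicon maps both names onto an overlapping
    product-keyword set (same type of retailer / product line).
    """
    cfg = cfg or MatcherConfig()
    if a.joined == b.joined:
        return NameTier.SAME
    sa, sb = set(a.tokens), set(b.tokens)
    if sa <= sb or sb <= sa:
        return NameTier.SIMILAR
    if _char_similarity(a.joined, b.joined) >= cfg.similar_threshold:
        return NameTier.SIMILAR
    ka = _keywords(a, cfg.keyword_lexicon)
    if ka and ka & _keywords(b, cfg.keyword_lexicon):
        return NameTier.TOLERABLE
    return NameTier.NONE


@dataclass
class MatchResult:
    """One-to-one pairing plus the leftovers on each side."""

    pairs: list[tuple[str, str, NameTier, float]]
    unmatched_register: set[str]
    unmatched_field: set[str]
    closed_field: set[str] = dc_field(default_factory=set)

    def __post_init__(self) -> None:
        reg = [p[0] for p in self.pairs]
        fld = [p[1] for p in self.pairs]
        if len(set(reg)) != len(reg) or len(set(fld)) != len(fld):
            raise ValueError("assignment is not one-to-one")

    def merge(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            pairs=self.pairs + other.pairs,
            unmatched_register=self.unmatched_register | other.unmatched_register,
            unmatched_field=self.unmatched_field | other.unmatched_field,
            closed_field=self.closed_field | other.closed_field,
        )


def match(
    register: Sequence[OutletRecord],
    field: Sequence[OutletRecord],
    grid: Optional[GridCell] = None,
    cfg: Optional[MatcherConfig] = None,
    exclude_register: Optional[set[str]] = None,
) -> MatchResult:
    """Match register candidates against field records of one study grid.

    Permanently-closed field records are registered by name and location
    but never matched.  ``exclude_register`` removes register ids already
    claimed by another grid, preserving global one-to-oneness.
    """
    cfg = cfg or MatcherConfig()
    exclude_register = exclude_register or set()
    register = [r for r in register if r.record_id not in exclude_register]
    closed = {f.record_id for f in field
              if f.open_status == OpenStatus.PERMANENTLY_CLOSED}
    open_field = [f for f in field if f.record_id not in closed]

    if grid is not None:
        covers = prep(grid.polygon).covers
        in_grid = {
            r.record_id: covers(Point(r.longitude, r.latitude))
            for r in list(register) + list(open_field)
        }
    else:
        in_grid = {r.record_id: True for r in list(register) + list(open_field)}

    norm = {r.record_id: normalize_name(r.raw_name)
            for r in list(register) + list(open_field)}

    candidates = []
    for r in register:
        for f in open_field:
            tier = name_tier(norm[r.record_id], norm[f.record_id], cfg)
            if tier == NameTier.NONE:
                continue
            d = haversine((r.latitude, r.longitude), (f.latitude, f.longitude))
            both_inside = in_grid[r.record_id] and in_grid[f.record_id]
            if both_inside or d < cfg.max_outside_distance:
                candidates.append((r.record_id, f.record_id, tier, d))

    candidates.sort(key=lambda c: (-TIER_RANK[c[2]], c[3], c[0], c[1]))
    used_r: set[str] = set()
    used_f: set[str] = set()
    pairs = []
    for rid, fid, tier, d in candidates:
        if rid in used_r or fid in used_f:
            continue
        pairs.append((rid, fid, tier, d))
        used_r.add(rid)
        used_f.add(fid)

    return MatchResult(
        pairs=pairs,
        unmatched_register={r.record_id for r in register} - used_r,
        unmatched_field=({f.record_id for f in field} - used_f),
        closed_field=closed,
    )


def match_in_grids(
    register: Sequence[OutletRecord],
    field: Sequence[OutletRecord],
    cells: Sequence[GridCell],
    cfg: Optional[MatcherConfig] = None,
    projection=None,
) -> MatchResult:
    """Run per-grid matching over every study cell and combine the results.

    Field records are assigned to cells (they were surveyed per grid);
    register candidates for a grid are the register records assigned to it
    plus any register record within ``max_outside_distance`` of one of its
    field records.  Register records assigned to no study cell and never
    matched are outside the evaluation and are not counted unmatched.
    """
    from scipy.spatial import cKDTree

    from .grid_sampling import LocalProjection, assign_outlets

    cfg = cfg or MatcherConfig()
    cells = sorted(cells, key=lambda c: c.cell_id)
    if projection is None:
        from shapely.ops import unary_union

        projection = LocalProjection.for_region(
            unary_union([c.polygon for c in cells])
        )
    field_by_id = {f.record_id: f for f in field}
    reg_by_id = {r.record_id: r for r in register}
    field_cells = assign_outlets(cells, field)
    reg_cells = assign_outlets(cells, register)

    rx, ry = projection.to_xy(
        [r.latitude for r in register], [r.longitude for r in register]
    )
    reg_tree = cKDTree(np.column_stack([rx, ry])) if register else None
    reg_ids = [r.record_id for r in register]

    result = MatchResult([], set(), set())
    used_register: set[str] = set()
    for cell in cells:
        fids = field_cells.get(cell.cell_id, [])
        if not fids:
            continue
        f_recs = [field_by_id[i] for i in fids]
        cand_ids = set(reg_cells.get(cell.cell_id, []))
        if reg_tree is not None:
            fx, fy = projection.to_xy(
                [f.latitude for f in f_recs], [f.longitude for f in f_recs]
            )
            near = reg_tree.query_ball_point(
                np.column_stack([fx, fy]), r=cfg.max_outside_distance
            )
            for idxs in near:
                cand_ids.update(reg_ids[k] for k in idxs)
        r_recs = [reg_by_id[i] for i in sorted(cand_ids)]
        res = match(r_recs, f_recs, grid=cell, cfg=cfg,
                    exclude_register=used_register)
        # unmatched register records are only final for their own cell;
        # cross-grid candidates may still match elsewhere
        res.unmatched_register &= set(reg_cells.get(cell.cell_id, []))
        used_register |= {p[0] for p in res.pairs}
        result = result.merge(res)

    matched_reg = {p[0] for p in result.pairs}
    in_study = {
        rid for cell in cells for rid in reg_cells.get(cell.cell_id, [])
    }
    result.unmatched_register = in_study - matched_reg
    return result


def confusion_counts(result: MatchResult) -> tuple[int, int, int]:
    """(TP, FP, FN): pairs, unmatched register records, unmatched open field
    records.  Permanently-closed field outlets never count as false negatives."""
    tp = len(result.pairs)
    fp = len(result.unmatched_register)
    fn = len(result.unmatched_field - result.closed_field)
    return tp, fp, fn
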