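"""Grid construction over a study region and seeded grid-cell sampling.

Cells are 250 m squares laid out in a local spherical transverse-Mercator
projection centred on the region, which keeps side lengths metrically
accurate over city-scale regions without any external CRS definitions.
Study cells are drawn at random among occupied cells until every taxonomy
cell reaches its coverage target; expected-empty cells are a seeded sample
of register-empty cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from shapely.strtree import STRtree

from .data_model import GridCell, OutletRecord
from .taxonomy import (
    BaseCategory,
    Classification,
    ClassificationOutcome,
    Definition,
    Method,
    classification_cells,
    membership,
)

log = logging.getLogger("foodscape")

_EARTH_RADIUS_M = 6_371_000.0


class LocalProjection:
    """Spherical transverse Mercator centred on (lat0, lon0), in metres."""

    def __init__(self, lat0: float, lon0: float, radius: float = _EARTH_RADIUS_M):
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self.radius = radius
        self._y0 = radius * math.radians(lat0)

    @classmethod
    def for_region(cls, region: Polygon) -> "LocalProjection":
        c = region.centroid
        return cls(lat0=c.y, lon0=c.x)

    def to_xy(self, lat, lon):
        lat = np.radians(np.asarray(lat, dtype=float))
        dlon = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        b = np.cos(lat) * np.sin(dlon)
        x = self.radius * np.arctanh(b)
        y = self.radius * np.arctan2(np.tan(lat), np.cos(dlon)) - self._y0
        return x, y

    def to_latlon(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius
        d = (np.asarray(y, dtype=float) + self._y0) / self.radius
        lat = np.arcsin(np.sin(d) / np.cosh(x))
        lon = np.arctan2(np.sinh(x), np.cos(d))
        return np.degrees(lat), np.degrees(lon) + self.lon0

    def project_polygon(self, poly: Polygon) -> Polygon:
        def ring(coords):
            lons = [c[0] for c in coords]
            lats = [c[1] for c in coords]
            x, y = self.to_xy(lats, lons)
            return list(zip(x, y))

        return Polygon(
            ring(poly.exterior.coords),
            [ring(i.coords) for i in poly.interiors],
        )

    def unproject_polygon(self, poly: Polygon) -> Polygon:
        def ring(coords):
            xs = [c[0] for c in coords]
            ys = [c[1] for c in coords]
            lat, lon = self.to_latlon(xs, ys)
            return list(zip(lon, lat))

        return Polygon(
            ring(poly.exterior.coords),
            [ring(i.coords) for i in poly.interiors],
        )


@dataclass
class SamplerConfig:
    cell_size: float = 250.0          # metres
    coverage_fraction: float = 0.10   # share of each outlet type to cover
    n_empty: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (0 < self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must lie in (0, 1]")


@dataclass
class GridSample:
    study_cells: list[GridCell]
    empty_cells: list[GridCell] = field(default_factory=list)
    coverage: dict = field(default_factory=dict)
    skipped_types: list = field(default_factory=list)


def build_grid(region, cfg: Optional[SamplerConfig] = None,
               projection: Optional[LocalProjection] = None) -> list[GridCell]:
    """Tile ``region`` (lon/lat Polygon/MultiPolygon) with square cells.

    Cells intersecting the region with positive area are kept, including
    those straddling the boundary.  Deterministic: the lattice is anchored
    at integer multiples of the cell size in the projection's coordinates.
    """
    cfg = cfg or SamplerConfig()
    if region is None or region.is_empty or region.area == 0:
        raise ValueError("degenerate or empty region")
    projection = projection or LocalProjection.for_region(region)
    polys = getattr(region, "geoms", [region])
    metric = [projection.project_polygon(p) for p in polys]
    from shapely.ops import unary_union

    metric_region = unary_union(metric)
    prepared = prep(metric_region)
    minx, miny, maxx, maxy = metric_region.bounds
    s = cfg.cell_size
    i0, i1 = math.floor(minx / s), math.ceil(maxx / s)
    j0, j1 = math.floor(miny / s), math.ceil(maxy / s)
    cells: list[GridCell] = []
    for j in range(j0, j1):
        for i in range(i0, i1):
            sq = Polygon([
                (i * s, j * s), ((i + 1) * s, j * s),
                ((i + 1) * s, (j + 1) * s), (i * s, (j + 1) * s),
            ])
            if prepared.intersects(sq) and metric_region.intersection(sq).area > 1e-6:
                cells.append(GridCell(
                    cell_id=f"c{i - i0:04d}_{j - j0:04d}",
                    polygon=projection.unproject_polygon(sq),
                ))
    if not cells:
        raise ValueError("region produced no grid cells")
    return cells


def assign_outlets(
    cells: Sequence[GridCell], outlets: Sequence[OutletRecord]
) -> dict[str, list[str]]:
    """Map cell_id → record_ids, each outlet assigned to exactly one cell.

    A point on a shared boundary goes to the cell with the smaller cell_id.
    Outlets outside every cell are left unassigned.
    """
    order = sorted(range(len(cells)), key=lambda k: cells[k].cell_id)
    polys = [cells[k].polygon for k in order]
    tree = STRtree(polys)
    assignment: dict[str, list[str]] = {c.cell_id: [] for c in cells}
    for rec in sorted(outlets, key=lambda r: r.record_id):
        pt = Point(rec.longitude, rec.latitude)
        hits = sorted(
            int(k) for k in tree.query(pt)
            if polys[int(k)].covers(pt)
        )
        if hits:
            assignment[cells[order[hits[0]]].cell_id].append(rec.record_id)
    return assignment


def select_study_grids(
    cells: Sequence[GridCell],
    outlets: Sequence[OutletRecord],
    outcomes: Sequence[ClassificationOutcome],
    cfg: Optional[SamplerConfig] = None,
) -> GridSample:
    """Seeded random selection of occupied cells meeting per-type coverage.

    Cells containing at least one classified register outlet are drawn in
    seeded random order until, for every (classification, definition) cell
    of the taxonomy, the selected grids hold at least ``coverage_fraction``
    of that type's outlets.  Types with zero outlets are skipped with a
    warning.  Multi-membership counts an outlet in every type it belongs to.
    """
    cfg = cfg or SamplerConfig()
    category_of = {
        oc.record_id: oc.base_category
        for oc in outcomes
        if oc.method in (Method.SYSTEMATIC, Method.MANUAL)
        and oc.base_category is not None
    }
    assignment = assign_outlets(cells, outlets)
    cell_by_id = {c.cell_id: c for c in cells}

    types = classification_cells()
    totals = {t: 0 for t in types}
    per_cell = {cid: {t: 0 for t in types} for cid in assignment}
    for cid, rids in assignment.items():
        for rid in rids:
            cat = category_of.get(rid)
            if cat is None:
                continue
            for (c, d) in types:
                if membership(cat, c, d):
                    totals[(c, d)] += 1
                    per_cell[cid][(c, d)] += 1

    skipped = [t for t in types if totals[t] == 0]
    for c, d in skipped:
        log.warning("no outlets of type (%s, %s); coverage target skipped",
                    c.value, d.value if d else "-")
    active = [t for t in types if totals[t] > 0]

    occupied = sorted(cid for cid, rids in assignment.items() if rids)
    rng = np.random.default_rng(cfg.seed)
    order = list(rng.permutation(occupied))

    got = {t: 0 for t in active}
    selected: list[str] = []
    for cid in order:
        if all(got[t] >= cfg.coverage_fraction * totals[t] for t in active):
            break
        selected.append(cid)
        for t in active:
            got[t] += per_cell[cid][t]

    coverage = {t: got[t] / totals[t] for t in active}
    return GridSample(
        study_cells=[cell_by_id[cid] for cid in sorted(selected)],
        coverage=coverage,
        skipped_types=skipped,
    )


def select_empty_grids(
    cells: Sequence[GridCell],
    outlets: Sequence[OutletRecord],
    n_empty: int,
    seed: int,
    mask=None,
) -> list[GridCell]:
    """Seeded sample of cells holding zero register outlets.

    An optional ``mask`` polygon (e.g. populated areas) restricts candidates
    to cells whose centroid lies inside it.  Selected cells are returned
    flagged ``expected_empty``.
    """
    assignment = assign_outlets(cells, outlets)
    candidates = sorted(
        c.cell_id for c in cells
        if not assignment.get(c.cell_id)
        and (mask is None or mask.covers(c.polygon.centroid))
    )
    if n_empty > len(candidates):
        raise ValueError(
            f"requested {n_empty} empty cells but only {len(candidates)} "
            "candidate cells have no register outlets"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(candidates, size=n_empty, replace=False)) if n_empty else []
    cell_by_id = {c.cell_id: c for c in cells}
    out = []
    for cid in chosen:
        cell = cell_by_id[cid]
        out.append(GridCell(cell_id=cell.cell_id, polygon=cell.polygon,
                            expected_empty=True))
    return out
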