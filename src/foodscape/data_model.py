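"""Domain types, name normalization, and CSV/GeoJSON I/O for outlet datasets.

All coordinates are stored and exchanged as WGS84 decimal degrees (the
register's native form); metric computations project on the fly.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape

log = logging.getLogger("foodscape")

OUTLET_CSV_COLUMNS = [
    "record_id", "source", "name", "branch_code", "lat", "lon", "address",
    "inspection_date", "open_status", "annotation_category",
    "annotation_excluded", "annotation_reason",
]


class Source(str, Enum):
    REGISTER = "register"
    FIELD = "field"


class OpenStatus(str, Enum):
    OPEN = "open"
    PERMANENTLY_CLOSED = "permanently_closed"
    UNKNOWN = "unknown"


class ExclusionReason(str, Enum):
    INACCESSIBLE = "inaccessible"
    IRRELEVANT = "irrelevant"
    PRIVATE_KITCHEN = "private_kitchen"
    INSUFFICIENT_INFO = "insufficient_info"
    NONE = "none"


@dataclass(frozen=True)
class ManualAnnotation:
    """Outcome of a manual (virtual-audit style) review of one record."""

    base_category: Optional[str] = None  # BaseCategory value, see taxonomy
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if self.excluded != (self.exclusion_reason != ExclusionReason.NONE):
            raise ValueError(
                "excluded=True requires a reason; excluded=False requires none"
            )


@dataclass(frozen=True)
class OutletRecord:
    """One food-outlet observation, from either the register or the field."""

    record_id: str
    source: Source
    raw_name: str
    branch_code: Optional[str]
    latitude: float
    longitude: float
    address: Optional[str] = None
    inspection_date: Optional[_dt.date] = None
    open_status: OpenStatus = OpenStatus.UNKNOWN
    annotation: Optional[ManualAnnotation] = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} out of [-180, 180]")
        if self.source == Source.FIELD and self.inspection_date is not None:
            raise ValueError("field records carry no inspection date")


@dataclass(frozen=True)
class NormalizedName:
    tokens: tuple[str, ...]
    joined: str


@dataclass
class GridCell:
    """A 250 m square study cell; the polygon is stored in lon/lat degrees."""

    cell_id: str
    polygon: Polygon
    expected_empty: bool = False


class RejectedRow(NamedTuple):
    row_number: int
    reason: str
    raw: dict


class LoadResult(NamedTuple):
    records: list[OutletRecord]
    rejects: list[RejectedRow]


class FormatError(ValueError):
    """The input file does not conform to the documented layout."""


# ---------------------------------------------------------------------------
# Name normalization
# ---------------------------------------------------------------------------

# Danish legal-form suffixes commonly appended to registered company names.
_LEGAL_FORMS = r"aps|a/s|i/s|k/s|p/s|ivs|smba|amba|enk"
_LEGAL_RE = re.compile(rf"(?<![\w])(?:{_LEGAL_FORMS})(?![\w])\.?", re.IGNORECASE)
_VSLASH_RE = re.compile(r"(?<![\w])v/\s*", re.IGNORECASE)


def normalize_name(raw: str) -> NormalizedName:
    """Normalize an outlet name for comparison and rule matching.

    Lowercases, strips punctuation and Danish legal-form suffixes
    ("ApS", "A/S", "v/" owner markers, ...), collapses whitespace.
    Letters å/ø/æ and accented letters are preserved.  Idempotent.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("cannot normalize an empty name")
    s = str(raw).casefold()
    s = _VSLASH_RE.sub(" ", s)
    s = _LEGAL_RE.sub(" ", s)
    s = "".join(ch if (ch.isalnum() or ch.isspace()) else " " for ch in s)
    tokens = tuple(s.split())
    if not tokens:
        # name consisted solely of legal-form/punctuation text; keep the
        # alphanumeric residue so every record remains comparable
        s = "".join(
            ch if (ch.isalnum() or ch.isspace()) else " " for ch in str(raw).casefold()
        )
        tokens = tuple(s.split())
    if not tokens:
        raise ValueError(f"name {raw!r} has no alphanumeric content")
    return NormalizedName(tokens=tokens, joined=" ".join(tokens))


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def _parse_date(value) -> Optional[_dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    return _dt.date.fromisoformat(s)


def read_outlets(path: Union[str, Path], source: Source) -> LoadResult:
    """Read an outlet CSV into records, reporting unparseable rows.

    Required columns: ``name``, ``lat``, ``lon`` (plus ``branch_code`` for
    register data).  Rows with unparseable coordinates are returned in the
    rejects list, never silently dropped.  Duplicate record ids raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    source = Source(source)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= 1:
        log.warning("outlet file %s is empty", path)
        return LoadResult([], [])
    required = ["name", "lat", "lon"] + (
        ["branch_code"] if source == Source.REGISTER else []
    )
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    records: list[OutletRecord] = []
    rejects: list[RejectedRow] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.to_dict("records")):
        rid = str(row.get("record_id") or f"{source.value}-{i:05d}")
        if rid in seen_ids:
            raise FormatError(f"duplicate record_id {rid!r} in {path}")
        try:
            lat = float(row["lat"])
            lon = float(row["lon"])
        except (TypeError, ValueError):
            rejects.append(RejectedRow(i, "unparseable coordinates", dict(row)))
            continue
        try:
            annotation = _annotation_from_row(row)
            rec = OutletRecord(
                record_id=rid,
                source=source,
                raw_name=str(row["name"]),
                branch_code=(str(row["branch_code"]) or None)
                if "branch_code" in row else None,
                latitude=lat,
                longitude=lon,
                address=(str(row.get("address")) or None),
                inspection_date=_parse_date(row.get("inspection_date"))
                if source == Source.REGISTER else None,
                open_status=OpenStatus(row.get("open_status") or "unknown"),
                annotation=annotation,
            )
        except (ValueError, KeyError) as exc:
            rejects.append(RejectedRow(i, str(exc), dict(row)))
            continue
        seen_ids.add(rid)
        records.append(rec)
    if rejects:
        log.warning("%d rows rejected reading %s", len(rejects), path)
    return LoadResult(records, rejects)


def _annotation_from_row(row: dict) -> Optional[ManualAnnotation]:
    cat = str(row.get("annotation_category") or "").strip() or None
    excl = str(row.get("annotation_excluded") or "").strip().lower() in (
        "true", "1", "yes",
    )
    reason = str(row.get("annotation_reason") or "").strip() or "none"
    if cat is None and not excl and reason == "none":
        return None
    return ManualAnnotation(
        base_category=cat, excluded=excl, exclusion_reason=ExclusionReason(reason)
    )


def write_outlets(records: Sequence[OutletRecord], path: Union[str, Path]) -> None:
    """Write records to the documented CSV layout (UTF-8, header row)."""
    rows = []
    for r in records:
        ann = r.annotation
        rows.append({
            "record_id": r.record_id,
            "source": r.source.value,
            "name": r.raw_name,
            "branch_code": r.branch_code or "",
            "lat": f"{r.latitude:.7f}",
            "lon": f"{r.longitude:.7f}",
            "address": r.address or "",
            "inspection_date": r.inspection_date.isoformat()
            if r.inspection_date else "",
            "open_status": r.open_status.value,
            "annotation_category": (ann.base_category or "") if ann else "",
            "annotation_excluded": "true" if (ann and ann.excluded) else "",
            "annotation_reason": ann.exclusion_reason.value
            if (ann and ann.excluded) else "",
        })
    pd.DataFrame(rows, columns=OUTLET_CSV_COLUMNS).to_csv(
        path, index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def deduplicate(
    records: Sequence[OutletRecord], position_tol_m: float = 5.0
) -> tuple[list[OutletRecord], list[list[str]]]:
    """Collapse duplicate records identified by name and address.

    Two records are duplicates when their normalized names coincide AND
    either their normalized addresses coincide or (when an address is
    missing on either side) their positions are within ``position_tol_m``.
    The survivor of each group is the lexicographically smallest record_id;
    every group of size > 1 is reported for human review.
    """
    from .matching import haversine  # local import avoids a cycle

    by_name: dict[str, list[OutletRecord]] = {}
    for r in records:
        by_name.setdefault(normalize_name(r.raw_name).joined, []).append(r)

    kept: list[OutletRecord] = []
    groups: list[list[str]] = []
    for _, bucket in sorted(by_name.items()):
        bucket = sorted(bucket, key=lambda r: r.record_id)
        assigned: list[list[OutletRecord]] = []
        for r in bucket:
            placed = False
            for grp in assigned:
                if _same_place(grp[0], r, position_tol_m, haversine):
                    grp.append(r)
                    placed = True
                    break
            if not placed:
                assigned.append([r])
        for grp in assigned:
            kept.append(grp[0])
            if len(grp) > 1:
                groups.append([r.record_id for r in grp])
    kept.sort(key=lambda r: r.record_id)
    return kept, groups


def _same_place(a: OutletRecord, b: OutletRecord, tol_m: float, haversine) -> bool:
    if a.address and b.address:
        return (
            normalize_name(a.address).joined == normalize_name(b.address).joined
        )
    return haversine(
        (a.latitude, a.longitude), (b.latitude, b.longitude)
    ) <= tol_m


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def write_geojson(
    features: Iterable[Union[GridCell, OutletRecord]], path: Union[str, Path]
) -> None:
    """Write cells (polygons) or outlets (points) as an RFC 7946 FeatureCollection."""
    out = {"type": "FeatureCollection", "features": []}
    for f in features:
        if isinstance(f, GridCell):
            geom = mapping(f.polygon)
            props = {"cell_id": f.cell_id, "expected_empty": f.expected_empty}
        else:
            geom = mapping(Point(f.longitude, f.latitude))
            props = {
                "record_id": f.record_id,
                "source": f.source.value,
                "name": f.raw_name,
                "branch_code": f.branch_code,
                "open_status": f.open_status.value,
            }
        out["features"].append(
            {"type": "Feature", "geometry": geom, "properties": props}
        )
    Path(path).write_text(json.dumps(out), encoding="utf-8")


def read_grid_geojson(path: Union[str, Path]) -> list[GridCell]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection")
    cells = []
    for feat in data["features"]:
        props = feat.get("properties") or {}
        cells.append(
            GridCell(
                cell_id=str(props["cell_id"]),
                polygon=shape(feat["geometry"]),
                expected_empty=bool(props.get("expected_empty", False)),
            )
        )
    return cells


def read_region_geojson(path: Union[str, Path]):
    """Read a Polygon/MultiPolygon region (plain geometry, Feature or collection)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in data["features"]]
        from shapely.ops import unary_union

        return unary_union(geoms)
    if data.get("type") == "Feature":
        return shape(data["geometry"])
    return shape(data)
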