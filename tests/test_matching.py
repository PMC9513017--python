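"""Name tiers, spatial matching rules, and the one-to-one assignment."""

import math

import numpy as np
import pytest

from foodscape import (
    MatcherConfig,
    NameTier,
    confusion_counts,
    haversine,
    match,
    name_tier,
    normalize_name,
)
from foodscape.data_model import GridCell, OpenStatus, Source
from foodscape.grid_sampling import LocalProjection, SamplerConfig, build_grid
from foodscape.matching import TIER_RANK, MatchResult
from shapely.geometry import Polygon

from conftest import make_record

EARTH_R = 6_371_000.0


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine((55.0, 12.0), (55.0, 12.0)) == 0.0

    def test_against_spherical_law_of_cosines(self):
        p1, p2 = (55.0, 12.0), (55.0, 12.001)
        lat1, lon1, lat2, lon2 = map(math.radians, (*p1, *p2))
        oracle = EARTH_R * math.acos(
            math.sin(lat1) * math.sin(lat2)
            + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
        )
        assert haversine(p1, p2) == pytest.approx(oracle, abs=0.01)

    def test_symmetry(self):
        a, b = (55.1, 12.3), (55.7, 12.9)
        assert haversine(a, b) == pytest.approx(haversine(b, a))


class TestNameTier:
    @pytest.mark.parametrize(
        "a, b, tier",
        [
            ("Netto", "Netto", NameTier.SAME),
            ("Café Noir ApS", "café noir", NameTier.SAME),
            ("Ristorante da Claudio", "Da Claudio", NameTier.SIMILAR),
            ("Mon Solo", "Non Solo Trattoria", NameTier.SIMILAR),
            ("Dominos", "Pizza Group", NameTier.TOLERABLE),
            ("Netto", "Lagkagehuset", NameTier.NONE),
        ],
    )
    def test_examples(self, matcher_cfg, a, b, tier):
        assert name_tier(normalize_name(a), normalize_name(b),
                         matcher_cfg) == tier

    def test_symmetric(self, matcher_cfg):
        pairs = [("Ristorante da Claudio", "Da Claudio"),
                 ("Dominos", "Pizza Group"), ("Netto", "Fakta")]
        for a, b in pairs:
            na, nb = normalize_name(a), normalize_name(b)
            assert name_tier(na, nb, matcher_cfg) == \
                name_tier(nb, na, matcher_cfg)


def one_cell_grid(center=(55.68, 12.57), side_m=250.0):
    proj = LocalProjection(*center)
    h = side_m / 2
    poly = proj.unproject_polygon(Polygon([(-h, -h), (h, -h), (h, h), (-h, h)]))
    return GridCell(cell_id="g0", polygon=poly), proj


def place(proj, x, y, rid, name, source=Source.REGISTER, **kw):
    lat, lon = proj.to_latlon(x, y)
    branch = "DD.56.10.99" if source == Source.REGISTER else None
    return make_record(rid, source=source, name=name, branch_code=branch,
                       lat=float(lat), lon=float(lon), **kw)


class TestMatch:
    def test_simple_in_grid_pair(self, matcher_cfg):
        grid, proj = one_cell_grid()
        r = place(proj, 0, 0, "r1", "Netto")
        f = place(proj, 10, 0, "f1", "Netto", source=Source.FIELD)
        res = match([r], [f], grid, matcher_cfg)
        assert res.pairs == [("r1", "f1", NameTier.SAME, pytest.approx(10.0, abs=0.1))]

    def test_in_grid_pair_matches_at_any_in_grid_distance(self, matcher_cfg):
        grid, proj = one_cell_grid()
        r = place(proj, -100, -100, "r1", "Netto")
        f = place(proj, 100, 100, "f1", "Netto", source=Source.FIELD)
        res = match([r], [f], grid, matcher_cfg)
        assert len(res.pairs) == 1  # ~283 m apart but both inside the grid

    def test_outside_grid_beyond_50m_unmatched(self, matcher_cfg):
        grid, proj = one_cell_grid()
        f = place(proj, 120, 0, "f1", "Ristorante da Claudio",
                  source=Source.FIELD)
        r = place(proj, 185, 0, "r1", "Da Claudio")  # 60 m outside the cell
        res = match([r], [f], grid, matcher_cfg)
        assert res.pairs == []
        assert res.unmatched_register == {"r1"}
        assert res.unmatched_field == {"f1"}

    def test_outside_grid_within_50m_matches(self, matcher_cfg):
        grid, proj = one_cell_grid()
        f = place(proj, 120, 0, "f1", "Ristorante da Claudio",
                  source=Source.FIELD)
        r = place(proj, 155, 0, "r1", "Da Claudio")  # 30 m outside, 35 m away
        res = match([r], [f], grid, matcher_cfg)
        assert len(res.pairs) == 1
        assert res.pairs[0][2] == NameTier.SIMILAR

    def test_closed_field_records_never_match(self, matcher_cfg):
        grid, proj = one_cell_grid()
        r = place(proj, 0, 0, "r1", "Netto")
        f = place(proj, 5, 0, "f1", "Netto", source=Source.FIELD,
                  open_status=OpenStatus.PERMANENTLY_CLOSED)
        res = match([r], [f], grid, matcher_cfg)
        assert res.pairs == []
        assert res.closed_field == {"f1"}
        tp, fp, fn = confusion_counts(res)
        assert (tp, fp, fn) == (0, 1, 0)  # closed outlet is not a FN

    def test_raising_distance_never_decreases_tp(self, matcher_cfg):
        grid, proj = one_cell_grid()
        rng = np.random.default_rng(5)
        names = ["Netto", "Fakta", "Irma", "Café Luna", "Pizzeria Roma"]
        regs = [place(proj, rng.uniform(-300, 300), rng.uniform(-300, 300),
                      f"r{i}", names[i % 5]) for i in range(12)]
        flds = [place(proj, rng.uniform(-120, 120), rng.uniform(-120, 120),
                      f"f{i}", names[i % 5], source=Source.FIELD)
                for i in range(12)]
        tps = []
        for dist in (10.0, 50.0, 200.0):
            cfg = MatcherConfig(max_outside_distance=dist,
                                keyword_lexicon=matcher_cfg.keyword_lexicon)
            tps.append(len(match(regs, flds, grid, cfg).pairs))
        assert tps == sorted(tps)


# ---------------------------------------------------------------------------
# Brute-force assignment oracle
# ---------------------------------------------------------------------------

def brute_force_best(register, field, grid, cfg):
    """Exhaustively search one-to-one assignments, maximizing the sorted
    sequence of (tier, -distance) pair scores lexicographically."""
    from shapely.geometry import Point
    from shapely.prepared import prep

    covers = prep(grid.polygon).covers
    cands = {}
    for r in register:
        for f in field:
            if f.open_status == OpenStatus.PERMANENTLY_CLOSED:
                continue
            tier = name_tier(normalize_name(r.raw_name),
                             normalize_name(f.raw_name), cfg)
            if tier == NameTier.NONE:
                continue
            d = haversine((r.latitude, r.longitude), (f.latitude, f.longitude))
            inside = covers(Point(r.longitude, r.latitude)) and \
                covers(Point(f.longitude, f.latitude))
            if inside or d < cfg.max_outside_distance:
                cands.setdefault(r.record_id, []).append(
                    (f.record_id, tier, d)
                )
    reg_ids = sorted(cands)
    best = {"key": None}

    def rec(i, used_f, chosen):
        if i == len(reg_ids):
            key = sorted(
                ((TIER_RANK[t], -d) for _, _, t, d in chosen), reverse=True
            )
            if best["key"] is None or key > best["key"]:
                best["key"] = key
            return
        rec(i + 1, used_f, chosen)  # leave this register record unmatched
        for fid, tier, d in cands[reg_ids[i]]:
            if fid not in used_f:
                chosen.append((reg_ids[i], fid, tier, d))
                rec(i + 1, used_f | {fid}, chosen)
                chosen.pop()

    rec(0, frozenset(), [])
    return best["key"] or []


def random_instance(rng, n_reg, n_fld, proj):
    pool = ["Netto", "Netto Valby", "Fakta", "Pizzeria Roma", "Roma Pizza",
            "Dominos", "Café Luna", "Luna", "Irma", "Da Claudio",
            "Ristorante da Claudio"]
    regs = [place(proj, rng.uniform(-200, 200), rng.uniform(-200, 200),
                  f"r{i}", pool[rng.integers(len(pool))])
            for i in range(n_reg)]
    flds = [place(proj, rng.uniform(-140, 140), rng.uniform(-140, 140),
                  f"f{i}", pool[rng.integers(len(pool))], source=Source.FIELD)
            for i in range(n_fld)]
    return regs, flds


class TestAssignmentOptimality:
    def test_greedy_equals_brute_force_on_small_instances(self, matcher_cfg):
        grid, proj = one_cell_grid()
        rng = np.random.default_rng(42)
        for trial in range(40):
            n_reg = int(rng.integers(1, 5))
            n_fld = int(rng.integers(1, 5))
            regs, flds = random_instance(rng, n_reg, n_fld, proj)
            res = match(regs, flds, grid, matcher_cfg)
            greedy_key = sorted(
                ((TIER_RANK[t], -d) for _, _, t, d in res.pairs), reverse=True
            )
            oracle_key = brute_force_best(regs, flds, grid, matcher_cfg)
            assert greedy_key == oracle_key, f"trial {trial}"

    def test_greedy_equals_brute_force_on_6x6(self, matcher_cfg):
        grid, proj = one_cell_grid()
        rng = np.random.default_rng(7)
        for trial in range(3):
            regs, flds = random_instance(rng, 6, 6, proj)
            res = match(regs, flds, grid, matcher_cfg)
            greedy_key = sorted(
                ((TIER_RANK[t], -d) for _, _, t, d in res.pairs), reverse=True
            )
            assert greedy_key == brute_force_best(regs, flds, grid, matcher_cfg)


class TestConfusionCounts:
    def test_study_totals(self):
        res = MatchResult(
            pairs=[(f"r{i}", f"f{i}", NameTier.SAME, 1.0) for i in range(3)],
            unmatched_register={"r8", "r9"},
            unmatched_field={"f8"},
        )
        assert confusion_counts(res) == (3, 2, 1)

    def test_empty_inputs(self):
        res = MatchResult(pairs=[], unmatched_register=set(),
                          unmatched_field=set())
        assert confusion_counts(res) == (0, 0, 0)

    def test_partition_identities(self, matcher_cfg):
        grid, proj = one_cell_grid()
        rng = np.random.default_rng(13)
        regs, flds = random_instance(rng, 7, 6, proj)
        res = match(regs, flds, grid, matcher_cfg)
        tp, fp, fn = confusion_counts(res)
        assert tp + fp == len(regs)
        n_open_field = sum(
            1 for f in flds if f.open_status != OpenStatus.PERMANENTLY_CLOSED
        )
        assert tp + fn == n_open_field
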