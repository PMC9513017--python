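"""Validity statistics: sensitivity, PPV, confidence intervals, Landis
labels, positional error, empty-grid agreement, inspection-date split.

Sensitivity = TP/(TP+FN) measures how completely the register captures the
outlets actually present in the field; PPV = TP/(TP+FP) measures how many
register entries are confirmed open at their listed position.  Per-class
PPVs are computed over location-matched pairs only: among pairs whose
register side falls in a (classification, definition) cell, the share whose
field-side classification agrees.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_model import GridCell, OpenStatus, OutletRecord
from .grid_sampling import assign_outlets
from .matching import MatchResult, haversine
from .taxonomy import (
    BaseCategory,
    Classification,
    ClassificationOutcome,
    Definition,
    Method,
    automation_fraction,
    classification_cells,
    membership,
)

#: Sentinel for statistics with an empty denominator.
UNDEFINED = float("nan")

_Z95 = 1.959964


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def sensitivity(c: ConfusionCounts) -> float:
    """TP/(TP+FN); NaN when no field outlet exists."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else UNDEFINED


def ppv(c: ConfusionCounts) -> float:
    """TP/(TP+FP); NaN when the register side is empty."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else UNDEFINED


def wald_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald interval for a proportion, clipped to [0, 1]."""
    if n <= 0 or math.isnan(p):
        return (UNDEFINED, UNDEFINED)
    from scipy.stats import norm

    z = _Z95 if level == 0.95 else norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def wilson_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (alternative CI behind a config flag)."""
    if n <= 0 or math.isnan(p):
        return (UNDEFINED, UNDEFINED)
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(round(p * n), n, alpha=1 - level, method="wilson")
    return (float(lo), float(hi))


def landis_label(x: float) -> str:
    """Qualitative agreement band for a proportion (Landis scale)."""
    if math.isnan(x):
        return "undefined"
    if x > 1:
        raise ValueError("agreement statistic cannot exceed 1")
    if x < 0.0:
        return "poor"
    if x <= 0.20:
        return "slight"
    if x <= 0.40:
        return "fair"
    if x <= 0.60:
        return "moderate"
    if x <= 0.80:
        return "substantial"
    return "almost perfect"


def per_class_ppv(
    pairs: Sequence[tuple[Optional[BaseCategory], Optional[BaseCategory]]],
    classification: Classification,
    definition: Optional[Definition],
) -> tuple[int, int, float]:
    """(TP, FP, PPV) of classification agreement over location-matched pairs.

    ``pairs`` holds (register category, field category) per matched pair.
    Restricted to pairs whose register side is a member of the cell: TP when
    the field side also is, FP otherwise.  NaN PPV on an empty cell.
    """
    tp = fp = 0
    for reg_cat, fld_cat in pairs:
        if reg_cat is None or not membership(reg_cat, classification, definition):
            continue
        if fld_cat is not None and membership(fld_cat, classification, definition):
            tp += 1
        else:
            fp += 1
    total = tp + fp
    return tp, fp, (tp / total if total else UNDEFINED)


def positional_error(distances_m: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range (linear-interpolation quantiles)."""
    if len(distances_m) == 0:
        return (UNDEFINED, UNDEFINED)
    arr = np.asarray(distances_m, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return (float(med), float(q3 - q1))


def empty_grid_check(
    empty_cells: Sequence[GridCell], field_records: Sequence[OutletRecord]
) -> float:
    """Share of expected-empty cells where the field survey found no open outlet.

    The cells were flagged empty from the register; ground truth is what the
    surveyors found.  NaN when no cell is flagged.
    """
    flagged = [c for c in empty_cells if c.expected_empty]
    if not flagged:
        return UNDEFINED
    open_field = [f for f in field_records
                  if f.open_status != OpenStatus.PERMANENTLY_CLOSED]
    assignment = assign_outlets(flagged, open_field)
    n_empty = sum(1 for c in flagged if not assignment.get(c.cell_id))
    return n_empty / len(flagged)


def inspection_split(
    result: MatchResult,
    register: Sequence[OutletRecord],
    cutoff: _dt.date,
) -> tuple[float, float]:
    """(FP fraction, TP fraction) of register records last inspected before
    ``cutoff``; records without a date drop out of the denominators."""
    by_id = {r.record_id: r for r in register}
    matched = {p[0] for p in result.pairs}

    def frac(ids: Iterable[str]) -> float:
        dated = [by_id[i].inspection_date for i in ids
                 if i in by_id and by_id[i].inspection_date is not None]
        if not dated:
            return UNDEFINED
        return sum(1 for d in dated if d < cutoff) / len(dated)

    return frac(result.unmatched_register), frac(matched)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class ClassRow:
    classification: Classification
    definition: Optional[Definition]
    tp: int
    fp: int
    ppv: float
    ci: tuple[float, float]
    automation: float


@dataclass
class ValidityReport:
    counts: ConfusionCounts
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    sensitivity_label: str
    ppv_label: str
    per_class: list[ClassRow]
    positional_median_m: float
    positional_iqr_m: float
    empty_grid_proportion: float
    inspection_split: Optional[tuple[float, float]] = None
    n_register: int = 0
    n_field: int = 0

    def to_dict(self) -> dict:
        def pair(t):
            return None if t is None else [_r(t[0]), _r(t[1])]

        return {
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "fn": self.counts.fn},
            "sensitivity": _r(self.sensitivity),
            "sensitivity_ci": pair(self.sensitivity_ci),
            "sensitivity_label": self.sensitivity_label,
            "ppv": _r(self.ppv),
            "ppv_ci": pair(self.ppv_ci),
            "ppv_label": self.ppv_label,
            "per_class": [
                {
                    "classification": row.classification.value,
                    "definition": row.definition.value if row.definition else None,
                    "tp": row.tp, "fp": row.fp, "ppv": _r(row.ppv),
                    "ci": pair(row.ci), "automation": _r(row.automation),
                }
                for row in self.per_class
            ],
            "positional_median_m": _r(self.positional_median_m),
            "positional_iqr_m": _r(self.positional_iqr_m),
            "empty_grid_proportion": _r(self.empty_grid_proportion),
            "inspection_split": pair(self.inspection_split),
            "n_register": self.n_register,
            "n_field": self.n_field,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [
            "Register validity against field audit",
            "=" * 46,
            f"register records: {self.n_register}   field outlets: {self.n_field}",
            f"TP={self.counts.tp}  FP={self.counts.fp}  FN={self.counts.fn}",
            f"sensitivity: {self.sensitivity:.0%} ({self.sensitivity_label})",
            f"PPV:         {self.ppv:.0%} ({self.ppv_label})",
            f"positional error: {self.positional_median_m:.2f} "
            f"± {self.positional_iqr_m:.2f} m (median ± IQR)",
            f"empty grids correct: {self.empty_grid_proportion:.0%}"
            if not math.isnan(self.empty_grid_proportion) else
            "empty grids correct: n/a",
            "",
            f"{'classification':<20}{'definition':<11}{'TP':>5}{'FP':>5}"
            f"{'PPV (95% CI)':>20}{'% systematic':>14}",
        ]
        for row in self.per_class:
            ci = (f"{row.ppv:.2f} ({row.ci[0]:.2f}-{row.ci[1]:.2f})"
                  if not math.isnan(row.ppv) else "-")
            auto = f"{row.automation:.0%}" if not math.isnan(row.automation) else "-"
            lines.append(
                f"{row.classification.value:<20}"
                f"{(row.definition.value if row.definition else '-'):<11}"
                f"{row.tp:>5}{row.fp:>5}{ci:>20}{auto:>14}"
            )
        return "\n".join(lines) + "\n"


def _r(x: Optional[float]) -> Optional[float]:
    if x is None:
        return None
    return None if (isinstance(x, float) and math.isnan(x)) else round(float(x), 4)


def build_report(
    result: MatchResult,
    register: Sequence[OutletRecord],
    register_outcomes: Sequence[ClassificationOutcome],
    field_categories: dict[str, Optional[BaseCategory]],
    empty_cells: Sequence[GridCell] = (),
    field_records: Sequence[OutletRecord] = (),
    inspection_cutoff: Optional[_dt.date] = None,
    ci_method: str = "wald",
) -> ValidityReport:
    """Assemble the full validity report from a match result.

    A pure function of its inputs: identical inputs yield an identical
    report.  ``field_categories`` maps field record ids to their surveyed
    category; ``ci_method`` is "wald" (default) or "wilson".
    """
    ci = wald_ci if ci_method == "wald" else wilson_ci
    reg_by_id = {r.record_id: r for r in register}
    cat_of = {oc.record_id: oc.base_category for oc in register_outcomes
              if oc.method in (Method.SYSTEMATIC, Method.MANUAL)}

    tp, fp = len(result.pairs), len(result.unmatched_register)
    fn = len(result.unmatched_field - result.closed_field)
    counts = ConfusionCounts(tp, fp, fn)
    sens, p = sensitivity(counts), ppv(counts)

    class_pairs = [
        (cat_of.get(rid), field_categories.get(fid))
        for rid, fid, _, _ in result.pairs
    ]
    rows = []
    for c, d in classification_cells():
        ctp, cfp, cppv = per_class_ppv(class_pairs, c, d)
        rows.append(ClassRow(
            classification=c, definition=d, tp=ctp, fp=cfp, ppv=cppv,
            ci=ci(cppv, ctp + cfp),
            automation=automation_fraction(register_outcomes, c, d),
        ))

    distances = [p4 for _, _, _, p4 in result.pairs]
    med, iqr = positional_error(distances)

    split = None
    if inspection_cutoff is not None:
        split = inspection_split(result, register, inspection_cutoff)

    return ValidityReport(
        counts=counts,
        sensitivity=sens,
        sensitivity_ci=ci(sens, counts.tp + counts.fn),
        ppv=p,
        ppv_ci=ci(p, counts.tp + counts.fp),
        sensitivity_label=landis_label(sens),
        ppv_label=landis_label(p),
        per_class=rows,
        positional_median_m=med,
        positional_iqr_m=iqr,
        empty_grid_proportion=empty_grid_check(empty_cells, field_records)
        if empty_cells else UNDEFINED,
        inspection_split=split,
        n_register=len(register),
        n_field=len(field_records) if field_records else len(
            result.unmatched_field | {p[1] for p in result.pairs}
        ),
    )
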