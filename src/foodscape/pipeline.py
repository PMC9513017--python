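"""End-to-end orchestration: classify → match per grid → validity report."""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Optional, Sequence

from .data_model import GridCell, OutletRecord, deduplicate
from .matching import MatcherConfig, MatchResult, match_in_grids
from .taxonomy import (
    BaseCategory,
    ClassificationOutcome,
    Method,
    RuleSet,
    classify_all,
    filter_branch_codes,
)
from .validity import ValidityReport, build_report

log = logging.getLogger("foodscape")


def run_validation(
    register: Sequence[OutletRecord],
    field: Sequence[OutletRecord],
    cells: Sequence[GridCell],
    rules: Optional[RuleSet] = None,
    matcher_cfg: Optional[MatcherConfig] = None,
    inspection_cutoff: Optional[_dt.date] = _dt.date(2020, 3, 13),
    ci_method: str = "wald",
) -> tuple[ValidityReport, MatchResult, list[ClassificationOutcome]]:
    """Validate a register snapshot against a field audit over study grids.

    Steps: branch-code filter and deduplication of the register,
    systematic + manual classification, exclusion of discarded records,
    per-grid name+location matching within the non-empty study cells, and
    the full statistics report (expected-empty cells are checked against
    the field observations).
    """
    reg_kept, dropped = filter_branch_codes(register)
    reg_kept, dup_groups = deduplicate(reg_kept)
    if dup_groups:
        log.info("collapsed %d duplicate groups", len(dup_groups))
    outcomes = classify_all(reg_kept, rules)
    excluded = {oc.record_id for oc in outcomes if oc.method == Method.EXCLUDED}
    reg_final = [r for r in reg_kept if r.record_id not in excluded]
    outcomes = [oc for oc in outcomes if oc.record_id not in excluded]

    field_final = [
        f for f in field if not (f.annotation and f.annotation.excluded)
    ]
    field_categories = {
        f.record_id: BaseCategory(f.annotation.base_category)
        for f in field_final
        if f.annotation and f.annotation.base_category
    }

    study_cells = [c for c in cells if not c.expected_empty]
    empty_cells = [c for c in cells if c.expected_empty]
    result = match_in_grids(reg_final, field_final, study_cells, matcher_cfg)

    report = build_report(
        result,
        register=reg_final,
        register_outcomes=outcomes,
        field_categories=field_categories,
        empty_cells=empty_cells,
        field_records=field_final,
        inspection_cutoff=inspection_cutoff,
        ci_method=ci_method,
    )
    return report, result, outcomes
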