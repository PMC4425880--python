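"""Rendering of audit results: percent formatting, TSV/JSON serialization.

Audit rows carry integers only; every percentage is derived at render time
with round-half-up two-decimal formatting, locale-independent (decimal
point, no thousands separators in machine output).
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from io import StringIO
from typing import Any

from .corpus import AUDITABLE_FIELDS, FieldRef
from .field_audit import AuditTable, FieldAuditRow
from .lexicon import ProtocolStep
from .study_audit import ReagentOverlap, StudySummary

__all__ = [
    "format_percent",
    "render_audit",
    "parse_audit",
]

_STEP_COLUMNS = [step.value for step in ProtocolStep]
_COUNT_COLUMNS = _STEP_COLUMNS + ["all_steps", "any_step", "null_count"]
_NA = "NA"


def format_percent(numerator: int, denominator: int, decimals: int = 2) -> str:
    """Round-half-up percentage with a fixed number of decimals.

    >>> format_percent(29799, 419620)
    '7.10'
    """
    if denominator <= 0:
        raise ValueError("format_percent requires a positive denominator")
    quantum = Decimal(1).scaleb(-decimals)
    pct = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return f"{pct:f}"


def _row_counts(row: FieldAuditRow) -> dict[str, int]:
    counts = {step.value: row.per_step[step] for step in ProtocolStep}
    counts["all_steps"] = row.all_steps
    counts["any_step"] = row.any_step
    counts["null_count"] = row.null_count
    return counts


def _row_percents(row: FieldAuditRow) -> dict[str, str]:
    if row.total <= 0:
        return {col: _NA for col in _COUNT_COLUMNS}
    counts = _row_counts(row)
    return {col: format_percent(counts[col], row.total) for col in _COUNT_COLUMNS}


def _to_document(
    table: AuditTable,
    study_summary: StudySummary | None,
    reagent_summary: ReagentOverlap | None,
) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "fields": [
            {
                "table": row.ref.table_name,
                "field": row.ref.field_name,
                "total": row.total,
                **_row_counts(row),
                "percent": _row_percents(row),
            }
            for row in table.rows
        ]
    }
    if study_summary is not None:
        n = study_summary.n_studies
        doc["studies"] = {
            "total": n,
            "fully_annotated": study_summary.n_fully_annotated,
            "unannotated": study_summary.n_unannotated,
            "percent": {
                "fully_annotated": (
                    format_percent(study_summary.n_fully_annotated, n) if n else _NA
                ),
                "unannotated": (
                    format_percent(study_summary.n_unannotated, n) if n else _NA
                ),
            },
        }
    if reagent_summary is not None:
        doc["reagent"] = {
            "kit_records": reagent_summary.n_kit_records,
            "all_steps_and_kit": reagent_summary.n_all_steps_and_kit,
            "studies_with_overlap": reagent_summary.n_studies_with_overlap,
        }
    return doc


def render_audit(
    table: AuditTable,
    study_summary: StudySummary | None = None,
    reagent_summary: ReagentOverlap | None = None,
    fmt: str = "tsv",
) -> str:
    """Serialize an audit deterministically as TSV or JSON.

    The TSV carries one row per audited field with count and percent
    columns; study and reagent summaries are appended as '#'-prefixed
    comment lines so the tabular body stays rectangular.
    """
    if fmt == "json":
        doc = _to_document(table, study_summary, reagent_summary)
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    out = StringIO()
    header = ["table", "field", "total"]
    for col in _COUNT_COLUMNS:
        header += [col, f"{col}_pct"]
    out.write("\t".join(header) + "\n")
    for row in table.rows:
        counts = _row_counts(row)
        pcts = _row_percents(row)
        cells = [row.ref.table_name, row.ref.field_name, str(row.total)]
        for col in _COUNT_COLUMNS:
            cells += [str(counts[col]), pcts[col]]
        out.write("\t".join(cells) + "\n")
    if study_summary is not None:
        out.write(
            "# studies\ttotal=%d\tfully_annotated=%d\tunannotated=%d\n"
            % study_summary
        )
    if reagent_summary is not None:
        out.write(
            "# reagent\tkit_records=%d\tall_steps_and_kit=%d"
            "\tstudies_with_overlap=%d\n" % reagent_summary
        )
    return out.getvalue()


def _row_from_counts(ref: FieldRef, total: int, counts: dict[str, int]) -> FieldAuditRow:
    return FieldAuditRow(
        ref=ref,
        total=total,
        per_step={step: counts[step.value] for step in ProtocolStep},
        all_steps=counts["all_steps"],
        any_step=counts["any_step"],
        null_count=counts["null_count"],
    )


def parse_audit(text: str, fmt: str = "tsv") -> AuditTable:
    """Re-parse a rendered audit document back into an :class:`AuditTable`."""
    rows: list[FieldAuditRow] = []
    if fmt == "json":
        doc = json.loads(text)
        for entry in doc["fields"]:
            ref = FieldRef(entry["table"], entry["field"])
            counts = {col: int(entry[col]) for col in _COUNT_COLUMNS}
            rows.append(_row_from_counts(ref, int(entry["total"]), counts))
    elif fmt == "tsv":
        lines = [
            ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
        ]
        header = lines[0].split("\t")
        for line in lines[1:]:
            cells = dict(zip(header, line.split("\t")))
            ref = FieldRef(cells["table"], cells["field"])
            counts = {col: int(cells[col]) for col in _COUNT_COLUMNS}
            rows.append(_row_from_counts(ref, int(cells["total"]), counts))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    order = {ref: i for i, ref in enumerate(AUDITABLE_FIELDS)}
    rows.sort(key=lambda r: order[r.ref])
    return AuditTable(rows=tuple(rows))
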