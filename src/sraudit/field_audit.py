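"""Record-level annotation audit of the seven free-text metadata fields.

For every auditable (table, field) pair this module counts how many records'
text matches each protocol-step word list, how many match all three steps
within that single field value, how many match at least one step, and how
many are null. It also measures cross-field correspondence: of the records
that mention a step in a secondary field (study abstract, design
description, ...), what fraction also document it in the canonical
``library_construction_protocol`` field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .corpus import (
    AUDITABLE_FIELDS,
    FieldRef,
    MetadataCorpus,
    field_values,
    is_null_text,
)
from .lexicon import Lexicon, ProtocolStep, matched_steps

__all__ = [
    "FieldAuditRow",
    "AuditTable",
    "CorrespondenceRate",
    "audit_field",
    "audit_corpus",
    "correspondence_rate",
]

LCP_FIELD = FieldRef("experiment", "library_construction_protocol")


@dataclass(frozen=True)
class FieldAuditRow:
    """Annotation counts for one (table, field) pair. Counts, never percents."""

    ref: FieldRef
    total: int
    per_step: dict[ProtocolStep, int]
    all_steps: int
    any_step: int
    null_count: int

    @property
    def non_matching_non_null(self) -> int:
        return self.total - self.any_step - self.null_count

    def __post_init__(self) -> None:
        # all_steps <= min(per_step) additionally holds under the default
        # within-field scope, but not under the record-union option
        counts = list(self.per_step.values())
        assert 0 <= self.all_steps <= self.any_step
        assert max(counts, default=0) <= self.any_step <= sum(counts)
        assert 0 <= self.null_count <= self.total
        assert self.non_matching_non_null >= 0


@dataclass(frozen=True)
class AuditTable:
    """One :class:`FieldAuditRow` per auditable field, in report order."""

    rows: tuple[FieldAuditRow, ...]

    def __post_init__(self) -> None:
        assert tuple(r.ref for r in self.rows) == AUDITABLE_FIELDS

    def row(self, ref: FieldRef) -> FieldAuditRow:
        for r in self.rows:
            if r.ref == ref:
                return r
        raise KeyError(ref)


def _record_union_steps(
    corpus: MetadataCorpus, table: str, lex: Lexicon
) -> dict[str, frozenset[ProtocolStep]]:
    """Union of matched steps across all audited fields of each record."""
    union: dict[str, frozenset[ProtocolStep]] = {}
    for ref in AUDITABLE_FIELDS:
        if ref.table_name != table:
            continue
        for acc, text in field_values(corpus, ref):
            steps = matched_steps(None if is_null_text(text) else text, lex)
            union[acc] = union.get(acc, frozenset()) | steps
    return union


def audit_field(
    corpus: MetadataCorpus,
    ref: FieldRef,
    lex: Lexicon,
    *,
    all_steps_scope: str = "field",
) -> FieldAuditRow:
    """Count step annotation over every record's value of one field.

    Null values (absent / empty / whitespace) contribute only to
    ``null_count``. ``all_steps`` requires hits from all three word lists
    within this single field value (``all_steps_scope="field"``, the
    default); ``"record"`` instead credits a record whose audited fields of
    the same table jointly cover the three steps, provided this field
    matched at least one of them.
    """
    if all_steps_scope not in ("field", "record"):
        raise ValueError(f"unknown all_steps_scope {all_steps_scope!r}")
    per_step = {step: 0 for step in ProtocolStep}
    total = all_steps = any_step = null_count = 0
    record_union = (
        _record_union_steps(corpus, ref.table_name, lex)
        if all_steps_scope == "record"
        else None
    )
    for acc, text in field_values(corpus, ref):
        total += 1
        if is_null_text(text):
            null_count += 1
            continue
        steps = matched_steps(text, lex)
        for step in steps:
            per_step[step] += 1
        if steps:
            any_step += 1
            covered = steps if record_union is None else record_union[acc]
            if len(covered) == len(ProtocolStep):
                all_steps += 1
    return FieldAuditRow(
        ref=ref,
        total=total,
        per_step=per_step,
        all_steps=all_steps,
        any_step=any_step,
        null_count=null_count,
    )


def audit_corpus(
    corpus: MetadataCorpus, lex: Lexicon, *, all_steps_scope: str = "field"
) -> AuditTable:
    """Audit all seven fields; one row per field, canonical order."""
    return AuditTable(
        rows=tuple(
            audit_field(corpus, ref, lex, all_steps_scope=all_steps_scope)
            for ref in AUDITABLE_FIELDS
        )
    )


@dataclass(frozen=True)
class CorrespondenceRate:
    """Fraction of step-annotated source records whose canonical
    library_construction_protocol field documents the same step.

    ``unit`` is "study" or "experiment" depending on the source field's
    table. When no source record matches the step, the rate is undefined
    (``defined`` False, ``value`` NaN) — never silently zero.
    """

    source: FieldRef
    step: ProtocolStep
    unit: str
    n_source: int
    n_corresponding: int

    @property
    def defined(self) -> bool:
        return self.n_source > 0

    @property
    def value(self) -> float:
        if not self.defined:
            return math.nan
        return self.n_corresponding / self.n_source


def correspondence_rate(
    corpus: MetadataCorpus,
    source: FieldRef,
    step: ProtocolStep,
    lex: Lexicon,
    *,
    unit: str | None = None,
) -> CorrespondenceRate:
    """Measure source-field vs library_construction_protocol agreement.

    For experiment-level sources the unit is the experiment record: among
    experiments whose source field matches ``step``, the fraction whose own
    protocol field also matches. For study-level sources the natural unit is
    the study: a study "corresponds" if at least one child experiment's
    protocol field matches (abstracts are per-study, protocols
    per-experiment). Passing ``unit="experiment"`` for a study-level source
    instead counts over the child experiments of matching studies.
    """
    if source.table_name not in ("study", "experiment"):
        raise ValueError("source must be a study- or experiment-level field")
    if source not in AUDITABLE_FIELDS:
        raise ValueError(f"{source} is not an auditable field")

    def lcp_matches(exp) -> bool:
        text = exp.library_construction_protocol
        return not is_null_text(text) and step in matched_steps(text, lex)

    if source.table_name == "experiment":
        unit = unit or "experiment"
        if unit != "experiment":
            raise ValueError("experiment-level sources count experiment records")
        n_source = n_corr = 0
        for exp in corpus.experiments.values():
            text = getattr(exp, source.field_name)
            if is_null_text(text) or step not in matched_steps(text, lex):
                continue
            n_source += 1
            if lcp_matches(exp):
                n_corr += 1
        return CorrespondenceRate(source, step, unit, n_source, n_corr)

    unit = unit or "study"
    if unit not in ("study", "experiment"):
        raise ValueError(f"unknown unit {unit!r}")
    children = corpus.experiments_by_study()
    n_source = n_corr = 0
    for acc, study in corpus.studies.items():
        text = getattr(study, source.field_name)
        if is_null_text(text) or step not in matched_steps(text, lex):
            continue
        kids = children.get(acc, [])
        if unit == "study":
            n_source += 1
            if any(lcp_matches(exp) for exp in kids):
                n_corr += 1
        else:
            n_source += len(kids)
            n_corr += sum(1 for exp in kids if lcp_matches(exp))
    return CorrespondenceRate(source, step, unit, n_source, n_corr)
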