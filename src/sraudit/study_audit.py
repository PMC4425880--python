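"""Study-level aggregation of record annotation.

Depositors often annotate one experiment record and leave its siblings
blank, so record-level counts understate what a study as a whole documents.
Here every study's own fields, its child experiments' fields, and its linked
samples' descriptions are pooled: any keyword hit anywhere counts as
evidence for that protocol step for the whole study. A study is "fully
annotated" (non-conservatively) if at least one child experiment's
library_construction_protocol covers all three steps, and "unannotated" if
no audited field of the study or its children matched any step at all. The
annotated-to-total ratio per study and the reagent-kit overlap counts are
produced here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .corpus import MetadataCorpus, is_null_text
from .lexicon import Lexicon, ProtocolStep, matched_steps, matches_reagent

__all__ = [
    "StudyAnnotation",
    "RatioPoint",
    "StudySummary",
    "ReagentOverlap",
    "aggregate_by_study",
    "count_fully_annotated_studies",
    "count_unannotated_studies",
    "summarize_studies",
    "ratio_series",
    "reagent_overlap",
]

_STUDY_FIELDS = ("study_abstract", "study_description")
_EXPERIMENT_FIELDS = (
    "design_description",
    "library_selection",
    "library_construction_protocol",
    "experiment_attribute",
)


@dataclass(frozen=True)
class StudyAnnotation:
    """Aggregate annotation state of one study."""

    study_accession: str
    n_experiments: int
    step_flags: dict[ProtocolStep, bool]
    n_fully_annotated_experiments: int
    fully_annotated: bool
    unannotated: bool

    @property
    def ratio(self) -> float:
        """Fully annotated experiments over total experiments (0 if none)."""
        if self.n_experiments == 0:
            return 0.0
        return self.n_fully_annotated_experiments / self.n_experiments


class RatioPoint(NamedTuple):
    """One scatter point: study size vs fully-annotated fraction."""

    n_experiments: int
    ratio: float


class StudySummary(NamedTuple):
    n_studies: int
    n_fully_annotated: int
    n_unannotated: int


class ReagentOverlap(NamedTuple):
    """Experiment-level reagent-kit mention counts and their study spread."""

    n_kit_records: int
    n_all_steps_and_kit: int
    n_studies_with_overlap: int


def _text_steps(text: str | None, lex: Lexicon) -> frozenset[ProtocolStep]:
    return matched_steps(None if is_null_text(text) else text, lex)


def aggregate_by_study(
    corpus: MetadataCorpus, lex: Lexicon, *, fields: str = "all"
) -> list[StudyAnnotation]:
    """Aggregate annotation evidence up to each study.

    ``fields="all"`` (default) scans the study's own fields, all child
    experiment fields, and linked sample descriptions; ``"experiment"``
    restricts the scan to experiment-table fields only. Experiments with
    unresolvable study references are skipped here (they still appear in
    record-level audits).
    """
    if fields not in ("all", "experiment"):
        raise ValueError(f"unknown fields mode {fields!r}")
    children = corpus.experiments_by_study()
    sample_links = corpus.sample_to_study if fields == "all" else {}
    study_sample_steps: dict[str, frozenset[ProtocolStep]] = {}
    for sample_acc, study_accs in sample_links.items():
        sample = corpus.samples.get(sample_acc)
        if sample is None:
            continue
        steps = _text_steps(sample.description, lex)
        if not steps:
            continue
        for study_acc in study_accs:
            study_sample_steps[study_acc] = (
                study_sample_steps.get(study_acc, frozenset()) | steps
            )

    out: list[StudyAnnotation] = []
    all_steps = frozenset(ProtocolStep)
    for acc, study in corpus.studies.items():
        evidence: frozenset[ProtocolStep] = frozenset()
        if fields == "all":
            for name in _STUDY_FIELDS:
                evidence |= _text_steps(getattr(study, name), lex)
            evidence |= study_sample_steps.get(acc, frozenset())
        kids = children.get(acc, [])
        n_full = 0
        for exp in kids:
            for name in _EXPERIMENT_FIELDS:
                evidence |= _text_steps(getattr(exp, name), lex)
            lcp_steps = _text_steps(exp.library_construction_protocol, lex)
            if lcp_steps == all_steps:
                n_full += 1
        out.append(
            StudyAnnotation(
                study_accession=acc,
                n_experiments=len(kids),
                step_flags={step: step in evidence for step in ProtocolStep},
                n_fully_annotated_experiments=n_full,
                fully_annotated=n_full >= 1,
                unannotated=not evidence,
            )
        )
    return out


def count_fully_annotated_studies(aggs: Iterable[StudyAnnotation]) -> int:
    """Studies with at least one all-three-steps experiment record."""
    return sum(1 for a in aggs if a.fully_annotated)


def count_unannotated_studies(aggs: Iterable[StudyAnnotation]) -> int:
    """Studies with no step annotation whatsoever in any audited field."""
    return sum(1 for a in aggs if a.unannotated)


def summarize_studies(aggs: Sequence[StudyAnnotation]) -> StudySummary:
    return StudySummary(
        n_studies=len(aggs),
        n_fully_annotated=count_fully_annotated_studies(aggs),
        n_unannotated=count_unannotated_studies(aggs),
    )


def ratio_series(aggs: Iterable[StudyAnnotation]) -> list[RatioPoint]:
    """Scatter series of (study size, annotated fraction).

    Only studies with at least one fully annotated experiment are included,
    so every point satisfies 1/n <= ratio <= 1: the lower bound is the
    "single annotated record stands for all" pattern, the upper bound the
    fully redundant one.
    """
    return [
        RatioPoint(a.n_experiments, a.ratio)
        for a in aggs
        if a.n_fully_annotated_experiments >= 1
    ]


def reagent_overlap(corpus: MetadataCorpus, lex: Lexicon) -> ReagentOverlap:
    """Overlap between protocol-step annotation and reagent-kit mentions.

    Counts experiment records whose library_construction_protocol mentions
    "reagent"/"kit"; those that additionally cover all three protocol steps;
    and the number of distinct parent studies of the latter.
    """
    all_steps = frozenset(ProtocolStep)
    n_kit = n_both = 0
    studies: set[str] = set()
    for exp in corpus.experiments.values():
        text = exp.library_construction_protocol
        if is_null_text(text) or not matches_reagent(text, lex):
            continue
        n_kit += 1
        if matched_steps(text, lex) == all_steps:
            n_both += 1
            if exp.study_accession in corpus.studies:
                studies.add(exp.study_accession)
    return ReagentOverlap(n_kit, n_both, len(studies))
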