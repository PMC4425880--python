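"""Synthetic SRA-like metadata corpora with exactly known planted truth.

The real archive snapshot the audit was designed for is external and huge,
so every pipeline stage here is exercised on generated corpora that emulate
its salient structure: the one-to-many study→experiment hierarchy with a
heavy-tailed size distribution (many small studies, a few enormous ones),
free-text fields that contain protocol-step keywords at configurable
per-field rates, a ~51% null rate in library_construction_protocol, and
reagent-kit mentions.

Field text is assembled from a validated template bank: each positive
template contains stems of exactly one step and nothing else, each negative
or kit template contains no step stem at all. Because every generation
decision (null / intended step set / kit mention) is a pure function of the
configuration and seed, :func:`planted_truth` can replay them and emit the
*exact* audit counts the matcher must reproduce — turning end-to-end tests
from statistical checks into equality checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .corpus import (
    AUDITABLE_FIELDS,
    ExperimentRecord,
    FieldRef,
    MetadataCorpus,
    RunRecord,
    SampleRecord,
    StudyRecord,
)
from .field_audit import AuditTable, FieldAuditRow
from .lexicon import Lexicon, ProtocolStep, default_lexicon, matched_steps, matches_reagent
from .study_audit import RatioPoint, ReagentOverlap, StudySummary

__all__ = [
    "ExperimentsPerStudy",
    "SyntheticConfig",
    "TemplateBank",
    "TemplateViolation",
    "default_template_bank",
    "validate_templates",
    "generate_corpus",
    "planted_truth",
    "PlantedTruth",
]

LCP = FieldRef("experiment", "library_construction_protocol")

_ALL_STEPS = frozenset(ProtocolStep)


# ---------------------------------------------------------------------------
# Experiments-per-study distribution


@dataclass(frozen=True)
class ExperimentsPerStudy:
    """Distribution of child-experiment counts per study.

    ``kind="fixed"`` gives every study exactly ``k`` experiments.
    ``kind="pareto"`` draws ``min(cap, floor(1 + X))`` with X ~ Lomax(alpha),
    a discretized Pareto tail with minimum 1: many studies with few
    experiments and a few very large ones. The cap (default 1000) keeps
    desk-scale runtimes while preserving the heavy tail.
    """

    kind: str = "pareto"
    k: int = 1
    alpha: float = 1.1
    cap: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "pareto"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "fixed" and self.k < 1:
            raise ValueError("fixed distribution requires k >= 1")
        if self.kind == "pareto" and (self.alpha <= 0 or self.cap < 1):
            raise ValueError("pareto distribution requires alpha > 0, cap >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return self.k
        n = int(np.floor(1.0 + rng.pareto(self.alpha)))
        return min(self.cap, max(1, n))

    def mean(self) -> float:
        """Exact mean of the discretized, capped distribution."""
        if self.kind == "fixed":
            return float(self.k)
        # E[N] = sum_{k=1..cap} P(N >= k); P(N >= k) = P(X >= k-1) = k^-alpha
        ks = np.arange(1, self.cap + 1, dtype=float)
        return float(np.sum(ks ** (-self.alpha)))


# ---------------------------------------------------------------------------
# Configuration

# Null probabilities per audited field. The canonical protocol field's rate
# mirrors the ~51% observed in the wild; the others are plausible defaults
# for how often submitters leave each field blank.
DEFAULT_NULL_RATES: dict[FieldRef, float] = {
    FieldRef("study", "study_abstract"): 0.05,
    FieldRef("study", "study_description"): 0.30,
    FieldRef("sample", "description"): 0.40,
    FieldRef("experiment", "design_description"): 0.30,
    FieldRef("experiment", "library_selection"): 0.05,
    LCP: 0.5112,
    FieldRef("experiment", "experiment_attribute"): 0.60,
}

# Per-step keyword rates conditional on the field being non-null, chosen so
# the marginal (over all records) rates land near those observed in the
# archive: e.g. LCP fragmentation 0.145 * (1 - 0.5112) ≈ 7.1% of records.
DEFAULT_STEP_RATES: dict[FieldRef, dict[ProtocolStep, float]] = {
    FieldRef("study", "study_abstract"): {
        ProtocolStep.FRAGMENTATION: 0.013,
        ProtocolStep.ADAPTER_LIGATION: 0.005,
        ProtocolStep.ENRICHMENT: 0.034,
    },
    FieldRef("study", "study_description"): {
        ProtocolStep.FRAGMENTATION: 0.014,
        ProtocolStep.ADAPTER_LIGATION: 0.007,
        ProtocolStep.ENRICHMENT: 0.024,
    },
    FieldRef("sample", "description"): {
        ProtocolStep.FRAGMENTATION: 0.006,
        ProtocolStep.ADAPTER_LIGATION: 0.003,
        ProtocolStep.ENRICHMENT: 0.008,
    },
    FieldRef("experiment", "design_description"): {
        ProtocolStep.FRAGMENTATION: 0.040,
        ProtocolStep.ADAPTER_LIGATION: 0.022,
        ProtocolStep.ENRICHMENT: 0.057,
    },
    FieldRef("experiment", "library_selection"): {
        ProtocolStep.FRAGMENTATION: 0.004,
        ProtocolStep.ADAPTER_LIGATION: 0.0,
        ProtocolStep.ENRICHMENT: 0.0,
    },
    LCP: {
        ProtocolStep.FRAGMENTATION: 0.145,
        ProtocolStep.ADAPTER_LIGATION: 0.119,
        ProtocolStep.ENRICHMENT: 0.155,
    },
    FieldRef("experiment", "experiment_attribute"): {
        ProtocolStep.FRAGMENTATION: 0.003,
        ProtocolStep.ADAPTER_LIGATION: 0.006,
        ProtocolStep.ENRICHMENT: 0.017,
    },
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a synthetic corpus.

    ``p_step_per_field`` and ``p_null`` override entries of the defaults
    above; ``p_kit`` is the probability a non-null protocol field mentions a
    reagent kit; ``p_full_study`` plants one all-three-steps experiment in a
    study regardless of the per-field draws (the redundancy pattern seen in
    real submissions, and the source of fully annotated studies).
    """

    n_studies: int = 500
    exp_per_study: ExperimentsPerStudy = field(default_factory=ExperimentsPerStudy)
    p_step_per_field: Mapping[FieldRef, Mapping[ProtocolStep, float]] | None = None
    p_null: Mapping[FieldRef, float] | None = None
    p_kit: float = 0.11
    p_full_study: float = 0.047
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 0:
            raise ValueError("n_studies must be non-negative")
        for p, name in ((self.p_kit, "p_kit"), (self.p_full_study, "p_full_study")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for ref, p in (self.p_null or {}).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_null[{ref}] out of [0, 1]: {p}")
        for ref, rates in (self.p_step_per_field or {}).items():
            for step, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"p_step_per_field[{ref}][{step}] out of [0, 1]")

    def null_rate(self, ref: FieldRef) -> float:
        if self.p_null is not None and ref in self.p_null:
            return float(self.p_null[ref])
        return DEFAULT_NULL_RATES[ref]

    def step_rate(self, ref: FieldRef, step: ProtocolStep) -> float:
        if self.p_step_per_field is not None and ref in self.p_step_per_field:
            return float(self.p_step_per_field[ref].get(step, 0.0))
        return DEFAULT_STEP_RATES[ref][step]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        kwargs: dict = {}
        for key in ("n_studies", "p_kit", "p_full_study", "seed"):
            if key in data:
                kwargs[key] = data[key]
        if "exp_per_study" in data:
            kwargs["exp_per_study"] = ExperimentsPerStudy(**data["exp_per_study"])
        for key in ("p_step_per_field", "p_null"):
            if key in data:
                parsed: dict = {}
                for ref_key, val in data[key].items():
                    table, field_name = ref_key.split(".", 1)
                    ref = FieldRef(table, field_name)
                    if key == "p_null":
                        parsed[ref] = float(val)
                    else:
                        parsed[ref] = {
                            ProtocolStep(step): float(p) for step, p in val.items()
                        }
                kwargs[key] = parsed
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Template bank


@dataclass(frozen=True)
class TemplateBank:
    """Phrase fragments used to realize field text.

    Positive templates contain stems of exactly their own step; negative
    templates contain no stem of any list (including reagent); kit templates
    mention "kit"/"reagent" and no step stem. The bank is validated against
    the active lexicon before use.
    """

    positive: Mapping[ProtocolStep, tuple[str, ...]]
    negative: tuple[str, ...]
    kit: tuple[str, ...]


def default_template_bank() -> TemplateBank:
    return TemplateBank(
        positive={
            ProtocolStep.FRAGMENTATION: (
                "genomic DNA was sheared to an average size of 300 bp",
                "chromatin was sonicated on ice in ten cycles",
                "the sample was nebulised prior to size selection",
                "DNA was digested and size selected on a gel",
                "fragments of 200-400 bp were produced by acoustic disruption",
            ),
            ProtocolStep.ADAPTER_LIGATION: (
                "indexed adapters were ligated onto the repaired ends",
                "ends were blunted and 5' phosphorylated with T4-PNK",
                "polynucleotide kinase treatment preceded A-tailing",
                "adapter annealing was performed overnight at 16 degrees",
            ),
            ProtocolStep.ENRICHMENT: (
                "the library was amplified by PCR using Taq polymerase",
                "enriched with Phusion high-fidelity polymerase for 12 cycles",
                "products were cloned into a sequencing vector",
                "the reaction temperature was cycled for 18 rounds",
            ),
        },
        negative=(
            "total RNA was extracted from whole blood",
            "reads were mapped to the reference genome with BWA",
            "the study includes three biological replicates",
            "samples were stored at -80 until processing",
            "sequencing was performed on an Illumina HiSeq 2000",
            "data quality was assessed with standard metrics",
        ),
        kit=(
            "prepared using the TruSeq sample prep kit",
            "all reagents were supplied by the manufacturer",
        ),
    )


@dataclass(frozen=True)
class TemplateViolation:
    template: str
    intended: str
    problem: str


def validate_templates(
    bank: TemplateBank, lex: Lexicon
) -> list[TemplateViolation]:
    """Check every template against its contract under the active lexicon.

    Returns the list of violations (empty means the bank is safe to use for
    exact-truth generation). The pipeline treats a non-empty result as a
    hard error.
    """
    violations: list[TemplateViolation] = []
    for step, templates in bank.positive.items():
        for tpl in templates:
            got = matched_steps(tpl, lex)
            if got != frozenset({step}):
                violations.append(
                    TemplateViolation(
                        tpl, f"positive:{step.value}", f"matches {sorted(s.value for s in got)}"
                    )
                )
            if matches_reagent(tpl, lex):
                violations.append(
                    TemplateViolation(tpl, f"positive:{step.value}", "matches reagent list")
                )
    for tpl in bank.negative:
        got = matched_steps(tpl, lex)
        if got:
            violations.append(
                TemplateViolation(
                    tpl, "negative", f"matches {sorted(s.value for s in got)}"
                )
            )
        if matches_reagent(tpl, lex):
            violations.append(TemplateViolation(tpl, "negative", "matches reagent list"))
    for tpl in bank.kit:
        got = matched_steps(tpl, lex)
        if got:
            violations.append(
                TemplateViolation(tpl, "kit", f"matches {sorted(s.value for s in got)}")
            )
        if not matches_reagent(tpl, lex):
            violations.append(TemplateViolation(tpl, "kit", "does not match reagent list"))
    return violations


# ---------------------------------------------------------------------------
# Generation


@dataclass(frozen=True)
class _FieldDecision:
    """The planted truth for one generated field value."""

    is_null: bool
    steps: frozenset[ProtocolStep]
    kit: bool


@dataclass
class _Generated:
    corpus: MetadataCorpus
    # (table, accession, field) -> decision
    decisions: dict[tuple[str, str, str], _FieldDecision]
    # study accession -> list of child experiment accessions
    children: dict[str, list[str]]


_STEP_ORDER = tuple(ProtocolStep)


def _realize(
    decision: _FieldDecision, bank: TemplateBank, rng: np.random.Generator
) -> str | None:
    if decision.is_null:
        return None
    parts: list[str] = []
    for step in _STEP_ORDER:
        if step in decision.steps:
            templates = bank.positive[step]
            parts.append(templates[rng.integers(len(templates))])
    if not parts:
        parts.append(bank.negative[rng.integers(len(bank.negative))])
    if decision.kit:
        parts.append(bank.kit[rng.integers(len(bank.kit))])
    return "; ".join(parts)


def _draw_decision(
    config: SyntheticConfig,
    ref: FieldRef,
    rng: np.random.Generator,
    *,
    force_all_steps: bool = False,
) -> _FieldDecision:
    is_null = (not force_all_steps) and rng.random() < config.null_rate(ref)
    if is_null:
        return _FieldDecision(True, frozenset(), False)
    if force_all_steps:
        steps = _ALL_STEPS
    else:
        steps = frozenset(
            step
            for step in _STEP_ORDER
            if rng.random() < config.step_rate(ref, step)
        )
    kit = ref == LCP and rng.random() < config.p_kit
    return _FieldDecision(False, steps, kit)


def _generate(
    config: SyntheticConfig,
    bank: TemplateBank | None = None,
    lex: Lexicon | None = None,
) -> _Generated:
    bank = bank if bank is not None else default_template_bank()
    lex = lex if lex is not None else default_lexicon()
    violations = validate_templates(bank, lex)
    if violations:
        detail = "; ".join(
            f"{v.intended}: {v.template!r} ({v.problem})" for v in violations[:5]
        )
        raise ValueError(f"template bank violates its contract: {detail}")

    rng = np.random.default_rng(config.seed)
    studies: list[StudyRecord] = []
    experiments: list[ExperimentRecord] = []
    samples: list[SampleRecord] = []
    runs: list[RunRecord] = []
    decisions: dict[tuple[str, str, str], _FieldDecision] = {}
    children: dict[str, list[str]] = {}

    exp_counter = 0
    study_fields = [r for r in AUDITABLE_FIELDS if r.table_name == "study"]
    exp_fields = [r for r in AUDITABLE_FIELDS if r.table_name == "experiment"]
    sample_field = FieldRef("sample", "description")

    for i in range(config.n_studies):
        study_acc = f"SRP{i + 1:06d}"
        n_exp = config.exp_per_study.sample(rng)
        study_values: dict[str, str | None] = {}
        for ref in study_fields:
            d = _draw_decision(config, ref, rng)
            decisions[("study", study_acc, ref.field_name)] = d
            study_values[ref.field_name] = _realize(d, bank, rng)
        studies.append(StudyRecord(study_accession=study_acc, **study_values))

        full_study = rng.random() < config.p_full_study
        forced_idx = int(rng.integers(n_exp)) if full_study else -1
        kids: list[str] = []
        for j in range(n_exp):
            exp_counter += 1
            exp_acc = f"SRX{exp_counter:07d}"
            sample_acc = f"SRS{exp_counter:07d}"
            run_acc = f"SRR{exp_counter:07d}"
            kids.append(exp_acc)
            exp_values: dict[str, str | None] = {}
            for ref in exp_fields:
                force = ref == LCP and j == forced_idx
                d = _draw_decision(config, ref, rng, force_all_steps=force)
                decisions[("experiment", exp_acc, ref.field_name)] = d
                exp_values[ref.field_name] = _realize(d, bank, rng)
            experiments.append(
                ExperimentRecord(
                    experiment_accession=exp_acc,
                    study_accession=study_acc,
                    sample_accession=sample_acc,
                    **exp_values,
                )
            )
            d = _draw_decision(config, sample_field, rng)
            decisions[("sample", sample_acc, "description")] = d
            samples.append(
                SampleRecord(
                    sample_accession=sample_acc,
                    description=_realize(d, bank, rng),
                )
            )
            runs.append(
                RunRecord(
                    run_accession=run_acc,
                    experiment_accession=exp_acc,
                    sample_accession=sample_acc,
                )
            )
        children[study_acc] = kids

    corpus = MetadataCorpus.from_records(studies, experiments, samples, runs)
    return _Generated(corpus=corpus, decisions=decisions, children=children)


def generate_corpus(
    config: SyntheticConfig,
    bank: TemplateBank | None = None,
    lex: Lexicon | None = None,
) -> MetadataCorpus:
    """Generate a deterministic corpus for the given configuration."""
    return _generate(config, bank, lex).corpus


# ---------------------------------------------------------------------------
# Planted truth


@dataclass(frozen=True)
class PlantedTruth:
    """Exact expected audit results recorded at generation time."""

    audit: AuditTable
    study_summary: StudySummary
    ratio_points: tuple[RatioPoint, ...]
    reagent: ReagentOverlap


def planted_truth(
    config: SyntheticConfig,
    corpus: MetadataCorpus,
    bank: TemplateBank | None = None,
    lex: Lexicon | None = None,
) -> PlantedTruth:
    """Replay the generation decisions and derive the exact expected audit.

    ``corpus`` must be the output of :func:`generate_corpus` under the same
    configuration (and template bank); a mismatch raises ``ValueError``.
    """
    gen = _generate(config, bank, lex)
    if gen.corpus != corpus:
        raise ValueError("corpus does not match this configuration/seed")

    rows: list[FieldAuditRow] = []
    for ref in AUDITABLE_FIELDS:
        table_accs = {
            "study": gen.corpus.studies,
            "experiment": gen.corpus.experiments,
            "sample": gen.corpus.samples,
        }[ref.table_name]
        per_step = {step: 0 for step in ProtocolStep}
        total = all_steps = any_step = null_count = 0
        for acc in table_accs:
            total += 1
            d = gen.decisions[(ref.table_name, acc, ref.field_name)]
            if d.is_null:
                null_count += 1
                continue
            for step in d.steps:
                per_step[step] += 1
            if d.steps:
                any_step += 1
            if d.steps == _ALL_STEPS:
                all_steps += 1
        rows.append(
            FieldAuditRow(
                ref=ref,
                total=total,
                per_step=per_step,
                all_steps=all_steps,
                any_step=any_step,
                null_count=null_count,
            )
        )
    audit = AuditTable(rows=tuple(rows))

    n_fully = n_unann = 0
    ratio_points: list[RatioPoint] = []
    n_kit = n_both = 0
    overlap_studies: set[str] = set()
    for study_acc, kids in gen.children.items():
        evidence: frozenset[ProtocolStep] = frozenset()
        for name in ("study_abstract", "study_description"):
            evidence |= gen.decisions[("study", study_acc, name)].steps
        n_full = 0
        for exp_acc in kids:
            for ref in AUDITABLE_FIELDS:
                if ref.table_name != "experiment":
                    continue
                evidence |= gen.decisions[("experiment", exp_acc, ref.field_name)].steps
            lcp_d = gen.decisions[("experiment", exp_acc, "library_construction_protocol")]
            if lcp_d.steps == _ALL_STEPS:
                n_full += 1
            sample_acc = gen.corpus.experiments[exp_acc].sample_accession
            if sample_acc is not None:
                evidence |= gen.decisions[("sample", sample_acc, "description")].steps
            if lcp_d.kit and not lcp_d.is_null:
                n_kit += 1
                if lcp_d.steps == _ALL_STEPS:
                    n_both += 1
                    overlap_studies.add(study_acc)
        if n_full >= 1:
            n_fully += 1
            ratio_points.append(RatioPoint(len(kids), n_full / len(kids)))
        if not evidence:
            n_unann += 1

    return PlantedTruth(
        audit=audit,
        study_summary=StudySummary(
            n_studies=len(gen.children),
            n_fully_annotated=n_fully,
            n_unannotated=n_unann,
        ),
        ratio_points=tuple(ratio_points),
        reagent=ReagentOverlap(n_kit, n_both, len(overlap_studies)),
    )
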