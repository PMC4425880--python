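"""Record-level field audits: counts, invariants, correspondence rates."""

import math

import pytest

from sraudit import (
    AUDITABLE_FIELDS,
    FieldRef,
    MetadataCorpus,
    ProtocolStep,
    SyntheticConfig,
    audit_corpus,
    audit_field,
    correspondence_rate,
    generate_corpus,
)
from sraudit.corpus import field_values, is_null_text

from conftest import brute_force_steps, build_corpus, corpus_from_lcp

FRAG = ProtocolStep.FRAGMENTATION
LIG = ProtocolStep.ADAPTER_LIGATION
ENR = ProtocolStep.ENRICHMENT
LCP = FieldRef("experiment", "library_construction_protocol")


class TestAuditField:
    def test_hand_evaluated_mixed_fixture(self, lex):
        corpus = corpus_from_lcp(
            [
                "sheared then ligated to adapters, PCR",
                None,
                "sonicated",
                "library kit",  # contains no step keyword
            ]
        )
        row = audit_field(corpus, LCP, lex)
        assert row.total == 4
        assert row.per_step == {FRAG: 2, LIG: 1, ENR: 1}
        assert row.all_steps == 1
        assert row.any_step == 2
        assert row.null_count == 1

    def test_empty_corpus_all_zero(self, lex):
        row = audit_field(MetadataCorpus(), LCP, lex)
        assert (row.total, row.all_steps, row.any_step, row.null_count) == (0, 0, 0, 0)
        assert all(v == 0 for v in row.per_step.values())

    def test_saturated_corpus(self, lex):
        corpus = corpus_from_lcp(["fragment ligat pcr"] * 5)
        row = audit_field(corpus, LCP, lex)
        assert row.all_steps == row.total == 5

    def test_whitespace_value_counts_as_null(self, lex):
        row = audit_field(corpus_from_lcp(["   ", None]), LCP, lex)
        assert row.null_count == 2

    def test_all_steps_scope_record_vs_field(self, lex):
        # steps split across two fields of one experiment record
        corpus = build_corpus(
            studies=[("SRP000001", None, None)],
            experiments=[
                ("SRX0000001", "SRP000001", "sonicated and ligated", None, "PCR amplified", None)
            ],
        )
        within_field = audit_field(corpus, LCP, lex)
        within_record = audit_field(corpus, LCP, lex, all_steps_scope="record")
        assert within_field.all_steps == 0
        assert within_record.all_steps == 1


class TestAuditCorpus:
    def test_seven_rows_in_order(self, tiny_corpus, lex):
        table = audit_corpus(tiny_corpus, lex)
        assert tuple(r.ref for r in table.rows) == AUDITABLE_FIELDS

    def test_same_total_within_each_table(self, tiny_corpus, lex):
        table = audit_corpus(tiny_corpus, lex)
        for row in table.rows:
            expected = {"study": 2, "experiment": 3, "sample": 2}[row.ref.table_name]
            assert row.total == expected

    def test_conservation_invariant(self, lex):
        corpus = generate_corpus(SyntheticConfig(n_studies=60, seed=11))
        for row in audit_corpus(corpus, lex).rows:
            assert row.any_step + row.non_matching_non_null + row.null_count == row.total

    def test_all_steps_bounded_by_min_step_count_within_field(self, lex):
        corpus = generate_corpus(SyntheticConfig(n_studies=60, seed=12))
        for row in audit_corpus(corpus, lex).rows:
            assert row.all_steps <= min(row.per_step.values())

    def test_additivity_of_disjoint_corpora(self, lex):
        a = corpus_from_lcp(["sheared", None, "PCR"], study_acc="SRP000001")
        b = corpus_from_lcp(["ligated to adapters"], study_acc="SRP000002")
        merged = MetadataCorpus.from_records(
            studies=list(a.studies.values()) + list(b.studies.values()),
            experiments=[
                e if e.study_accession != "SRP000002" else e
                for e in list(a.experiments.values())
            ]
            + [
                type(e)(
                    experiment_accession=f"SRXB{i:06d}",
                    study_accession=e.study_accession,
                    library_construction_protocol=e.library_construction_protocol,
                )
                for i, e in enumerate(b.experiments.values())
            ],
            samples=[],
        )
        ra = audit_field(a, LCP, lex)
        rb = audit_field(b, LCP, lex)
        rm = audit_field(merged, LCP, lex)
        assert rm.total == ra.total + rb.total
        assert rm.any_step == ra.any_step + rb.any_step
        assert rm.null_count == ra.null_count + rb.null_count
        for step in ProtocolStep:
            assert rm.per_step[step] == ra.per_step[step] + rb.per_step[step]

    def test_equals_nested_loop_scan_on_small_corpus(self, lex):
        """Independent record-by-record, stem-by-stem oracle."""
        corpus = generate_corpus(SyntheticConfig(n_studies=25, seed=5))
        assert len(corpus.experiments) <= 200
        table = audit_corpus(corpus, lex)
        for row in table.rows:
            per_step = {s: 0 for s in ProtocolStep}
            all_steps = any_step = null_count = 0
            for _, text in field_values(corpus, row.ref):
                if is_null_text(text):
                    null_count += 1
                    continue
                steps = brute_force_steps(text, lex)
                for s in steps:
                    per_step[s] += 1
                any_step += bool(steps)
                all_steps += len(steps) == 3
            assert row.per_step == per_step
            assert (row.all_steps, row.any_step, row.null_count) == (
                all_steps,
                any_step,
                null_count,
            )


class TestCorrespondence:
    def test_study_source_hand_fixture(self, lex):
        # two studies mention fragmentation in the abstract; one child
        # documents it in the protocol field
        corpus = build_corpus(
            studies=[
                ("SRP000001", "DNA was sheared", None),
                ("SRP000002", "sonication used", None),
            ],
            experiments=[
                ("SRX0000001", "SRP000001", None, None, "sheared DNA", None),
                ("SRX0000002", "SRP000002", None, None, "no protocol given", None),
            ],
        )
        res = correspondence_rate(
            corpus, FieldRef("study", "study_abstract"), FRAG, lex
        )
        assert res.defined and res.value == 0.5
        assert (res.n_source, res.n_corresponding, res.unit) == (2, 1, "study")

    def test_identical_texts_give_rate_one(self, lex):
        text = "fragmented, ligated, amplified by PCR"
        corpus = build_corpus(
            studies=[("SRP000001", None, None)],
            experiments=[("SRX0000001", "SRP000001", text, None, text, None)],
        )
        for step in ProtocolStep:
            res = correspondence_rate(
                corpus, FieldRef("experiment", "design_description"), step, lex
            )
            assert res.value == 1.0

    def test_zero_matching_sources_flagged_undefined(self, lex):
        corpus = corpus_from_lcp(["nothing relevant"])
        res = correspondence_rate(
            corpus, FieldRef("experiment", "design_description"), FRAG, lex
        )
        assert not res.defined
        assert math.isnan(res.value)

    def test_study_source_experiment_unit(self, lex):
        corpus = build_corpus(
            studies=[("SRP000001", "sheared chromatin", None)],
            experiments=[
                ("SRX0000001", "SRP000001", None, None, "sheared DNA", None),
                ("SRX0000002", "SRP000001", None, None, None, None),
            ],
        )
        res = correspondence_rate(
            corpus,
            FieldRef("study", "study_abstract"),
            FRAG,
            lex,
            unit="experiment",
        )
        assert (res.n_source, res.n_corresponding) == (2, 1)
        assert res.value == 0.5

    def test_sample_source_rejected(self, tiny_corpus, lex):
        with pytest.raises(ValueError):
            correspondence_rate(
                tiny_corpus, FieldRef("sample", "description"), FRAG, lex
            )
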