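"""Keyword lexicon contents and matching semantics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sraudit import (
    KeywordPattern,
    Lexicon,
    LexiconError,
    ProtocolStep,
    default_lexicon,
    load_lexicon,
    match_keyword,
    matched_steps,
    matches_reagent,
    step_term_overlap,
)

from conftest import brute_force_steps

FRAG = ProtocolStep.FRAGMENTATION
LIG = ProtocolStep.ADAPTER_LIGATION
ENR = ProtocolStep.ENRICHMENT


class TestDefaultLexicon:
    def test_step_list_contents(self, lex):
        raws = {step: [p.raw for p in pats] for step, pats in lex.step_lists.items()}
        assert "sonic" in raws[FRAG] and "nebulisation" in raws[FRAG]
        assert "t4-pnk" in raws[LIG] and "blunt%" in raws[LIG]
        for kw in ("pcr", "taq", "phusion"):
            assert kw in raws[ENR]

    def test_list_sizes_match_transcription(self, lex):
        sizes = {step: len(pats) for step, pats in lex.step_lists.items()}
        assert sizes == {FRAG: 11, LIG: 12, ENR: 10}

    def test_reagent_list(self, lex):
        assert [p.stem for p in lex.reagent_list] == ["reagent", "kit"]

    def test_stems_are_percent_free_and_lowercase(self, lex):
        for _, pat in lex.all_step_patterns():
            assert pat.stem and "%" not in pat.stem
            assert pat.stem == pat.stem.casefold()

    def test_loadable_from_file(self, lex, tmp_path):
        import yaml

        data = {
            step.value: [p.raw for p in pats]
            for step, pats in lex.step_lists.items()
        }
        data["reagent"] = [p.raw for p in lex.reagent_list]
        path = tmp_path / "lexicon.yaml"
        path.write_text(yaml.safe_dump(data))
        assert load_lexicon(path) == lex

    def test_malformed_file_reports_parse_error(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("fragmentation: [\n  unclosed")
        with pytest.raises(LexiconError, match="line"):
            load_lexicon(path)

    def test_missing_list_rejected(self, tmp_path):
        path = tmp_path / "partial.yaml"
        path.write_text("fragmentation: [shear]\n")
        with pytest.raises(LexiconError, match="adapter_ligation"):
            load_lexicon(path)


class TestMatching:
    @pytest.mark.parametrize(
        ("text", "raw", "expected"),
        [
            ("DNA was amplified by PCR", "amplif%", True),
            ("", "shear", False),
            ("Supersonic transport", "sonic", True),  # documented false positive
            ("SONICATED SAMPLE", "sonic", True),
        ],
    )
    def test_match_keyword_substring_semantics(self, text, raw, expected):
        assert match_keyword(text, KeywordPattern(raw)) is expected

    def test_match_keyword_rejects_null(self):
        with pytest.raises(ValueError):
            match_keyword(None, KeywordPattern("shear"))

    def test_percent_placement_is_irrelevant(self):
        for raw in ("nebuliz", "nebuliz%", "%nebuliz"):
            assert match_keyword("DNA was nebulized", KeywordPattern(raw))

    @pytest.mark.parametrize(
        ("text", "expected"),
        [
            (
                "fragments were ligated to adapters and PCR amplified",
                {FRAG, LIG, ENR},
            ),
            (None, set()),
            ("RNA extracted with TRIzol", set()),
            ("sonicated", {FRAG}),
        ],
    )
    def test_matched_steps(self, lex, text, expected):
        assert matched_steps(text, lex) == frozenset(expected)

    @pytest.mark.parametrize(
        ("text", "expected"),
        [
            ("Nextera kit used per manufacturer", True),
            (None, False),
            ("ubiquitin ligase", False),
            ("reagents were chilled", True),
            ("first aid kits", True),  # documented false-positive class
        ],
    )
    def test_matches_reagent(self, lex, text, expected):
        assert matches_reagent(text, lex) is expected


class TestOracleEquivalence:
    def test_random_assembled_texts(self, lex, all_stems):
        """Matcher equals a regex scan on texts mixing stems and decoys."""
        import random

        decoys = ["genome", "tissue", "assay", "illumina", "rna", "depth"]
        rng = random.Random(20211203)
        vocab = all_stems + decoys
        for _ in range(500):
            words = [rng.choice(vocab) for _ in range(rng.randint(0, 8))]
            text = " ".join(words)
            assert matched_steps(text, lex) == brute_force_steps(text, lex)


class TestOverlap:
    def test_within_list_nesting_detected(self, lex):
        overlap = step_term_overlap(lex)
        # "t4" nests inside "t4-pnk" (and "pnk" likewise) within one list
        assert overlap[(LIG, LIG)] >= 2

    def test_matrix_is_symmetric(self, lex):
        overlap = step_term_overlap(lex)
        for a in ProtocolStep:
            for b in ProtocolStep:
                assert overlap[(a, b)] == overlap[(b, a)]

    def test_equals_brute_force_all_pairs(self, lex):
        overlap = step_term_overlap(lex)
        for a in ProtocolStep:
            for b in ProtocolStep:
                pa, pb = lex.step_lists[a], lex.step_lists[b]
                if a == b:
                    expected = sum(
                        1
                        for i in range(len(pa))
                        for j in range(i + 1, len(pa))
                        if pa[i].stem in pa[j].stem or pa[j].stem in pa[i].stem
                    )
                else:
                    expected = sum(
                        1
                        for p in pa
                        for q in pb
                        if p.stem in q.stem or q.stem in p.stem
                    )
                assert overlap[(a, b)] == expected

    def test_disjoint_stems_give_zero(self):
        lex = Lexicon(
            step_lists={
                FRAG: (KeywordPattern("aaa"),),
                LIG: (KeywordPattern("bbb"),),
                ENR: (KeywordPattern("ccc"),),
            },
            reagent_list=(KeywordPattern("kit"),),
        )
        assert all(v == 0 for v in step_term_overlap(lex).values())


words = st.lists(
    st.text(alphabet="abcdefghijklmnopqrstuvwxyz -%4", min_size=1, max_size=10),
    max_size=6,
).map(" ".join)


class TestProperties:
    @settings(max_examples=150, derandomize=True)
    @given(text=words, suffix=words)
    def test_matching_monotone_in_text_extension(self, text, suffix):
        lex = default_lexicon()
        assert matched_steps(text, lex) <= matched_steps(text + " " + suffix, lex)

    @settings(max_examples=150, derandomize=True)
    @given(text=words)
    def test_case_insensitivity(self, text):
        lex = default_lexicon()
        assert matched_steps(text, lex) == matched_steps(text.upper(), lex)

    @settings(max_examples=100, derandomize=True)
    @given(
        text=words,
        extra=st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=8),
        step=st.sampled_from(list(ProtocolStep)),
    )
    def test_adding_a_pattern_never_shrinks_matches(self, text, extra, step):
        lex = default_lexicon()
        grown = Lexicon(
            step_lists={
                s: pats + ((KeywordPattern(extra),) if s == step else ())
                for s, pats in lex.step_lists.items()
            },
            reagent_list=lex.reagent_list,
        )
        assert matched_steps(text, lex) <= matched_steps(text, grown)
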