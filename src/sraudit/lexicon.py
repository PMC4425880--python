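"""Protocol-step keyword lexicon and free-text matching.

Library-preparation metadata in SRA-style archives is free text, so the only
portable way to decide whether a record documents a protocol step is a
controlled keyword search. This module houses the three step word lists
(fragmentation, adapter ligation, enrichment) and the reagent-kit keywords,
and implements the matching rule they were designed for: each pattern is
reduced to a '%'-free stem and tested as an unanchored, case-insensitive
substring of the field text. That reproduces SQL ``LIKE '%stem%'`` semantics,
including its known false-positive classes (e.g. "sonic" inside
"supersonic"), which are accepted deliberately and documented rather than
patched over with NLP.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ProtocolStep",
    "KeywordPattern",
    "Lexicon",
    "LexiconError",
    "default_lexicon",
    "load_lexicon",
    "match_keyword",
    "matched_steps",
    "matches_reagent",
    "step_term_overlap",
]


class ProtocolStep(str, Enum):
    """The three audited library-preparation stages."""

    FRAGMENTATION = "fragmentation"
    ADAPTER_LIGATION = "adapter_ligation"
    ENRICHMENT = "enrichment"

    def __str__(self) -> str:  # stable serialization name
        return self.value


class LexiconError(ValueError):
    """Raised for malformed lexicon files or patterns."""


@dataclass(frozen=True)
class KeywordPattern:
    """A search pattern as printed in the word list.

    ``raw`` may carry '%' fuzzy-match markers; ``stem`` is the lowercased,
    '%'-stripped form actually matched.
    """

    raw: str
    stem: str = ""

    def __post_init__(self) -> None:
        stem = self.raw.replace("%", "").casefold()
        if not stem:
            raise LexiconError(f"pattern {self.raw!r} has an empty stem")
        object.__setattr__(self, "stem", stem)


@dataclass(frozen=True)
class Lexicon:
    """Ordered keyword lists per protocol step plus the reagent-kit list."""

    step_lists: Mapping[ProtocolStep, tuple[KeywordPattern, ...]]
    reagent_list: tuple[KeywordPattern, ...]

    def __post_init__(self) -> None:
        for step in ProtocolStep:
            if not self.step_lists.get(step):
                raise LexiconError(f"empty or missing word list for {step}")
        if not self.reagent_list:
            raise LexiconError("empty reagent list")

    def patterns(self, step: ProtocolStep) -> tuple[KeywordPattern, ...]:
        return self.step_lists[step]

    def all_step_patterns(self) -> tuple[tuple[ProtocolStep, KeywordPattern], ...]:
        return tuple(
            (step, pat) for step in ProtocolStep for pat in self.step_lists[step]
        )


def _lexicon_from_mapping(data: object, origin: str) -> Lexicon:
    if not isinstance(data, dict):
        raise LexiconError(f"{origin}: expected a mapping of lists")
    step_lists: dict[ProtocolStep, tuple[KeywordPattern, ...]] = {}
    for step in ProtocolStep:
        raw = data.get(step.value)
        if not isinstance(raw, list) or not raw:
            raise LexiconError(f"{origin}: missing or empty list {step.value!r}")
        step_lists[step] = tuple(KeywordPattern(str(p)) for p in raw)
    reagent_raw = data.get("reagent")
    if not isinstance(reagent_raw, list) or not reagent_raw:
        raise LexiconError(f"{origin}: missing or empty list 'reagent'")
    return Lexicon(
        step_lists=step_lists,
        reagent_list=tuple(KeywordPattern(str(p)) for p in reagent_raw),
    )


def default_lexicon() -> Lexicon:
    """Return the built-in lexicon shipped with the package."""
    text = resources.files("sraudit.data").joinpath("lexicon.yaml").read_text("utf-8")
    return _lexicon_from_mapping(yaml.safe_load(text), "built-in lexicon")


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a YAML/JSON file (for substitution studies)."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text("utf-8"))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise LexiconError(f"{path}: parse error{where}: {exc}") from exc
    return _lexicon_from_mapping(data, str(path))


def match_keyword(text: str, pattern: KeywordPattern) -> bool:
    """True iff the pattern's stem occurs anywhere in ``text`` (case-blind)."""
    if text is None:
        raise ValueError("match_keyword requires non-null text; filter nulls first")
    return pattern.stem in text.casefold()


def matched_steps(text: str | None, lex: Lexicon) -> frozenset[ProtocolStep]:
    """Set of protocol steps with at least one keyword hit in ``text``.

    Null text matches nothing. A record counts once per step regardless of
    how many of that step's keywords hit.
    """
    if text is None:
        return frozenset()
    folded = text.casefold()
    return frozenset(
        step
        for step, patterns in lex.step_lists.items()
        if any(p.stem in folded for p in patterns)
    )


def matches_reagent(text: str | None, lex: Lexicon) -> bool:
    """True iff the text mentions a reagent-kit keyword ("reagent"/"kit")."""
    if text is None:
        return False
    folded = text.casefold()
    return any(p.stem in folded for p in lex.reagent_list)


def _stems_nested(a: KeywordPattern, b: KeywordPattern) -> bool:
    return a.stem in b.stem or b.stem in a.stem


def step_term_overlap(
    lex: Lexicon,
) -> dict[tuple[ProtocolStep, ProtocolStep], int]:
    """Count pattern pairs whose stems contain one another, per step pair.

    There is substantial overlap between the lists (e.g. "t4" inside
    "t4-pnk" within the adapter-ligation list), which inflates multi-step
    hits; this quantifies it. The result is a full symmetric matrix; the
    diagonal counts unordered distinct pairs within one list.
    """
    out: dict[tuple[ProtocolStep, ProtocolStep], int] = {}
    steps = list(ProtocolStep)
    for i, a in enumerate(steps):
        pats_a = lex.step_lists[a]
        for b in steps[i:]:
            pats_b = lex.step_lists[b]
            if a == b:
                count = sum(
                    1
                    for x in range(len(pats_a))
                    for y in range(x + 1, len(pats_a))
                    if _stems_nested(pats_a[x], pats_a[y])
                )
            else:
                count = sum(
                    1 for p in pats_a for q in pats_b if _stems_nested(p, q)
                )
            out[(a, b)] = count
            out[(b, a)] = count
    return out
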