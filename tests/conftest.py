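import re

import pytest

from sraudit import (
    ExperimentRecord,
    MetadataCorpus,
    RunRecord,
    SampleRecord,
    StudyRecord,
    default_lexicon,
)


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


@pytest.fixture(scope="session")
def all_stems(lex):
    return [p.stem for pats in lex.step_lists.values() for p in pats]


def brute_force_steps(text, lex):
    """Independent regex-based oracle for matched_steps."""
    if text is None:
        return frozenset()
    hits = set()
    for step, patterns in lex.step_lists.items():
        for p in patterns:
            if re.search(re.escape(p.raw.replace("%", "")), text, re.IGNORECASE):
                hits.add(step)
                break
    return frozenset(hits)


def build_corpus(studies=(), experiments=(), samples=(), runs=()):
    """Assemble a corpus from shorthand tuples.

    studies: (acc, abstract, description)
    experiments: (acc, study_acc, design, selection, lcp, attribute[, sample_acc])
    samples: (acc, description)
    runs: (acc, experiment_acc[, sample_acc])
    """
    return MetadataCorpus.from_records(
        studies=[StudyRecord(*s) for s in studies],
        experiments=[ExperimentRecord(*e) for e in experiments],
        samples=[SampleRecord(*s) for s in samples],
        runs=[RunRecord(*r) for r in runs],
    )


def corpus_from_lcp(values, study_acc="SRP000001"):
    """One study whose experiments carry the given protocol-field values."""
    return build_corpus(
        studies=[(study_acc, None, None)],
        experiments=[
            (f"SRX{i:07d}", study_acc, None, None, v, None) for i, v in enumerate(values, 1)
        ],
    )


@pytest.fixture
def tiny_corpus():
    """2 studies, 3 experiments, 2 samples, 2 runs."""
    return build_corpus(
        studies=[
            ("SRP000001", "Genome study", "A description"),
            ("SRP000002", None, None),
        ],
        experiments=[
            ("SRX0000001", "SRP000001", None, "RANDOM", "sheared and ligated, then PCR", None, "SRS0000001"),
            ("SRX0000002", "SRP000001", "exome capture", None, None, None, "SRS0000002"),
            ("SRX0000003", "SRP000002", None, None, "", None, None),
        ],
        samples=[
            ("SRS0000001", "liver tissue"),
            ("SRS0000002", None),
        ],
        runs=[
            ("SRR0000001", "SRX0000001", "SRS0000001"),
            ("SRR0000002", "SRX0000002", "SRS0000002"),
        ],
    )
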