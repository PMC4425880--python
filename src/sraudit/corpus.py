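"""Relational SRA-style metadata corpus: typed records, loaders and writers.

The archive's metadata schema is hierarchical — a study owns many
experiments, which reference samples and runs — and is distributed either as
a SQLite database or as flat per-table files. This module reads either
dialect into one in-memory :class:`MetadataCorpus` and exposes the seven
free-text (table, field) pairs that are worth probing for protocol
annotation. Iteration order is fixed by lexicographic accession sort so every
downstream count is reproducible.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord",
    "ExperimentRecord",
    "SampleRecord",
    "RunRecord",
    "FieldRef",
    "MetadataCorpus",
    "SchemaError",
    "AUDITABLE_FIELDS",
    "auditable_fields",
    "load_corpus",
    "write_corpus",
    "field_values",
    "is_null_text",
]

NULL_TOKEN = r"\N"  # encodes SQL NULL in the TSV dialect


class SchemaError(ValueError):
    """A required table or column is missing from the input."""


@dataclass(frozen=True)
class StudyRecord:
    study_accession: str
    study_abstract: str | None = None
    study_description: str | None = None


@dataclass(frozen=True)
class ExperimentRecord:
    experiment_accession: str
    study_accession: str
    design_description: str | None = None
    library_selection: str | None = None
    library_construction_protocol: str | None = None
    experiment_attribute: str | None = None
    sample_accession: str | None = None


@dataclass(frozen=True)
class SampleRecord:
    sample_accession: str
    description: str | None = None


@dataclass(frozen=True)
class RunRecord:
    run_accession: str
    experiment_accession: str
    sample_accession: str | None = None


class FieldRef(NamedTuple):
    """One auditable (table, field) pair."""

    table_name: str
    field_name: str


#: The seven auditable free-text fields, in canonical report row order.
AUDITABLE_FIELDS: tuple[FieldRef, ...] = (
    FieldRef("study", "study_abstract"),
    FieldRef("study", "study_description"),
    FieldRef("sample", "description"),
    FieldRef("experiment", "design_description"),
    FieldRef("experiment", "library_selection"),
    FieldRef("experiment", "library_construction_protocol"),
    FieldRef("experiment", "experiment_attribute"),
)

_REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "study": ("study_accession", "study_abstract", "study_description"),
    "experiment": (
        "experiment_accession",
        "study_accession",
        "design_description",
        "library_selection",
        "library_construction_protocol",
        "experiment_attribute",
    ),
    "sample": ("sample_accession", "description"),
}
_OPTIONAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "experiment": ("sample_accession",),
}
_RUN_COLUMNS = ("run_accession", "experiment_accession")


def auditable_fields() -> tuple[FieldRef, ...]:
    """Return the seven audited (table, field) pairs in report order."""
    return AUDITABLE_FIELDS


def is_null_text(text: str | None) -> bool:
    """A value is "null" if absent, empty, or whitespace-only.

    SQL NULL is the archive's usual way of leaving a field blank, but
    whitespace-only free text carries no annotation either, so it is treated
    the same (conservative nullness).
    """
    return text is None or text.strip() == ""


@dataclass
class MetadataCorpus:
    """In-memory relational view of study/experiment/sample/run records.

    Dictionaries are keyed and insertion-ordered by accession. Experiments
    whose ``study_accession`` does not resolve are kept (record-level audits
    include them) but excluded from study-level aggregation.
    """

    studies: dict[str, StudyRecord] = field(default_factory=dict)
    experiments: dict[str, ExperimentRecord] = field(default_factory=dict)
    samples: dict[str, SampleRecord] = field(default_factory=dict)
    runs: dict[str, RunRecord] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        studies: Iterable[StudyRecord],
        experiments: Iterable[ExperimentRecord],
        samples: Iterable[SampleRecord],
        runs: Iterable[RunRecord] = (),
    ) -> "MetadataCorpus":
        corpus = cls()
        for rec in sorted(studies, key=lambda r: r.study_accession):
            if rec.study_accession in corpus.studies:
                raise SchemaError(f"duplicate study accession {rec.study_accession}")
            corpus.studies[rec.study_accession] = rec
        for rec in sorted(experiments, key=lambda r: r.experiment_accession):
            if rec.experiment_accession in corpus.experiments:
                raise SchemaError(
                    f"duplicate experiment accession {rec.experiment_accession}"
                )
            corpus.experiments[rec.experiment_accession] = rec
        for rec in sorted(samples, key=lambda r: r.sample_accession):
            if rec.sample_accession in corpus.samples:
                raise SchemaError(f"duplicate sample accession {rec.sample_accession}")
            corpus.samples[rec.sample_accession] = rec
        for rec in sorted(runs, key=lambda r: r.run_accession):
            corpus.runs[rec.run_accession] = rec
        return corpus

    # -- linkage ---------------------------------------------------------

    @property
    def sample_to_study(self) -> dict[str, frozenset[str]]:
        """Sample accession -> set of owning study accessions.

        Built from the experiment table's ``sample_accession`` column when
        present, supplemented by run-table linkage. Without either source the
        mapping is empty (sample hits then cannot reach study aggregates).
        """
        links: dict[str, set[str]] = {}

        def add(sample_acc: str | None, study_acc: str | None) -> None:
            if sample_acc and study_acc and study_acc in self.studies:
                links.setdefault(sample_acc, set()).add(study_acc)

        for exp in self.experiments.values():
            add(exp.sample_accession, exp.study_accession)
        for run in self.runs.values():
            exp = self.experiments.get(run.experiment_accession)
            if exp is not None:
                add(run.sample_accession, exp.study_accession)
        if not links and self.samples:
            logger.warning(
                "no sample-to-study linkage available; sample-level hits "
                "will not contribute to study aggregation"
            )
        return {acc: frozenset(s) for acc, s in sorted(links.items())}

    def experiments_by_study(self) -> dict[str, list[ExperimentRecord]]:
        """Resolvable experiments grouped under their parent study."""
        grouped: dict[str, list[ExperimentRecord]] = {
            acc: [] for acc in self.studies
        }
        for exp in self.experiments.values():
            if exp.study_accession in grouped:
                grouped[exp.study_accession].append(exp)
        return grouped

    def dangling_experiments(self) -> list[ExperimentRecord]:
        """Experiments whose study reference does not resolve."""
        return [
            exp
            for exp in self.experiments.values()
            if exp.study_accession not in self.studies
        ]

    def counts(self) -> tuple[int, int, int]:
        return (len(self.studies), len(self.experiments), len(self.samples))


# ---------------------------------------------------------------------------
# Loading


def _check_columns(table: str, present: Sequence[str]) -> None:
    missing = [c for c in _REQUIRED_COLUMNS[table] if c not in present]
    if missing:
        raise SchemaError(
            f"table {table!r} is missing required column(s): {', '.join(missing)}"
        )


def _cell(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return str(value)


def _frames_to_corpus(frames: dict[str, pd.DataFrame]) -> MetadataCorpus:
    for table in _REQUIRED_COLUMNS:
        _check_columns(table, list(frames[table].columns))

    def rows(table: str) -> Iterator[dict[str, str | None]]:
        df = frames[table]
        cols = [
            c
            for c in _REQUIRED_COLUMNS.get(table, _RUN_COLUMNS)
            + _OPTIONAL_COLUMNS.get(table, ())
            if c in df.columns
        ]
        if table == "run":
            cols = [c for c in (*_RUN_COLUMNS, "sample_accession") if c in df.columns]
        for tup in df[cols].itertuples(index=False):
            yield {c: _cell(v) for c, v in zip(cols, tup)}

    studies = [StudyRecord(**r) for r in rows("study")]
    experiments = [ExperimentRecord(**r) for r in rows("experiment")]
    samples = [SampleRecord(**r) for r in rows("sample")]
    runs: list[RunRecord] = []
    if "run" in frames:
        run_cols = frames["run"].columns
        if all(c in run_cols for c in _RUN_COLUMNS):
            runs = [RunRecord(**r) for r in rows("run")]
        else:
            logger.warning("run table lacks linkage columns; ignoring it")
    corpus = MetadataCorpus.from_records(studies, experiments, samples, runs)
    n_dangling = len(corpus.dangling_experiments())
    logger.info(
        "loaded corpus: %d studies, %d experiments (%d dangling), %d samples, %d runs",
        len(corpus.studies),
        len(corpus.experiments),
        n_dangling,
        len(corpus.samples),
        len(corpus.runs),
    )
    return corpus


def _load_sqlite(path: Path) -> MetadataCorpus:
    with sqlite3.connect(path) as conn:
        existing = {
            name
            for (name,) in conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            )
        }
        frames: dict[str, pd.DataFrame] = {}
        for table in _REQUIRED_COLUMNS:
            if table not in existing:
                raise SchemaError(f"required table {table!r} not found in {path}")
            frames[table] = pd.read_sql_query(f"SELECT * FROM {table}", conn)
        if "run" in existing:
            frames["run"] = pd.read_sql_query("SELECT * FROM run", conn)
        else:
            logger.warning("no run table in %s; run linkage unavailable", path)
    return _frames_to_corpus(frames)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        na_values=[NULL_TOKEN],
    )


def _load_tsv_dir(path: Path) -> MetadataCorpus:
    frames: dict[str, pd.DataFrame] = {}
    for table in _REQUIRED_COLUMNS:
        tsv = path / f"{table}.tsv"
        if not tsv.exists():
            raise SchemaError(f"required table {table!r} not found ({tsv} missing)")
        frames[table] = _read_tsv(tsv)
    run_tsv = path / "run.tsv"
    if run_tsv.exists():
        frames["run"] = _read_tsv(run_tsv)
    else:
        logger.warning("no run.tsv in %s; run linkage unavailable", path)
    return _frames_to_corpus(frames)


def load_corpus(path: str | Path, dialect: str | None = None) -> MetadataCorpus:
    """Load a corpus from a SQLite file or a directory of per-table TSVs.

    Parameters
    ----------
    path
        SQLite database file (``dialect="sqlite"``) or directory holding
        ``study.tsv``, ``experiment.tsv``, ``sample.tsv`` and optionally
        ``run.tsv`` (``dialect="tsv"``). If ``dialect`` is None it is
        inferred from whether ``path`` is a directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "tsv" if path.is_dir() else "sqlite"
    if dialect == "sqlite":
        return _load_sqlite(path)
    if dialect == "tsv":
        return _load_tsv_dir(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Writing (used by the synthetic generator and the CLI)

_WRITE_COLUMNS: dict[str, tuple[str, ...]] = {
    "study": _REQUIRED_COLUMNS["study"],
    "experiment": _REQUIRED_COLUMNS["experiment"] + ("sample_accession",),
    "sample": _REQUIRED_COLUMNS["sample"],
    "run": ("run_accession", "experiment_accession", "sample_accession"),
}


def _corpus_frames(corpus: MetadataCorpus) -> dict[str, pd.DataFrame]:
    tables: dict[str, Iterable] = {
        "study": corpus.studies.values(),
        "experiment": corpus.experiments.values(),
        "sample": corpus.samples.values(),
        "run": corpus.runs.values(),
    }
    frames = {}
    for table, records in tables.items():
        cols = _WRITE_COLUMNS[table]
        frames[table] = pd.DataFrame(
            [[getattr(r, c) for c in cols] for r in records], columns=list(cols)
        ).astype(object)
    return frames


def write_corpus(corpus: MetadataCorpus, path: str | Path, dialect: str) -> Path:
    """Write a corpus as SQLite (single file) or TSV (one file per table)."""
    path = Path(path)
    frames = _corpus_frames(corpus)
    if dialect == "sqlite":
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as conn:
            for table, df in frames.items():
                cols = ", ".join(f"{c} TEXT" for c in df.columns)
                conn.execute(f"CREATE TABLE {table} ({cols})")
                placeholders = ", ".join("?" for _ in df.columns)
                conn.executemany(
                    f"INSERT INTO {table} VALUES ({placeholders})",
                    [
                        tuple(None if pd.isna(v) else v for v in row)
                        for row in df.itertuples(index=False)
                    ],
                )
            conn.commit()
        return path
    if dialect == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        for table, df in frames.items():
            df.to_csv(
                path / f"{table}.tsv", sep="\t", index=False, na_rep=NULL_TOKEN
            )
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Field access


def field_values(
    corpus: MetadataCorpus, ref: FieldRef
) -> list[tuple[str, str | None]]:
    """Per-record (accession, raw text) pairs for one auditable field.

    Text is passed through unmodified — nullness is judged later by
    :func:`is_null_text`, not here.
    """
    if ref not in AUDITABLE_FIELDS:
        raise ValueError(f"{ref} is not an auditable field")
    tables = {
        "study": corpus.studies,
        "experiment": corpus.experiments,
        "sample": corpus.samples,
    }
    records = tables[ref.table_name]
    return [(acc, getattr(rec, ref.field_name)) for acc, rec in records.items()]
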