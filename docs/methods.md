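# Methods

## The audit model

The unit of observation is a metadata *record* (a row of the study,
experiment or sample table) and the quantity of interest is whether its
free text documents each of three library-preparation protocol steps:
fragmentation, adapter ligation and enrichment.

Annotation is operationalised as keyword presence. Each step has an ordered
pattern list (11 / 12 / 10 patterns; `src/sraudit/data/lexicon.yaml`), and a
pattern matches a text iff its `%`-stripped, lowercased stem occurs as a
substring of the case-folded text. This deliberately reproduces SQL
`LIKE '%stem%'` semantics:

* `%` placement is irrelevant (`ligat%`, `%ligat` and `ligat` are
  equivalent), since the stem is matched unanchored;
* matching is case-insensitive (the SQLite `LIKE` default for ASCII) and
  otherwise byte-transparent — stems are ASCII, text is only case-folded;
* known false positives are accepted as part of the method: "sonic" hits
  *supersonic*, "t4" hits *T450*, "kit" hits *kits* and *kitchen*. The
  `step_term_overlap` operation quantifies a related artefact — stems
  nested inside other stems (e.g. `t4` ⊂ `t4-pnk`, `pnk` ⊂ `t4-pnk`) make
  some multi-pattern hits inevitable.

No stemming, tokenisation or other NLP is applied; anything deeper than
substring search is out of scope for this package by design.

Word lists are shipped as data, not code, so the transcription is
reviewable and swappable (`--lexicon` accepts an alternative YAML file with
keys `fragmentation`, `adapter_ligation`, `enrichment`, `reagent`).

### Nullness

A value counts as null if it is SQL NULL, empty, or whitespace-only. The
strict-SQL convention would count only NULL; whitespace-only text carries no
annotation, so folding it into "null" is the conservative, testable choice.
Nullness is judged at audit time — loaders pass text through unmodified and
preserve the NULL / empty-string distinction (TSV dialect encodes NULL as
`\N`).

### Record-level audit

For each of the seven audited (table, field) pairs: `total`, per-step
matched counts, `all_steps` (all three word lists hit *within that single
field value* — a record whose steps are scattered across different fields
is credited only under the optional `all_steps_scope="record"` variant),
`any_step`, and `null_count`. The conservation identity
`any_step + non-matching-non-null + null_count == total` holds for every
row and is asserted in tests. `library_selection` is a controlled-vocabulary
field but is audited identically to the free-text fields — its vocabulary
("Restriction Digest", ...) genuinely contains fragmentation stems, so
special-casing would change the counts.

Correspondence rates measure redundancy between fields: among records whose
*source* field (e.g. `study_abstract`, `design_description`) matches a
step, the fraction whose `library_construction_protocol` also matches it.
For study-level sources the natural unit is the study ("corresponds" = ≥ 1
child experiment's protocol field matches, since abstracts are per-study
and protocols per-experiment); an experiment-record unit is also available
because either reading of an archive-scale rate is defensible. A
step/source pair with zero matching records yields an explicitly undefined
rate (NaN with a `defined` flag), never a silent zero.

### Study-level aggregation

Hits in any audited field of the study itself, any child experiment, or any
linked sample are evidence for that step for the whole study. Samples link
to studies through the experiment table's `sample_accession` column and/or
the run table; without either source, sample hits cannot reach study
aggregates (a warning is logged). Experiments whose `study_accession` does
not resolve (real archive dumps contain such rows) stay in record-level
counts but are excluded from aggregation.

* **Fully annotated study**: ≥ 1 child experiment whose
  `library_construction_protocol` alone covers all three steps. This is the
  deliberately non-conservative rule — one annotated record is taken to
  stand for its siblings.
* **Unannotated study**: no audited field of the study or its children
  matched any step — the strictest reading of "no annotation whatsoever".
  A flag (`fields="experiment"`) restricts the scan to experiment-table
  fields, since an archive-scale unannotated rate could have been computed
  either way.
* **Annotation ratio**: fully-annotated experiments over total experiments,
  reported only for studies with ≥ 1 fully annotated experiment, hence
  bounded by 1/n and 1.

Percentages never live in result objects — audits carry integers, and
rendering applies round-half-up two-decimal formatting (`format_percent`,
`decimal`-based, locale-independent). Three published percent cells (0.98,
0.51, 1.53) are not derivable from their own printed integer counts under
any standard rounding; they are treated as typos, asserted irreproducible
in the test suite, and excluded from the acceptance report.

## The synthetic generator

`sraudit.synth` generates corpora that emulate the archive features the
audit is sensitive to, with defaults fixed once as the package's study
conditions:

* **Hierarchy**: `n_studies` (default 500) studies; experiments per study
  from a discretized Pareto law `min(cap, floor(1 + Lomax(alpha)))` with
  `alpha = 1.1`, `cap = 1000` (mean ≈ 5.6) — many small studies, a few very
  large ones. The cap keeps desk-scale runtimes; real archives contain
  studies with >15,000 experiments, a tail the default deliberately
  truncates. Each experiment gets one sample and one run, giving full
  linkage.
* **Annotation rates**: per-field per-step probabilities *conditional on
  the field being non-null*, back-derived from archive-scale marginal
  rates: e.g. the protocol field's null rate is 0.5112 and its conditional
  fragmentation rate 0.145, so the marginal matched fraction lands near
  7.1 %. Per-step draws are independent, which understates the real
  correlation between steps; the `p_full_study` parameter (default 0.047)
  compensates at the study level by planting one all-three-steps experiment
  in that fraction of studies — the redundancy pattern real submitters
  exhibit.
* **Reagent kits**: non-null protocol values mention "kit"/"reagent" with
  probability `p_kit = 0.11` (from the ≈ 5.5 % marginal mention rate).
* **Text realisation**: values are assembled from a validated template
  bank. Every positive template contains stems of exactly one step (and no
  reagent keyword); negative and kit templates contain no step stem.
  `validate_templates` enforces these contracts against the active lexicon
  and the pipeline refuses to generate from a violating bank. Templates are
  joined with `"; "`, and no stem contains a space or semicolon, so
  concatenation cannot create accidental cross-boundary matches.

Because every generation decision (null / intended step set / kit mention)
is recorded and templates are validated, `planted_truth` replays the
decisions and yields the *exact* audit table, study summary, ratio series
and reagent counts the pipeline must reproduce — the central end-to-end
oracle. Any deviation, on any seed, is a matcher or audit bug, not noise.
Generation is a pure function of the configuration, so equal seeds give
byte-identical output files.

### What passing tests do and do not show

The generator emulates structure, not prose: real metadata contains
misspellings, URLs standing in for protocols, tag-value blobs and
vocabulary drift that template text cannot represent. Exact-oracle
agreement therefore validates the pipeline's mechanics (matching,
counting, aggregation, serialization), not the lexicon's recall on real
submissions — by construction the lexicon's recall on template text is
perfect. Archive-scale percentages in the acceptance report are arithmetic
reproductions from published integer counts, not re-measurements of a live
archive.

## Numerical and design notes

* Iteration order everywhere is lexicographic by accession; synthetic
  accessions are zero-padded (`SRP`/`SRX`/`SRS`/`SRR`) so lexicographic and
  generation order coincide.
* Percent rendering uses round-half-up; of the published percent cells
  checked in the test suite, all self-consistent ones reproduce exactly
  under it.
* Two distinct archive-scale experiment totals circulate (419,620 in the
  tabulated audit vs 414,788 in the prose any-step rate); the package
  reports whatever it counts, and the acceptance report pairs each printed
  numerator with its own denominator.
* The published null rate 51.12 % truncates 212,070/414,788 = 51.127 %;
  the round-half-up value 51.13 is reported.
* Degenerate inputs: empty corpora audit to seven all-zero rows with `NA`
  percent cells; a zero-experiment study has ratio 0 and is excluded from
  the ratio series; undefined correspondence rates are flagged, not zeroed.
* Known limitations: no XML parsing, no submission-date handling (stored
  too inconsistently in the wild to be worth modelling), no per-keyword hit
  attribution (per-step booleans only), no modelling of realistic English
  beyond template assembly.
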