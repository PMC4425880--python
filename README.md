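# sraudit

**sraudit** audits how well free-text sequencing metadata documents the three
key library-preparation protocol steps — **DNA fragmentation**, **adapter
ligation** (including blunting and phosphorylation) and **library
enrichment** (e.g. PCR) — in SRA-style archives. It is aimed at
bioinformaticians and data curators who need to know whether a corpus of
submissions carries enough protocol annotation to support bias-aware
meta-analysis, and at archive maintainers quantifying metadata completeness.

Sample-preparation steps are known sources of sequence-level bias (shearing
resistance, ligation strand preference, PCR GC bias). Quantifying those
biases downstream requires knowing which protocol was used — information
that lives, if anywhere, in free-text metadata fields such as the
experiment table's `library_construction_protocol`.

## Method

Because the fields are free text, annotation is detected by controlled
keyword search. For each protocol step *s* there is an ordered word list
*W<sub>s</sub>* (11 fragmentation, 12 adapter-ligation and 10 enrichment
patterns, shipped as reviewable data in
`src/sraudit/data/lexicon.yaml`). A pattern may carry a `%` fuzzy-match
marker (`amplif%` matches *amplify*, *amplified*); matching strips `%` and
tests the stem as an unanchored case-insensitive substring, i.e. SQL
`LIKE '%stem%'`. A field value *t* is **annotated for step s** iff some
stem of *W<sub>s</sub>* occurs in *t*, **fully annotated** iff it is
annotated for all three steps, and **null** iff it is absent, empty or
whitespace.

Seven (table, field) pairs are audited: `study.study_abstract`,
`study.study_description`, `sample.description`, and the experiment table's
`design_description`, `library_selection`, `library_construction_protocol`
and `experiment_attribute`. Record-level audits count, per field, the
records annotated per step, for all steps, for any step, and the nulls.
Study-level aggregation pools every audited field of a study and its child
records: a study is *fully annotated* if ≥ 1 child experiment's
`library_construction_protocol` covers all three steps (the deliberately
non-conservative rule), *unannotated* if nothing matched anywhere. For each
study with at least one fully annotated experiment the **annotation ratio**
r = (fully annotated experiments)/(total experiments) is reported; by
construction 1/n ≤ r ≤ 1, and points on the 1/n curve are the
"annotate one record for the whole study" pattern.

A synthetic-corpus generator (`sraudit.synth`) emulates the archive's
hierarchy and annotation rates with *planted*, exactly recorded truth, so
the whole pipeline is testable end to end without any download.

## Worked example

Generate a 200-study synthetic corpus and audit it:

```
$ sraudit synth --n-studies 200 --seed 42 --out corpus
$ sraudit audit --tables-dir corpus --format tsv
```

which prints (percent columns abbreviated here):

```
table       field                          total  frag  frag_pct  lig  enr  all  any  null
study       study_abstract                 200    2     1.00      0    11   0    13   9
study       study_description              200    1     0.50      0    1    0    2    62
sample      description                    881    2     0.23      1    4    0    7    337
experiment  design_description             881    21    2.38      17   38   0    74   271
experiment  library_selection              881    5     0.57      0    0    0    5    44
experiment  library_construction_protocol  881    72    8.17      51   78   14   155  457
experiment  experiment_attribute           881    0     0.00      3    6    0    9    498
# studies   total=200  fully_annotated=14  unannotated=105
# reagent   kit_records=54  all_steps_and_kit=2  studies_with_overlap=2
```

Reading it: of 881 experiment records, 72 (8.17 %) mention a fragmentation
keyword in the protocol field, only 14 mention keywords of all three steps
in that field, and 457 (51.87 %) leave it null — the canonical field is
empty for half the records. At the study level 14 of 200 studies have at
least one fully annotated experiment while 105 have no protocol annotation
anywhere. `sraudit plot --tables-dir corpus --out ratios.png` renders the
per-study annotation-ratio scatter with the 1/n guide curve, and
`sraudit audit --ratios ratios.tsv ...` exports the underlying points.

The same audit runs on any SRAdb-shaped SQLite file via `--db meta.sqlite`
(tables `study`, `experiment`, `sample`, optionally `run`, with the column
names above) or on per-table TSVs (`\N` encodes NULL).

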