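# pgdbkit

A curation toolkit for frame-based pathway/genome databases (PGDBs).

Organism databases in the BioCyc tradition store everything known about one
organism as *frames* — one record per gene, protein, compound, reaction,
pathway, or regulatory interaction — with named *slots* holding values and
*slot-value annotations* holding per-value metadata (citations, evidence
codes, curator identity). Keeping the manually curated content of such
databases alive across rebuilds, and sharing it between sister databases
built from the same genome, is tedious and error-prone by hand. pgdbkit is
for curators and bioinformaticians who need to do that work in batch, with a
preview before anything is written and a full rollback if it goes wrong.

## What it does

* **Frame store** — an in-memory frame database with a class taxonomy,
  three write modes (`overwrite`, `append`, `append-ignore-duplicates`),
  per-value annotations, curator credit stamping, single-level transactions
  (`begin` / `rollback` / `commit`), and referential-integrity checking.
* **Strict identifier resolution** — alternate identifiers (synonyms,
  accessions, gene-model names) resolve to frame IDs only when they match a
  name-slot value *exactly and entirely* (case-insensitive) and the match is
  *unique*; partial and ambiguous hits are rejected rather than guessed.
* **Batch imports** — five import types from CSV files (slot data,
  slot-value annotations, GO annotations, frame deletion, new regulation
  frames), with a plan → preview (character-level diffs) → apply →
  commit/rollback lifecycle and a timestamped per-row change log.
* **Cascading deletion** — deleting a gene deletes its products, orphaned
  enzymatic reactions and reactions, and linked regulation and history-note
  frames, leaving the database referentially intact.
* **GO-annotation migration** — export annotations from a source database,
  keep only experimentally verified ones (evidence codes beginning
  `EV-EXP`), map proteins into a target database through shared gene-model
  names (`STEM_P01`-style, splice-variant aware), and import the survivors.
* **Strain derivation** — clone a parent database and replay engineering
  interventions (gene knockouts, comment appends, predicted regulation,
  cassette replacements) to produce a strain-specific database.
* **Synthetic fixtures** — a deterministic generator of single and paired
  databases with recorded ground truth, so every pipeline is testable
  without any external database.

## Worked example

Generate a paired fixture — a "source" database carrying GO annotations and
a "target" database sharing its gene-model namespace but not its frame IDs —
then migrate the experimentally supported annotations:

```bash
$ pgdbkit generate-fixture --out pair --paired --seed 11 --split 40,10,50
paired fixture written to pair (split 40/10/50)

$ pgdbkit migrate-go --source pair/source --target pair/target \
      --policy exact --report report.tsv --log log.tsv
proteins: 40 exact, 0 relaxed-only, 60 unmatched; 40 annotation rows imported, 0 failed

$ pgdbkit validate --db pair/target
0 violations
```

The fixture was built so that 40 gene models have an exactly matching splice
variant in the target, 10 match only after relaxing the splice-variant
suffix, and 50 are absent. Under the strict `exact` policy only the 40 exact
matches receive annotations (the 10 relaxed candidates are counted among the
60 unmatched); re-running with `--policy relaxed` reports
`40 exact, 10 relaxed-only, 50 unmatched` and also annotates the
lowest-numbered variant for each relaxed match. The report file lists the
outcome per protein:

```text
gene_model_name	outcome	target_frame_ids	n_annotations_migrated
GM2G574354_P01	exact	GDQC-0001-1	1
GM2G686963_P01	exact	GDQC-0002-1	1
...
# proteins: exact=40 relaxed_only=0 unmatched=60
# annotation records: exact=40 relaxed_only=0 unmatched=60
```

The same operations are available as a library:

```python
from pgdbkit import generate_paired_pgdbs, migrate_go
from pgdbkit.fixture_gen import builtin_go_reference

source, target, truth = generate_paired_pgdbs(split=(40, 10, 50), seed=11)
log, report = migrate_go(source, target, builtin_go_reference(), "exact")
target.commit()
print(report.n_exact, report.n_relaxed_only, report.n_unmatched)  # 40 0 60
```

Other subcommands: `import` (with `--dry-run` previews), `resolve`,
`delete`, `clone`, `derive-strain`, `diff`, `validate`.

## Documentation

The model, its assumptions, parameter defaults, and known limitations are
described in [docs/methods.md](docs/methods.md).
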