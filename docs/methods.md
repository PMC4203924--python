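# Methods

This note documents the data model, the policies each pipeline implements,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the toolkit's known limitations.

## The frame model

A database is a named, ordered collection of frames. A frame has an
immutable frame ID (non-empty token, no whitespace or commas), one or more
object classes, and an ordered map of slots; each slot holds an ordered list
of values, and each value carries its own ordered annotation map
(label → list of scalars). All scalars are stored as text; values in a fixed
set of reference slots (`GENE`, `PRODUCT`, `ENZYME`, `REACTION`, `LEFT`,
`RIGHT`, `REACTION-LIST`, `REGULATOR`, `REGULATED-ENTITY`,
`REFERENCED-FRAME`, `GO-TERMS`, `CREDITS`, …) are interpreted as frame
references and checked by `integrity_check`.

The class taxonomy is a forest seeded with the built-in classes (`Gene`,
`Protein` with subclasses `Polypeptide` and `Protein-Complex`,
`Enzymatic-Reaction`, `Reaction`, `Compound`, `Pathway`, `Regulation`,
`GO-Term`, `Person`, `Organization`, `History-Note`, `Organism`). Each class
declares its *name slots* — the slots whose values act as alternate
identifiers — defaulting to `ACCESSION`, `COMMON-NAME`, `SYNONYMS`,
`DBLINKS` and configurable per class. A single case-normalized index maps
every name-slot value to the frames carrying it; class filtering happens at
query time rather than in the index key, which keeps one index instead of
one per class with identical behaviour.

Iteration and serialization follow insertion order throughout, so the
canonical rendering of a database is deterministic and byte-identity of
serializations is a meaningful equality test. Revision records (creation,
credits, cascade side-effects) are kept in memory but deliberately excluded
from the canonical serialization: they describe the editing history, not the
biological content, and excluding them is what makes "rollback restores the
pre-transaction serialization" and "re-import is a no-op" crisp, checkable
properties.

## Write modes

Three modes govern every slot or annotation write:

* `overwrite` — delete existing content first (per-value annotations go
  with their values);
* `append` — new values follow existing ones in order;
* `append-ignore-duplicates` — a new value exactly equal to one already
  present is skipped; pre-existing duplicates are never removed. This makes
  the mode idempotent: applying the same values twice equals applying once.

Duplicate comparison is exact string equality on the value (for slot writes)
or on the annotation scalar (for annotation writes); annotation payloads are
not consulted when deciding whether a slot value is a duplicate, and vice
versa.

## Identifier resolution

All database operations address frames by frame ID, but curators supply
literature identifiers. Resolution applies, in order:

1. **Direct frame-ID hit** — a case-sensitive match against an existing
   frame ID of the requested class resolves immediately and bypasses search.
   (Case-sensitivity mirrors the distinction between identifier lookup and
   indexed text search; the class check prevents a compound ID from
   satisfying a protein query during migration.)
2. **Query validation** — search terms need ≥ 3 characters. A
   `compat=True` mode additionally rejects commas and spaces, emulating
   backends whose text index cannot take multi-word queries; the native mode
   allows them, since multi-word compound synonyms ("pyruvic acid") are
   legitimate identifiers. Both behaviours are exposed because the two
   constraints conflict in practice and the right choice depends on the
   backend being emulated. The length rule applies to search only, never to
   direct frame-ID lookup.
3. **Substring search, then strict filter** — candidates are frames of the
   class (or a subclass) whose ID equals the term or whose name-slot values
   contain it, case-insensitively; candidates survive only if some name-slot
   value equals the term *entirely*. A query for a bare gene-model stem
   therefore does not match a suffixed splice-variant synonym.
4. **Uniqueness** — exactly one survivor resolves; two or more yield
   `ambiguous`, zero yields `none`, and nothing is guessed.

Batch resolution skips the search step entirely when every identifier in
the batch is already a valid frame ID. Unresolvable identifiers either skip
their rows (reported) or abort the whole batch before any mapping is
returned, at the caller's choice.

## Imports

An import runs as **plan → preview → apply → commit/rollback**:

* *Planning* resolves every identifier and produces one action per
  surviving row; the database is untouched.
* *Preview* applies the plan to a scratch copy and reports per-frame edit
  scripts — equal/insert/delete character spans computed with stdlib
  `difflib.SequenceMatcher` on a stable one-line-per-value frame rendering.
  Applying the script to the before-text reproduces the after-text exactly;
  an unchanged frame yields an empty script, a deleted frame an empty
  after-text.
* *Apply* requires an open transaction. Rows are applied independently in
  file order (later rows see earlier rows' effects); a failing row is
  logged and never partially applied — each action validates its inputs
  before mutating anything. When an author is set, every frame actually
  modified gains a `CREDITS` entry once per run, with a timestamped
  revision.
* The change log records one timestamped success/fail entry per action,
  referring back to the 1-based data-row index; skipped rows are carried
  alongside, so every input row is accounted for.

`overwrite` clears a given (frame, slot) only on the *first* action of the
run that touches it; later rows of the same file append. This keeps all the
rows of an import file while still replacing pre-existing content, which is
the only reading under which a multi-row overwrite import is not
self-destructive.

GO-annotation rows create at most one `GO-Term` frame per distinct GO id
(name/namespace/definition populated from a GO reference — an OBO 1.2 file
parsed with `obonet`, a 4-column TSV, or the small built-in table), append a
reference to the protein's `GO-TERMS` slot, and attach `CITATIONS`,
`EVIDENCE`, `CURATOR`, and `TIMESTAMP` annotations to that one value. A row
whose content is already fully present (value and citation/evidence/curator)
is a logged success but modifies nothing — no credit, no timestamp — so that
re-imports are no-ops under a real wall clock, not just under the injected
test clock. A GO id missing from the reference fails that row only.

Regulation imports create one new frame per row with sequential zero-padded
ids (`REG-0001`, `REG-0002`, …; the counter skips ids already in use). No
duplicate-interaction detection is attempted: the same interaction listed
twice yields two frames, and deduplication is the data provider's
responsibility.

## Cascading deletion

`delete_frame_and_dependents` computes a fixed point of these rules and
then removes the closure atomically:

* a protein is deleted once **all** genes coding for it are deleted — a
  product still encoded by a surviving gene survives (multi-gene products
  are not addressed by the classical single-gene rule; deleting them while
  a coding gene survives would orphan live annotation, so the conservative
  reading was chosen);
* an enzymatic-reaction is deleted when its enzyme or its reaction is;
* a reaction that *had* catalysts is deleted when all of them are gone; an
  uncatalyzed (spontaneous) reaction is never cascaded;
* a regulation frame is deleted when its regulator or regulated entity is
  (this subsumes transcription-factor deletion);
* a history note is deleted with the frame it references.

Pathways are never cascade-deleted: deleted reactions are removed from
pathway reaction lists and the removal is recorded as a revision on the
pathway. After removal, any remaining references to deleted frames in
surviving frames (a surviving product's `GENE` entry, a complex's
components) are scrubbed, so `integrity_check` returns clean after any
deletion. The test suite checks the closure against an independently coded
brute-force reachability oracle on randomized fixtures.

## Transactions

Single-level transactions snapshot the full frame map, indexes, and
counters (`begin`), and restore them (`rollback`) or discard the snapshot
(`commit`). Databases here are at most tens of thousands of small frames, so
a full deep-copy snapshot is simpler and safer than operation journaling;
rollback restores a state whose canonical serialization is byte-identical to
the pre-begin state. Nested `begin` and rollback/commit without `begin` are
errors.

Timestamps come from an injectable clock (`Database.clock`); tests and the
fixture generator inject a deterministic tick clock so serializations that
include timestamp annotations are reproducible. Copying a database
deep-copies its clock, which is what makes preview's predicted after-texts
identical to the real apply's results.

## GO-annotation migration

The pipeline is export → evidence filter → protein mapping → import:

* **Export** emits one record per (protein, GO value, citation/evidence
  pair); parallel `CITATIONS`/`EVIDENCE` lists are paired by position, as
  they were imported. Proteins without a gene-model-name synonym
  (`STEM_P<digits>`) are exported with an empty name and flagged.
* **Filter** keeps exactly the records whose evidence code begins `EV-EXP`
  (experimentally verified, i.e. manually curated support); the filter is a
  fixed point.
* **Mapping** resolves each distinct protein's full gene-model name in the
  target under the strict policy above. Under `relaxed`, a protein with no
  exact hit may map to a target variant sharing its stem; when several
  variants share the stem the **lowest-numbered** one is chosen — some
  deterministic rule is required and lowest-number is reproducible and easy
  to audit. Ambiguous resolutions count as unmatched and are flagged. The
  report counts both proteins and annotation records per outcome, because
  "n matches" is ambiguous between the two and both are useful.
* **Import** feeds the surviving records into the GO import by target frame
  ID (so resolution is trivially skipped), under a transaction, defaulting
  to ignore-duplicates so the whole migration is idempotent.

Validation is by ground-truth recovery on paired synthetic fixtures: the
generator records the intended outcome per stem, and mapping must reproduce
it exactly, with zero annotations landing outside the matched set. Counts
from real database pairs depend entirely on the content of the specific
releases involved and are not meaningful test targets.

## Strain derivation

`derive_strain` clones the parent (deep copy; a clone must take a new
orgid, since two databases with the same name cannot coexist) and applies
interventions in file order on the clone, logging per-intervention success
or failure: gene deletions (full cascade), comment appends (new text after
any existing `COMMENT` content, separated by a blank line — existing text is
preserved verbatim and first), new regulation frames (mode `+`, `-`, or
`unknown`, since computational predictions may lack a sign and are imported
as direct regulator→gene links without binding sites), and cassette
replacements. A cassette replacement is modeled as deletion of the replaced
genes plus a comment on the organism summary frame naming the marker;
inserting the marker gene itself is out of scope, as marker detail belongs
in free-text comments rather than structured slots. The parent's
serialization is never changed by a derivation.

## Synthetic-data generator

`generate_pgdb` builds a structurally complete database: genes with 1–2
splice-variant products carrying `STEM_P01`-style synonyms, about half of
the proteins wired to reactions through enzymatic-reaction frames (with a
mix of reactions catalyzed by none, one, or two enzymes, so both the orphan
and the survivor cases of cascade deletion occur), transcription factors
with regulation frames, compounds with deliberately multi-word synonyms,
pathways, history notes, curator/organization frames, and GO annotations on
~40% of proteins with a 50/50 experimental/computational evidence mix.
Defaults (30 genes, 20 compounds, 12 reactions) keep a single fixture around
130 frames — large enough to exercise every rule, small enough to generate
hundreds of seeded instances in property tests. `generate_paired_pgdbs`
additionally controls the cross-database outcome per stem and records it as
ground truth; the default split (40 exact / 10 relaxed-only / 50 absent)
makes the strict-matching and relaxation behaviours both visible in every
run. Everything is a pure function of (params, seed).

What the generator does **not** emulate: biologically realistic network
topology, sequence data, protein complexes with components, multi-organism
content, malformed or inconsistent legacy records, and the scale of real
organism databases (tens of thousands of frames). Passing tests therefore
demonstrate the correctness of the policies on well-formed content, not
robustness against arbitrarily dirty real-world databases.

## File formats

PGDB content is read and written as attribute-value flat files (the de-facto
convention for frame databases): `UNIQUE-ID` and `TYPES` lines open each
record, `<LABEL> - <value>` lines carry slot values, `^<LABEL> - <value>`
lines attach annotations to the immediately preceding value,
`/`-continuation lines carry multi-line text, and `//` separates records.
The writer and reader are exact inverses on canonical serialization. CSV
import files use RFC 4180 quoting with one fixed column set per import type;
blank lines and `#` comments are ignored and row indices count data rows
only. Change logs and migration reports are TSV.

## Problem sizes and numerical choices

The acceptance checks use: one ≥500-frame fixture for round-trip identity,
100 seeded fixtures for the cascade oracle, 50 random edit sequences for
transaction identity, 10 paired fixtures (100 stems each) for migration
recovery, and 5 fixtures for strain-derivation safety — sizes chosen so the
full suite completes in seconds while every rule fires many times. Frame
diffs use Ratcliff-Obershelp matching (`difflib`) with `autojunk` disabled
so long common prefixes are never misclassified. GO identifiers are
normalized to `GO:` + 7 zero-padded digits; bare numbers are rejected rather
than guessed.

## Known limitations

* No concurrent multi-user editing, no disk-backed incremental persistence,
  no client–server protocol: the store is in-memory with whole-file I/O.
* Single-level transactions only.
* Deleting a non-enzyme, non-TF protein cascades only to linked regulation
  and history notes; any further domain-specific dependents would need new
  rules.
* No fuzzy or orthology-based identifier matching: resolution is exact by
  design.
* Flat-file values that themselves begin with the dialect's structural
  prefixes (`/`, `^`) on their first line are not escaped; generated and
  curated content does not produce them.
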