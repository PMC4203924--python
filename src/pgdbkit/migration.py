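"""Cross-database GO-annotation migration.

Two frame databases built from the same gene-model set can nevertheless use
entirely different internal frame IDs (different ID syntax rules per build
pipeline).  What they share is the gene-model name carried as a synonym on
protein frames — a stem plus a splice-variant suffix, e.g.
``GRMZM2G136161_P01``.  This module migrates manually curated GO-term
annotations from a source database to a target database through that shared
namespace:

1. export every (protein, GO term, citation/evidence) annotation record from
   the source;
2. keep only experimentally verified records — evidence codes beginning
   ``EV-EXP`` (manual curation), dropping computational ones;
3. map each source protein into the target by resolving its full gene-model
   name (strict, entire-string, unique); under the ``relaxed`` policy a
   protein whose exact splice variant is absent may instead map to a target
   variant sharing the stem (lowest-numbered variant, deterministically);
4. import the surviving records into the target under a transaction,
   creating GO-Term frames as needed.

The match report classifies every source protein as ``exact``,
``relaxed-only``, or ``unmatched``, and counts both proteins and annotation
records per class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .flatfile_io import GoTerm, ImportRow
from .frame_store import Database
from .id_resolution import STATUS_AMBIGUOUS, resolve
from .import_engine import ChangeLog, ImportOptions, import_go_annotations

__all__ = [
    "GoAnnotationRecord",
    "ProteinMatch",
    "MatchReport",
    "SPLICE_SUFFIX_RE",
    "split_gene_model_name",
    "export_go_annotations",
    "filter_experimental",
    "map_proteins",
    "migrate_go",
]

#: Gene-model names end in a numeric splice-variant suffix: stem + "_P" + digits.
SPLICE_SUFFIX_RE = re.compile(r"^(?P<stem>.+)_P(?P<num>\d+)$", re.IGNORECASE)

EXPERIMENTAL_PREFIX = "EV-EXP"


def split_gene_model_name(name: str) -> Optional[tuple[str, int]]:
    """Split ``STEM_P01`` into ("STEM", 1); None if the suffix is missing."""
    m = SPLICE_SUFFIX_RE.match(name)
    if not m:
        return None
    return m.group("stem"), int(m.group("num"))


@dataclass
class GoAnnotationRecord:
    """One exported (protein, GO term, citation/evidence pair) annotation."""

    protein_id: str
    gene_model_name: str  # "" when the protein lacks one (record is flagged)
    go_id: str
    evidence: str = ""
    citation: str = ""
    curator: str = ""
    flagged: bool = False

    @property
    def stem(self) -> Optional[str]:
        parts = split_gene_model_name(self.gene_model_name)
        return parts[0] if parts else None

    @property
    def suffix_number(self) -> Optional[int]:
        parts = split_gene_model_name(self.gene_model_name)
        return parts[1] if parts else None


@dataclass
class ProteinMatch:
    protein_id: str
    gene_model_name: str
    outcome: str  # exact | relaxed-only | unmatched
    targets: list[str] = field(default_factory=list)
    flagged_ambiguous: bool = False
    n_records: int = 0
    n_annotations_migrated: int = 0


@dataclass
class MatchReport:
    matches: list[ProteinMatch] = field(default_factory=list)

    def _count(self, outcome: str) -> int:
        return sum(1 for m in self.matches if m.outcome == outcome)

    def _count_records(self, outcome: str) -> int:
        return sum(m.n_records for m in self.matches if m.outcome == outcome)

    @property
    def n_exact(self) -> int:
        return self._count("exact")

    @property
    def n_relaxed_only(self) -> int:
        return self._count("relaxed-only")

    @property
    def n_unmatched(self) -> int:
        return self._count("unmatched")

    @property
    def n_records_exact(self) -> int:
        return self._count_records("exact")

    @property
    def n_records_relaxed_only(self) -> int:
        return self._count_records("relaxed-only")

    @property
    def n_records_unmatched(self) -> int:
        return self._count_records("unmatched")

    def by_protein(self) -> dict[str, ProteinMatch]:
        return {m.protein_id: m for m in self.matches}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _gene_model_name_of(db: Database, frame) -> str:
    for label in db.name_slots_for(frame):
        for value in frame.slot_values(label):
            if SPLICE_SUFFIX_RE.match(value):
                return value
    return ""


def export_go_annotations(db: Database) -> list[GoAnnotationRecord]:
    """One record per (protein, GO value, citation/evidence pair).

    A GO value carrying k parallel citation/evidence annotations yields k
    records sharing the GO id (annotations are paired by position, as they
    were imported).  Proteins without GO-TERMS yield nothing; a protein
    lacking a gene-model name is exported with an empty name and flagged.
    """
    records: list[GoAnnotationRecord] = []
    for frame in db.frames_of_class("Protein"):
        svs = frame.slots.get("GO-TERMS", [])
        if not svs:
            continue
        name = _gene_model_name_of(db, frame)
        for sv in svs:
            citations = sv.annotations.get("CITATIONS", [])
            evidence = sv.annotations.get("EVIDENCE", [])
            curators = sv.annotations.get("CURATOR", [])
            n = max(len(citations), len(evidence), 1)
            for i in range(n):
                records.append(GoAnnotationRecord(
                    protein_id=frame.id,
                    gene_model_name=name,
                    go_id=sv.value,
                    evidence=evidence[i] if i < len(evidence) else "",
                    citation=citations[i] if i < len(citations) else "",
                    curator=(curators[i] if i < len(curators)
                             else (curators[0] if curators else "")),
                    flagged=not name,
                ))
    return records


def filter_experimental(records: Sequence[GoAnnotationRecord]
                        ) -> list[GoAnnotationRecord]:
    """Keep exactly the records whose evidence code begins ``EV-EXP``
    (experimentally verified); order preserved.  Idempotent."""
    return [r for r in records if r.evidence.startswith(EXPERIMENTAL_PREFIX)]


# ---------------------------------------------------------------------------
# Protein mapping
# ---------------------------------------------------------------------------

def _relaxed_candidates(target: Database, stem: str) -> list[tuple[int, str, set[str]]]:
    """(suffix number, normalized name, frame ids) for target names sharing
    the stem, sorted by suffix number."""
    pattern = re.compile(re.escape(stem.lower()) + r"_p(\d+)$")
    out = []
    for key, ids in target.name_index.items():
        m = pattern.match(key)
        if m:
            protein_ids = {
                fid for fid in ids
                if target.is_instance(target.frames[fid], "Protein")}
            if protein_ids:
                out.append((int(m.group(1)), key, protein_ids))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def map_proteins(records: Sequence[GoAnnotationRecord], target: Database,
                 policy: str = "exact") -> MatchReport:
    """Classify each distinct source protein against the target database.

    ``exact``: the full gene-model name (stem + splice suffix) resolves
    uniquely in the target.  ``relaxed``: additionally, a protein with no
    exact hit may match the lowest-numbered target splice variant sharing
    its stem (outcome ``relaxed-only``).  Ambiguous resolutions count as
    unmatched and are flagged.
    """
    if policy not in ("exact", "relaxed"):
        raise ValueError(f"unknown mapping policy: {policy}")
    report = MatchReport()
    seen: dict[str, ProteinMatch] = {}
    for record in records:
        if record.protein_id in seen:
            seen[record.protein_id].n_records += 1
            continue
        match = _map_one(record, target, policy)
        match.n_records = 1
        seen[record.protein_id] = match
        report.matches.append(match)
    return report


def _map_one(record: GoAnnotationRecord, target: Database,
             policy: str) -> ProteinMatch:
    name = record.gene_model_name
    if not name:
        return ProteinMatch(record.protein_id, name, "unmatched")
    result = resolve(target, name, "Protein")
    if result.resolved:
        return ProteinMatch(record.protein_id, name, "exact", [result.frame_id])
    if result.status == STATUS_AMBIGUOUS:
        return ProteinMatch(record.protein_id, name, "unmatched",
                            list(result.matches), flagged_ambiguous=True)
    if policy == "relaxed" and record.stem is not None:
        for _, _, ids in _relaxed_candidates(target, record.stem):
            if len(ids) > 1:
                # several frames share the variant name: ambiguous, flag it
                return ProteinMatch(record.protein_id, name, "unmatched",
                                    sorted(ids), flagged_ambiguous=True)
            return ProteinMatch(record.protein_id, name, "relaxed-only",
                                sorted(ids))
    return ProteinMatch(record.protein_id, name, "unmatched")


# ---------------------------------------------------------------------------
# Migration pipeline
# ---------------------------------------------------------------------------

def migrate_go(source: Database, target: Database,
               go_ref: dict[str, GoTerm], policy: str = "exact",
               options: Optional[ImportOptions] = None
               ) -> tuple[ChangeLog, MatchReport]:
    """Migrate experimentally verified GO annotations from source to target.

    Only exact matches receive annotations under the ``exact`` policy;
    ``relaxed`` additionally migrates to relaxed-only matches.  The target is
    modified under a transaction (auto-opened if none) and left unsaved so
    the caller can review the change log before committing.  Defaults to
    ignore-duplicates so re-running the migration is a no-op.
    """
    options = options or ImportOptions(ignore_duplicates=True)
    records = filter_experimental(export_go_annotations(source))
    report = map_proteins(records, target, policy)
    allowed = {"exact"} if policy == "exact" else {"exact", "relaxed-only"}
    by_protein = report.by_protein()
    rows: list[ImportRow] = []
    for record in records:
        match = by_protein[record.protein_id]
        if match.outcome not in allowed:
            continue
        rows.append(ImportRow(row_index=len(rows) + 1, fields={
            "identifier": match.targets[0],
            "go-id": record.go_id,
            "evidence-code": record.evidence,
            "citation": record.citation,
            "curator": record.curator,
        }))
        match.n_annotations_migrated += 1
    log = import_go_annotations(target, rows, go_ref, options)
    return log, report
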