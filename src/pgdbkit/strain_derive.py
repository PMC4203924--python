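"""Strain-specific database derivation.

Metabolic engineering produces strains that differ from a well-curated
parent organism by a handful of interventions: gene knockouts, enzymes with
altered specificity (best recorded as free-text comments, since kinetic
detail has no structured slot), and predicted regulatory links.  Rather than
re-curating from scratch, a strain database is derived by cloning the parent
and replaying the interventions in order:

* ``gene-deletion`` — cascade-delete the gene, its products, orphaned
  enzymatic reactions and reactions, and linked regulation/history notes;
* ``comment-append`` — append text to a frame's COMMENT slot after any
  existing comment, separated by a blank line (existing text always first);
* ``add-regulation`` — create sequential Regulation frames (mode ``+``,
  ``-`` or unknown, since predictions may lack a sign);
* ``cassette-replacement`` — delete the replaced genes and record the
  inserted marker as a comment on the organism summary frame (marker genes
  themselves are not modeled).

The parent database is never modified: all edits go to the clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .frame_store import Database, PgdbError
from .id_resolution import resolve
from .import_engine import ChangeLog, ChangeLogEntry, ImportOptions

__all__ = [
    "INTERVENTION_KINDS",
    "Intervention",
    "SameOrgIdError",
    "clone_database",
    "derive_strain",
    "load_interventions",
]

INTERVENTION_KINDS = (
    "gene-deletion", "comment-append", "add-regulation", "cassette-replacement",
)


class SameOrgIdError(PgdbError):
    """Two databases cannot share an orgid; a clone must be renamed."""


@dataclass
class Intervention:
    """One engineering intervention; payload keys depend on the kind.

    gene-deletion: {"gene": identifier}
    comment-append: {"frame": identifier, "comment": text}
    add-regulation: {"regulator": id, "target": id, "mode": "+"|"-"|"unknown"}
    cassette-replacement: {"genes": [identifiers], "marker": text}
    """

    kind: str
    payload: dict = field(default_factory=dict)

    _REQUIRED = {
        "gene-deletion": ("gene",),
        "comment-append": ("frame", "comment"),
        "add-regulation": ("regulator", "target"),
        "cassette-replacement": ("genes",),
    }

    def __post_init__(self) -> None:
        if self.kind not in INTERVENTION_KINDS:
            raise PgdbError(f"unknown intervention kind: {self.kind}")
        missing = [k for k in self._REQUIRED[self.kind] if k not in self.payload]
        if missing:
            raise PgdbError(
                f"{self.kind} intervention missing field(s): {', '.join(missing)}")


def clone_database(db: Database, new_orgid: str, new_name: str,
                   new_version: Optional[str] = None) -> Database:
    """Deep-copy a database under a new orgid/name.

    The clone's frame content serializes identically to the source and
    shares no mutable state with it: edits to either never affect the other.
    """
    if new_orgid == db.orgid:
        raise SameOrgIdError(
            f"clone must use a different orgid (both are {db.orgid!r})")
    clone = db.copy()
    clone.orgid = new_orgid
    clone.name = new_name
    if new_version is not None:
        clone.version = new_version
    return clone


def _append_comment(db: Database, frame_id: str, text: str) -> None:
    frame = db.get(frame_id)
    existing = frame.slot_values("COMMENT")
    if existing:
        # keep existing comment text verbatim and first; blank-line separator
        merged = existing[0] + "\n\n" + text
        db.edit_slot(frame_id, "COMMENT", [merged] + existing[1:], "overwrite")
    else:
        db.edit_slot(frame_id, "COMMENT", [text], "overwrite")


def derive_strain(db: Database, interventions: Sequence[Intervention],
                  options: Optional[ImportOptions] = None,
                  new_orgid: Optional[str] = None,
                  new_name: Optional[str] = None
                  ) -> tuple[Database, ChangeLog]:
    """Clone ``db`` and apply the interventions in order to the clone.

    Returns the derived database (committed) and a change log with one entry
    per intervention (row_index = 1-based intervention position).  Failures
    (unresolvable identifiers) are logged per intervention and do not halt
    the rest.  The parent is untouched.
    """
    options = options or ImportOptions()
    strain = clone_database(
        db,
        new_orgid or f"{db.orgid}-D1",
        new_name or f"{db.name} (derived strain)")
    strain.begin()
    log = ChangeLog()
    for idx, iv in enumerate(interventions, start=1):
        try:
            frame_id, message = _apply_intervention(strain, iv, options)
            log.entries.append(ChangeLogEntry(
                strain.clock(), idx, "success", frame_id, message))
        except PgdbError as exc:
            log.entries.append(ChangeLogEntry(
                strain.clock(), idx, "fail", None, str(exc)))
    strain.commit()
    return strain, log


def _resolve_or_fail(db: Database, term: str, class_name: str) -> str:
    result = resolve(db, term, class_name)
    if not result.resolved:
        raise PgdbError(
            f"cannot resolve {term!r} to a unique {class_name} frame "
            f"({result.status})")
    return result.frame_id


def _apply_intervention(db: Database, iv: Intervention,
                        options: ImportOptions) -> tuple[Optional[str], str]:
    if iv.kind == "gene-deletion":
        gene = _resolve_or_fail(db, iv.payload["gene"], "Gene")
        deleted = db.delete_frame_and_dependents(gene)
        return gene, f"deleted {gene} and dependents: " + ", ".join(sorted(deleted))
    if iv.kind == "comment-append":
        # any object type may carry a comment, so resolve without class filter
        target = iv.payload["frame"]
        if target not in db.frames:
            hits = {resolve(db, target, cls).frame_id
                    for cls in ("Protein", "Gene", "Reaction", "Compound")}
            hits.discard(None)
            if len(hits) != 1:
                raise PgdbError(f"cannot resolve {target!r} to a unique frame")
            target = hits.pop()
        _append_comment(db, target, iv.payload["comment"])
        if options.author:
            db.add_credit(target, options.author,
                          ignore_duplicates=options.ignore_duplicates)
        return target, f"appended comment to {target}"
    if iv.kind == "add-regulation":
        reg = _resolve_or_fail(db, iv.payload["regulator"], "Protein")
        tgt = _resolve_or_fail(db, iv.payload["target"], "Gene")
        new_id = db.new_id("REG")
        db.create_frame(new_id, ["Regulation"])
        db.edit_slot(new_id, "REGULATOR", [reg])
        db.edit_slot(new_id, "REGULATED-ENTITY", [tgt])
        db.edit_slot(new_id, "MODE", [iv.payload.get("mode") or "unknown"])
        return new_id, f"created {new_id}: {reg} -> {tgt}"
    if iv.kind == "cassette-replacement":
        deleted_all: set[str] = set()
        genes = []
        for term in iv.payload["genes"]:
            gene = _resolve_or_fail(db, term, "Gene")
            genes.append(gene)
            deleted_all |= db.delete_frame_and_dependents(gene)
        marker = iv.payload.get("marker", "unnamed cassette")
        summary = next(iter(db.frames_of_class("Organism")), None)
        note = (f"Cassette replacement: genes {', '.join(genes)} replaced by "
                f"marker {marker}.")
        if summary is not None:
            _append_comment(db, summary.id, note)
        return genes[0] if genes else None, (
            note + " Deleted: " + ", ".join(sorted(deleted_all)))
    raise PgdbError(f"unknown intervention kind: {iv.kind}")


def load_interventions(path: Union[str, Path]) -> list[Intervention]:
    """Load an ordered interventions file (YAML or JSON): a list of mappings
    with a ``kind`` key; all other keys form the payload."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, list):
        raise PgdbError("interventions file must contain a list")
    out = []
    for i, entry in enumerate(data, start=1):
        if not isinstance(entry, dict) or "kind" not in entry:
            raise PgdbError(f"intervention {i}: expected a mapping with a 'kind'")
        payload = {k: v for k, v in entry.items() if k != "kind"}
        out.append(Intervention(kind=entry["kind"], payload=payload))
    return out
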