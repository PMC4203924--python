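"""Batch import pipeline: plan, preview, apply, log.

Five import types operate on a frame database: ``slot-data`` (write values
into slots), ``slot-value-annotation`` (attach metadata to individual slot
values), ``go-annotation`` (GO-term assignments with citation/evidence/
curator annotations, creating GO-Term frames on demand), ``delete-frames``
(cascading deletion), and ``create-regulation`` (new transcriptional
regulation frames with sequential IDs).

The lifecycle mirrors careful manual curation:

* ``plan_import`` resolves every identifier in the file to a frame ID
  (see :mod:`pgdbkit.id_resolution`) without touching the database;
* ``preview_plan`` applies the plan to a scratch copy and reports
  character-level edit scripts (equal/insert/delete spans) per frame, so a
  curator can spot data-entry errors that are technically valid imports;
* ``apply_plan`` runs inside an open transaction, applies each row
  independently (one row's failure never halts the others), appends curator
  credit to every frame actually modified, and returns a timestamped
  per-row change log;
* the caller then commits, or rolls back to the exact pre-import state.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

from .flatfile_io import GoTerm, ImportRow, normalize_go_id
from .frame_store import Database, PgdbError, TransactionError
from .id_resolution import BatchReport, resolve_batch

__all__ = [
    "IMPORT_TYPES",
    "ImportOptions",
    "PlanAction",
    "ImportPlan",
    "FrameDiff",
    "ChangeLogEntry",
    "ChangeLog",
    "render_frame",
    "plan_import",
    "preview_plan",
    "apply_plan",
    "import_go_annotations",
    "create_regulation_frames",
    "delete_frames_import",
]

IMPORT_TYPES = (
    "slot-data", "slot-value-annotation", "go-annotation",
    "delete-frames", "create-regulation",
)

#: Default object class used to resolve identifiers, per import type.
_RESOLVE_CLASS = {"go-annotation": "Protein"}


@dataclass
class ImportOptions:
    """User-facing import options.

    ``overwrite`` clears a slot (or annotation list) before the first new
    value from this import touches it; ``ignore_duplicates`` skips values
    exactly equal to an existing one without removing pre-existing
    duplicates.  The two combine: the slot is cleared first, then duplicates
    among the incoming rows themselves are ignored.  ``author`` credits a
    Person/Organization frame on every frame modified.
    """

    overwrite: bool = False
    ignore_duplicates: bool = False
    author: Optional[str] = None
    on_unresolved: str = "skip"  # or "abort"
    compat_search: bool = False


@dataclass
class PlanAction:
    row_index: int
    kind: str  # slot-edit | annotation-edit | go-annotation | delete | create-regulation | error
    target: Optional[str]  # resolved frame id, None for new-frame actions
    payload: dict = field(default_factory=dict)
    description: str = ""


@dataclass
class ImportPlan:
    type: str
    actions: list[PlanAction] = field(default_factory=list)
    skipped: list[tuple[int, str, str]] = field(default_factory=list)  # (row, term, status)
    reports: list[BatchReport] = field(default_factory=list)
    options: Optional[ImportOptions] = None

    @property
    def search_skipped(self) -> bool:
        return bool(self.reports) and all(r.search_skipped for r in self.reports)


@dataclass
class FrameDiff:
    """Character-level edit script between a frame's rendering before and
    after a plan.  An unchanged frame has an empty edit script; a deleted
    frame has empty ``after`` text."""

    frame_id: str
    before: str
    after: str
    edit_script: list[tuple[str, str]] = field(default_factory=list)

    def apply(self) -> str:
        """Replay the edit script on ``before``; must equal ``after``."""
        if not self.edit_script:
            return self.before
        return "".join(text for op, text in self.edit_script if op != "delete")


@dataclass
class ChangeLogEntry:
    timestamp: datetime
    row_index: int
    status: str  # success | fail
    frame: Optional[str]
    message: str


@dataclass
class ChangeLog:
    entries: list[ChangeLogEntry] = field(default_factory=list)
    skipped: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def n_success(self) -> int:
        return sum(1 for e in self.entries if e.status == "success")

    @property
    def n_fail(self) -> int:
        return sum(1 for e in self.entries if e.status == "fail")

    @property
    def exit_code(self) -> int:
        return 1 if self.n_fail else 0


def render_frame(frame) -> str:
    """Stable one-frame rendering used for previews: one line per slot value
    with its annotations indented beneath it."""
    lines = [f"UNIQUE-ID - {frame.id}"]
    lines.extend(f"TYPES - {cls}" for cls in frame.classes)
    for label, svs in frame.slots.items():
        for sv in svs:
            lines.append(f"{label} - {sv.value}")
            for ann_label, ann_values in sv.annotations.items():
                for ann in ann_values:
                    lines.append(f"    ^{ann_label} - {ann}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------

def plan_import(db: Database, rows: Sequence[ImportRow], import_type: str,
                options: Optional[ImportOptions] = None) -> ImportPlan:
    """Resolve a parsed import file into an executable plan; ``db`` is not
    modified.  Unresolvable identifiers are skipped or abort the batch per
    ``options.on_unresolved``."""
    options = options or ImportOptions()
    if import_type not in IMPORT_TYPES:
        raise PgdbError(f"unknown import type: {import_type}")
    plan = ImportPlan(type=import_type, options=options)
    if not rows:
        return plan
    builder = {
        "slot-data": _plan_slot_rows,
        "slot-value-annotation": _plan_slot_rows,
        "go-annotation": _plan_go_rows,
        "delete-frames": _plan_delete_rows,
        "create-regulation": _plan_regulation_rows,
    }[import_type]
    builder(db, rows, plan, options)
    return plan


def _resolve_column(db: Database, rows: Sequence[ImportRow], plan: ImportPlan,
                    options: ImportOptions, column: str,
                    class_of_row) -> dict[int, str]:
    """Resolve one identifier column, batched per object class.  Returns
    row_index -> frame id; unresolvable rows land in plan.skipped."""
    by_class: dict[str, list[ImportRow]] = {}
    for row in rows:
        by_class.setdefault(class_of_row(row), []).append(row)
    resolved: dict[int, str] = {}
    for class_name, class_rows in by_class.items():
        terms = [r[column] for r in class_rows]
        mapping, report = resolve_batch(
            db, terms, class_name,
            on_fail=options.on_unresolved, compat=options.compat_search)
        plan.reports.append(report)
        statuses = {res.query: res.status for res in report.results}
        for row in class_rows:
            term = row[column]
            if term in mapping:
                resolved[row.row_index] = mapping[term]
            else:
                plan.skipped.append((row.row_index, term, statuses.get(term, "none")))
    return resolved


def _plan_slot_rows(db, rows, plan, options):
    resolved = _resolve_column(db, rows, plan, options, "identifier",
                               lambda r: r["object-class"])
    annotated = plan.type == "slot-value-annotation"
    for row in rows:
        if row.row_index not in resolved:
            continue
        target = resolved[row.row_index]
        if annotated:
            plan.actions.append(PlanAction(
                row.row_index, "annotation-edit", target,
                payload={"slot": row["slot"], "value": row["value"],
                         "ann_label": row["annotation-label"],
                         "ann_value": row["annotation-value"]},
                description=(f"{target}: annotate {row['slot']}={row['value']} "
                             f"with {row['annotation-label']}={row['annotation-value']}")))
        else:
            plan.actions.append(PlanAction(
                row.row_index, "slot-edit", target,
                payload={"slot": row["slot"], "value": row["value"]},
                description=f"{target}: {row['slot']} += {row['value']}"))


def _plan_go_rows(db, rows, plan, options):
    resolved = _resolve_column(db, rows, plan, options, "identifier",
                               lambda r: _RESOLVE_CLASS["go-annotation"])
    for row in rows:
        if row.row_index not in resolved:
            continue
        target = resolved[row.row_index]
        plan.actions.append(PlanAction(
            row.row_index, "go-annotation", target,
            payload={"go_id": row["go-id"], "evidence": row["evidence-code"],
                     "citation": row["citation"], "curator": row["curator"]},
            description=f"{target}: GO-TERMS += {row['go-id']} ({row['evidence-code']})"))


def _plan_delete_rows(db, rows, plan, options):
    resolved = _resolve_column(db, rows, plan, options, "identifier",
                               lambda r: r["object-class"])
    for row in rows:
        if row.row_index not in resolved:
            continue
        target = resolved[row.row_index]
        plan.actions.append(PlanAction(
            row.row_index, "delete", target,
            description=f"delete {target} and dependents"))


def _plan_regulation_rows(db, rows, plan, options):
    # Regulation rows create new frames; an unresolvable endpoint is recorded
    # as a failing action (not a plan-time skip) so the change log shows it.
    from .id_resolution import resolve

    for row in rows:
        reg = resolve(db, row["regulator-identifier"], "Protein",
                      compat=options.compat_search)
        tgt = resolve(db, row["target-identifier"], "Gene",
                      compat=options.compat_search)
        if not reg.resolved or not tgt.resolved:
            bad = []
            if not reg.resolved:
                bad.append(f"regulator {row['regulator-identifier']!r} ({reg.status})")
            if not tgt.resolved:
                bad.append(f"target {row['target-identifier']!r} ({tgt.status})")
            plan.actions.append(PlanAction(
                row.row_index, "error", None,
                payload={"message": "unresolvable " + " and ".join(bad)},
                description="unresolvable regulation endpoints"))
            continue
        plan.actions.append(PlanAction(
            row.row_index, "create-regulation", None,
            payload={"regulator": reg.frame_id, "target": tgt.frame_id,
                     "mode": row["mode"]},
            description=f"new Regulation: {reg.frame_id} -> {tgt.frame_id}"))


# ---------------------------------------------------------------------------
# Preview
# ---------------------------------------------------------------------------

def _edit_script(before: str, after: str) -> list[tuple[str, str]]:
    if before == after:
        return []
    script: list[tuple[str, str]] = []
    sm = difflib.SequenceMatcher(None, before, after, autojunk=False)
    for op, i1, i2, j1, j2 in sm.get_opcodes():
        if op == "equal":
            script.append(("equal", before[i1:i2]))
        elif op == "delete":
            script.append(("delete", before[i1:i2]))
        elif op == "insert":
            script.append(("insert", after[j1:j2]))
        else:  # replace
            script.append(("delete", before[i1:i2]))
            script.append(("insert", after[j1:j2]))
    return script


def preview_plan(db: Database, plan: ImportPlan,
                 go_ref: Optional[dict[str, GoTerm]] = None) -> list[FrameDiff]:
    """Dry-run the plan on a scratch copy and report per-frame edit scripts;
    ``db`` itself is untouched.  Frames targeted but unchanged get a diff
    with an empty edit script; frames deleted get empty ``after`` text."""
    scratch = db.copy()
    scratch.begin()
    apply_plan(scratch, plan, go_ref=go_ref)
    touched = {a.target for a in plan.actions if a.target is not None}
    touched.update(set(db.frames) ^ set(scratch.frames))
    for fid in set(db.frames) & set(scratch.frames):
        if fid not in touched:
            if render_frame(db.frames[fid]) != render_frame(scratch.frames[fid]):
                touched.add(fid)
    diffs = []
    for fid in sorted(touched):
        before = render_frame(db.frames[fid]) if fid in db.frames else ""
        after = render_frame(scratch.frames[fid]) if fid in scratch.frames else ""
        diffs.append(FrameDiff(fid, before, after, _edit_script(before, after)))
    return diffs


# ---------------------------------------------------------------------------
# Apply
# ---------------------------------------------------------------------------

def apply_plan(db: Database, plan: ImportPlan,
               options: Optional[ImportOptions] = None,
               go_ref: Optional[dict[str, GoTerm]] = None) -> ChangeLog:
    """Execute a plan inside an open transaction.

    Each action is applied independently: a failing row is logged and does
    not halt the rest.  With ``options.author`` set, every frame modified by
    a successful action gains a CREDITS entry (once per run).  The database
    is left in a modified-but-unsaved state; commit or roll back afterwards.
    """
    if not db.in_transaction:
        raise TransactionError(
            "no open transaction: call begin() before applying an import")
    options = options or plan.options or ImportOptions()
    log = ChangeLog(skipped=list(plan.skipped))
    state: dict = {"cleared": set(), "credited": set()}
    for action in plan.actions:
        try:
            modified, message = _apply_action(db, action, options, state, go_ref)
            for fid in modified:
                if options.author and fid not in state["credited"]:
                    db.add_credit(fid, options.author,
                                  ignore_duplicates=options.ignore_duplicates)
                    state["credited"].add(fid)
            log.entries.append(ChangeLogEntry(
                db.clock(), action.row_index, "success",
                modified[0] if modified else action.target, message))
        except PgdbError as exc:
            log.entries.append(ChangeLogEntry(
                db.clock(), action.row_index, "fail", action.target, str(exc)))
    return log


def _slot_mode(options: ImportOptions) -> str:
    return "append-ignore-duplicates" if options.ignore_duplicates else "append"


def _apply_action(db: Database, action: PlanAction, options: ImportOptions,
                  state: dict, go_ref) -> tuple[list[str], str]:
    kind = action.kind
    if kind == "error":
        raise PgdbError(action.payload["message"])
    if kind == "delete":
        deleted = db.delete_frame_and_dependents(action.target)
        return [], "deleted: " + ", ".join(sorted(deleted))
    if kind == "create-regulation":
        new_id = db.new_id("REG")
        db.create_frame(new_id, ["Regulation"])
        db.edit_slot(new_id, "REGULATOR", [action.payload["regulator"]])
        db.edit_slot(new_id, "REGULATED-ENTITY", [action.payload["target"]])
        mode = action.payload.get("mode") or "unknown"
        db.edit_slot(new_id, "MODE", [mode])
        return [new_id], (f"created {new_id}: {action.payload['regulator']} "
                          f"-> {action.payload['target']} ({mode})")

    frame = db.get(action.target)  # raises UnknownFrameError if deleted mid-run
    before = render_frame(frame)

    if kind == "slot-edit":
        slot = action.payload["slot"].upper()
        key = (action.target, slot)
        if options.overwrite and key not in state["cleared"]:
            db.edit_slot(action.target, slot, [action.payload["value"]], "overwrite")
            state["cleared"].add(key)
        else:
            db.edit_slot(action.target, slot, [action.payload["value"]],
                         _slot_mode(options))
    elif kind == "annotation-edit":
        slot = action.payload["slot"].upper()
        value = action.payload["value"]
        ann_label = action.payload["ann_label"].upper()
        key = (action.target, slot, value, ann_label)
        if options.overwrite and key not in state["cleared"]:
            db.annotate_value(action.target, slot, value, ann_label,
                              [action.payload["ann_value"]], "overwrite")
            state["cleared"].add(key)
        else:
            db.annotate_value(action.target, slot, value, ann_label,
                              [action.payload["ann_value"]], _slot_mode(options))
    elif kind == "go-annotation":
        extra = _apply_go_annotation(db, action, options, state, go_ref)
        after = render_frame(db.get(action.target))
        changed = after != before
        if changed:
            # stamp only real modifications so repeat imports stay no-ops
            db.annotate_value(action.target, "GO-TERMS",
                              action.payload["_go_id_norm"], "TIMESTAMP",
                              [db.clock().isoformat()], "append")
        msg = action.description + ("" if changed else " (no-op, already present)")
        if extra:
            msg += f"; created GO-Term frame {extra}"
        return ([action.target] if changed else []), msg
    else:
        raise PgdbError(f"unknown action kind: {kind}")

    after = render_frame(db.get(action.target))
    changed = after != before
    msg = action.description + ("" if changed else " (no-op, already present)")
    return ([action.target] if changed else []), msg


def _apply_go_annotation(db: Database, action: PlanAction,
                         options: ImportOptions, state: dict,
                         go_ref) -> Optional[str]:
    """Returns the id of a newly created GO-Term frame, if any."""
    if go_ref is None:
        raise PgdbError("GO reference not loaded")
    go_id = normalize_go_id(action.payload["go_id"])
    action.payload["_go_id_norm"] = go_id
    if go_id not in go_ref:
        raise PgdbError(f"GO id {go_id} absent from the GO reference")
    created = None
    if go_id not in db.frames:
        term = go_ref[go_id]
        db.create_frame(go_id, ["GO-Term"])
        db.edit_slot(go_id, "COMMON-NAME", [term.name])
        if term.namespace:
            db.edit_slot(go_id, "NAMESPACE", [term.namespace])
        if term.definition:
            db.edit_slot(go_id, "DEFINITION", [term.definition])
        created = go_id
    target, slot = action.target, "GO-TERMS"
    key = (target, slot)
    if options.overwrite and key not in state["cleared"]:
        db.edit_slot(target, slot, [go_id], "overwrite")
        state["cleared"].add(key)
    else:
        db.edit_slot(target, slot, [go_id], "append-ignore-duplicates")
    ann_mode = _slot_mode(options)
    for label, field_name in (("CITATIONS", "citation"),
                              ("EVIDENCE", "evidence"),
                              ("CURATOR", "curator")):
        value = action.payload.get(field_name, "")
        if value:
            db.annotate_value(target, slot, go_id, label, [value], ann_mode)
    return created


# ---------------------------------------------------------------------------
# Convenience wrappers (plan + apply, auto-begin)
# ---------------------------------------------------------------------------

def _run_import(db: Database, rows, import_type, options, go_ref=None) -> ChangeLog:
    options = options or ImportOptions()
    plan = plan_import(db, rows, import_type, options)
    if not db.in_transaction:
        db.begin()
    return apply_plan(db, plan, options, go_ref=go_ref)


def import_go_annotations(db: Database, rows: Sequence[ImportRow],
                          go_ref: dict[str, GoTerm],
                          options: Optional[ImportOptions] = None) -> ChangeLog:
    """Import GO-term annotations; creates each distinct GO-Term frame at
    most once regardless of how many rows carry it.  Opens a transaction if
    none is open; the database is left modified-but-unsaved."""
    return _run_import(db, rows, "go-annotation", options, go_ref=go_ref)


def create_regulation_frames(db: Database, rows: Sequence[ImportRow],
                             options: Optional[ImportOptions] = None) -> ChangeLog:
    """Create one Regulation frame per row with sequential REG-nnnn ids.
    No duplicate-interaction detection: listing an interaction twice creates
    two frames."""
    return _run_import(db, rows, "create-regulation", options)


def delete_frames_import(db: Database, rows: Sequence[ImportRow],
                         options: Optional[ImportOptions] = None) -> ChangeLog:
    """Cascade-delete each resolved identifier; the log message of each row
    lists the full deleted set."""
    return _run_import(db, rows, "delete-frames", options)
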