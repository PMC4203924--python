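"""In-memory frame representation system for pathway/genome databases.

A pathway/genome database (PGDB) stores everything known about one organism as
*frames*: one record per biological entity (gene, protein, compound, pathway)
or relationship (reaction, regulation).  A frame has a unique *frame ID*, one
or more object classes drawn from a class taxonomy, and an ordered set of
*slots*, each holding one or more values.  Any individual slot value can carry
*slot-value annotations* — metadata such as citations, evidence codes, and
curator identity attached to that one value rather than to the whole slot.

This module provides the store itself: the class taxonomy, frame CRUD with
the three write modes used by batch imports (overwrite / append /
append-ignore-duplicates), name-slot indexing for synonym search, curator
credit stamping, cascading deletion over the gene-protein-reaction-regulation
dependency graph, single-level transactions, and referential-integrity
checking.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Iterator, Optional, Sequence

__all__ = [
    "PgdbError",
    "DuplicateFrameIdError",
    "UnknownFrameError",
    "UnknownClassError",
    "InvalidFrameIdError",
    "ValueNotInSlotError",
    "AuthorClassError",
    "TransactionError",
    "ObjectClass",
    "ClassTaxonomy",
    "default_taxonomy",
    "SlotValue",
    "Frame",
    "RevisionRecord",
    "Database",
    "normalize_name",
    "DEFAULT_NAME_SLOTS",
    "REFERENCE_SLOTS",
    "EDIT_MODES",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PgdbError(Exception):
    """Base class for all errors raised by the toolkit."""


class DuplicateFrameIdError(PgdbError):
    pass


class UnknownFrameError(PgdbError):
    pass


class UnknownClassError(PgdbError):
    pass


class InvalidFrameIdError(PgdbError):
    pass


class ValueNotInSlotError(PgdbError):
    pass


class AuthorClassError(PgdbError):
    """Credit author is not a Person or Organization frame."""


class TransactionError(PgdbError):
    """Nested begin, or rollback/commit without an open transaction."""


# ---------------------------------------------------------------------------
# Class taxonomy
# ---------------------------------------------------------------------------

#: Slots whose values serve as alternate identifiers for synonym search.
DEFAULT_NAME_SLOTS: tuple[str, ...] = (
    "ACCESSION", "COMMON-NAME", "SYNONYMS", "DBLINKS",
)

#: Slots whose values are frame references (checked by integrity_check and
#: scrubbed from survivors after a cascade deletion).
REFERENCE_SLOTS: frozenset[str] = frozenset({
    "GENE", "PRODUCT", "COMPONENTS",
    "ENZYME", "REACTION",
    "LEFT", "RIGHT",
    "REACTION-LIST", "IN-PATHWAY",
    "REGULATOR", "REGULATED-ENTITY",
    "REFERENCED-FRAME",
    "GO-TERMS", "CREDITS",
})

EDIT_MODES = ("overwrite", "append", "append-ignore-duplicates")


@dataclass
class ObjectClass:
    """A node in the class taxonomy.

    ``name_slots`` lists the slots whose values act as alternate identifiers
    for frames of this class; it can be customized per class.
    """

    name: str
    parent: Optional[str] = None
    name_slots: tuple[str, ...] = DEFAULT_NAME_SLOTS


class ClassTaxonomy:
    """A forest of object classes with subclass queries."""

    def __init__(self) -> None:
        self.classes: dict[str, ObjectClass] = {}

    def add_class(self, name: str, parent: Optional[str] = None,
                  name_slots: Optional[Sequence[str]] = None) -> ObjectClass:
        if parent is not None and parent not in self.classes:
            raise UnknownClassError(f"unknown parent class: {parent}")
        if name in self.classes:
            raise PgdbError(f"class already defined: {name}")
        cls = ObjectClass(
            name=name, parent=parent,
            name_slots=tuple(name_slots) if name_slots else DEFAULT_NAME_SLOTS,
        )
        self.classes[name] = cls
        return cls

    def __contains__(self, name: str) -> bool:
        return name in self.classes

    def ancestors(self, name: str) -> list[str]:
        """The class itself followed by its ancestors, root last."""
        out = []
        cur: Optional[str] = name
        while cur is not None:
            if cur in out:  # defensive: taxonomy must be a forest
                raise PgdbError(f"class cycle at {cur}")
            out.append(cur)
            cur = self.classes[cur].parent if cur in self.classes else None
        return out

    def is_subclass(self, name: str, ancestor: str) -> bool:
        return ancestor in self.ancestors(name)

    def name_slots(self, name: str) -> tuple[str, ...]:
        if name in self.classes:
            return self.classes[name].name_slots
        return DEFAULT_NAME_SLOTS


#: (class, parent) pairs every database starts with.
BUILTIN_CLASSES: tuple[tuple[str, Optional[str]], ...] = (
    ("Gene", None),
    ("Protein", None),
    ("Polypeptide", "Protein"),
    ("Protein-Complex", "Protein"),
    ("Enzymatic-Reaction", None),
    ("Reaction", None),
    ("Compound", None),
    ("Pathway", None),
    ("Regulation", None),
    ("GO-Term", None),
    ("Person", None),
    ("Organization", None),
    ("History-Note", None),
    ("Organism", None),
)


def default_taxonomy() -> ClassTaxonomy:
    tax = ClassTaxonomy()
    for name, parent in BUILTIN_CLASSES:
        tax.add_class(name, parent)
    return tax


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

_FRAME_ID_RE = re.compile(r"^\S+$")


def _check_frame_id(frame_id: str) -> str:
    if not frame_id or not _FRAME_ID_RE.match(frame_id) or "," in frame_id:
        raise InvalidFrameIdError(
            f"frame IDs must be non-empty with no whitespace or commas: {frame_id!r}"
        )
    return frame_id


def normalize_name(value: str) -> str:
    """Case-insensitive normal form used by the name index."""
    return value.strip().lower()


@dataclass
class SlotValue:
    """One value in a slot, plus its per-value annotations.

    Annotations are an ordered map of label -> ordered list of scalars, e.g.
    ``{"CITATIONS": ["PMID:12345"], "EVIDENCE": ["EV-EXP-IDA"]}`` attached to
    a single GO-term assignment.
    """

    value: str
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def copy(self) -> "SlotValue":
        return SlotValue(self.value, {k: list(v) for k, v in self.annotations.items()})


@dataclass
class RevisionRecord:
    timestamp: datetime
    author: Optional[str]
    action: str


@dataclass
class Frame:
    """A database record: id, classes, ordered slots, revision history."""

    id: str
    classes: list[str]
    slots: dict[str, list[SlotValue]] = field(default_factory=dict)
    revisions: list[RevisionRecord] = field(default_factory=list)

    def slot_values(self, label: str) -> list[str]:
        return [sv.value for sv in self.slots.get(label.upper(), [])]

    def first_value(self, label: str) -> Optional[str]:
        vals = self.slot_values(label)
        return vals[0] if vals else None

    def get_slot_value(self, label: str, value: str) -> Optional[SlotValue]:
        for sv in self.slots.get(label.upper(), []):
            if sv.value == value:
                return sv
        return None


# ---------------------------------------------------------------------------
# Database
# ---------------------------------------------------------------------------

def _utc_now() -> datetime:
    return datetime.now(timezone.utc)


class Database:
    """A named collection of frames with taxonomy, name index, and transactions.

    The clock is injectable so that credit/revision timestamps are
    deterministic under test.
    """

    def __init__(self, orgid: str = "SYN", name: str = "Synthetic PGDB",
                 version: str = "1.0",
                 taxonomy: Optional[ClassTaxonomy] = None,
                 clock: Optional[Callable[[], datetime]] = None) -> None:
        self.orgid = orgid
        self.name = name
        self.version = version
        self.taxonomy = taxonomy or default_taxonomy()
        self.frames: dict[str, Frame] = {}
        self.clock: Callable[[], datetime] = clock or _utc_now
        self.saved = True
        # name index: normalized name-slot value -> set of frame ids
        self._name_index: dict[str, set[str]] = {}
        # reverse: frame id -> the normalized values it is indexed under
        self._indexed: dict[str, set[str]] = {}
        self._seq: dict[str, int] = {}
        self._snapshot: Optional[dict] = None

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frames)

    def __contains__(self, frame_id: str) -> bool:
        return frame_id in self.frames

    def get(self, frame_id: str) -> Frame:
        try:
            return self.frames[frame_id]
        except KeyError:
            raise UnknownFrameError(f"no frame with id {frame_id!r}") from None

    def is_instance(self, frame: Frame, class_name: str) -> bool:
        return any(self.taxonomy.is_subclass(c, class_name) for c in frame.classes)

    def frames_of_class(self, class_name: str) -> Iterator[Frame]:
        for frame in self.frames.values():
            if self.is_instance(frame, class_name):
                yield frame

    def name_slots_for(self, frame: Frame) -> tuple[str, ...]:
        labels: list[str] = []
        for cls in frame.classes:
            for anc in self.taxonomy.ancestors(cls):
                for s in self.taxonomy.name_slots(anc):
                    if s not in labels:
                        labels.append(s)
        return tuple(labels)

    @property
    def name_index(self) -> dict[str, set[str]]:
        return self._name_index

    def new_id(self, prefix: str) -> str:
        """Next sequential frame ID for a prefix, e.g. REG-0001, REG-0002."""
        n = self._seq.get(prefix, 0)
        while True:
            n += 1
            candidate = f"{prefix}-{n:04d}"
            if candidate not in self.frames:
                self._seq[prefix] = n
                return candidate

    # -- name index maintenance --------------------------------------------

    def _reindex(self, frame: Frame) -> None:
        new_keys = set()
        for label in self.name_slots_for(frame):
            for value in frame.slot_values(label):
                if value:
                    new_keys.add(normalize_name(value))
        old_keys = self._indexed.get(frame.id, set())
        for key in old_keys - new_keys:
            ids = self._name_index.get(key)
            if ids is not None:
                ids.discard(frame.id)
                if not ids:
                    del self._name_index[key]
        for key in new_keys - old_keys:
            self._name_index.setdefault(key, set()).add(frame.id)
        if new_keys:
            self._indexed[frame.id] = new_keys
        else:
            self._indexed.pop(frame.id, None)

    def _drop_from_index(self, frame_id: str) -> None:
        for key in self._indexed.pop(frame_id, set()):
            ids = self._name_index.get(key)
            if ids is not None:
                ids.discard(frame_id)
                if not ids:
                    del self._name_index[key]

    # -- frame creation and editing ----------------------------------------

    def create_frame(self, frame_id: str, classes: Sequence[str]) -> Frame:
        _check_frame_id(frame_id)
        if frame_id in self.frames:
            raise DuplicateFrameIdError(f"duplicate frame id: {frame_id}")
        if not classes:
            raise UnknownClassError("a frame needs at least one class")
        for cls in classes:
            if cls not in self.taxonomy:
                raise UnknownClassError(f"unknown class: {cls}")
        frame = Frame(id=frame_id, classes=list(classes))
        frame.revisions.append(
            RevisionRecord(self.clock(), None, "created"))
        self.frames[frame_id] = frame
        self.saved = False
        return frame

    def edit_slot(self, frame_id: str, slot: str, values: Sequence[str],
                  mode: str = "overwrite") -> Frame:
        """Write values into a slot.

        overwrite replaces the slot's entire contents (existing per-value
        annotations are dropped with their values); append adds after the
        existing values; append-ignore-duplicates skips a new value exactly
        equal to one already in the slot but never removes pre-existing
        duplicates.
        """
        if mode not in EDIT_MODES:
            raise PgdbError(f"unknown edit mode: {mode}")
        frame = self.get(frame_id)
        slot = slot.upper()
        if mode == "overwrite":
            new = [SlotValue(str(v)) for v in values]
        else:
            new = [sv for sv in frame.slots.get(slot, [])]
            for v in values:
                v = str(v)
                if mode == "append-ignore-duplicates" and any(sv.value == v for sv in new):
                    continue
                new.append(SlotValue(v))
        if new:
            frame.slots[slot] = new
        else:
            frame.slots.pop(slot, None)
        if slot in self.name_slots_for(frame):
            self._reindex(frame)
        self.saved = False
        return frame

    def annotate_value(self, frame_id: str, slot: str, value: str,
                       ann_label: str, ann_values: Sequence[str],
                       mode: str = "append") -> Frame:
        """Attach annotation scalars to one specific value within a slot."""
        if mode not in EDIT_MODES:
            raise PgdbError(f"unknown edit mode: {mode}")
        frame = self.get(frame_id)
        sv = frame.get_slot_value(slot, value)
        if sv is None:
            raise ValueNotInSlotError(
                f"frame {frame_id}: slot {slot.upper()} has no value {value!r}")
        label = ann_label.upper()
        if mode == "overwrite":
            new = [str(v) for v in ann_values]
        else:
            new = list(sv.annotations.get(label, []))
            for v in ann_values:
                v = str(v)
                if mode == "append-ignore-duplicates" and v in new:
                    continue
                new.append(v)
        if new:
            sv.annotations[label] = new
        else:
            sv.annotations.pop(label, None)
        self.saved = False
        return frame

    def add_credit(self, frame_id: str, author: str,
                   timestamp: Optional[datetime] = None,
                   ignore_duplicates: bool = False) -> Frame:
        """Append a curator or organization to the frame's CREDITS slot.

        Records a timestamped revision on the frame.  With
        ``ignore_duplicates`` an author already credited is not re-appended
        (no revision is recorded either), which keeps repeat imports no-ops.
        """
        frame = self.get(frame_id)
        author_frame = self.get(author)
        if not (self.is_instance(author_frame, "Person")
                or self.is_instance(author_frame, "Organization")):
            raise AuthorClassError(
                f"credit author {author} is not a Person or Organization")
        if ignore_duplicates and author in frame.slot_values("CREDITS"):
            return frame
        self.edit_slot(frame_id, "CREDITS", [author], mode="append")
        frame.revisions.append(RevisionRecord(
            timestamp or self.clock(), author, "credited"))
        return frame

    # -- cascading deletion -------------------------------------------------

    def delete_frame_and_dependents(self, frame_id: str) -> set[str]:
        """Delete a frame and every frame that depends on it.

        Cascade rules, applied to a fixed point:

        * a protein is deleted once every gene coding for it is deleted
          (a product still encoded by a surviving gene is kept);
        * an enzymatic-reaction is deleted when its enzyme or its reaction is;
        * a catalyzed reaction is deleted when all of its enzymatic-reactions
          are (an uncatalyzed/spontaneous reaction is never cascaded);
        * a regulation frame is deleted when its regulator or its regulated
          entity is — this covers transcription-factor deletion;
        * a history note is deleted with the frame it refers to.

        Pathways are never cascade-deleted: deleted reactions are removed
        from pathway reaction lists and the removal is recorded as a revision
        on the pathway.  After removal, all remaining references to deleted
        frames are scrubbed so the database stays referentially intact.
        """
        if frame_id not in self.frames:
            raise UnknownFrameError(f"no frame with id {frame_id!r}")
        deleted: set[str] = {frame_id}
        changed = True
        while changed:
            changed = False
            for fid, frame in self.frames.items():
                if fid in deleted:
                    continue
                if self._cascades(frame, deleted):
                    deleted.add(fid)
                    changed = True
        for fid in deleted:
            self._drop_from_index(fid)
            del self.frames[fid]
        self._scrub_references(deleted)
        self.saved = False
        return deleted

    def _cascades(self, frame: Frame, deleted: set[str]) -> bool:
        if self.is_instance(frame, "Protein"):
            genes = frame.slot_values("GENE")
            if genes and all(g in deleted for g in genes):
                return True
        if self.is_instance(frame, "Enzymatic-Reaction"):
            if any(v in deleted for v in frame.slot_values("ENZYME")):
                return True
            if any(v in deleted for v in frame.slot_values("REACTION")):
                return True
        if self.is_instance(frame, "Reaction"):
            catalysts = [
                f.id for f in self.frames.values()
                if self.is_instance(f, "Enzymatic-Reaction")
                and frame.id in f.slot_values("REACTION")
            ]
            if catalysts and all(c in deleted for c in catalysts):
                return True
        if self.is_instance(frame, "Regulation"):
            if any(v in deleted for v in frame.slot_values("REGULATOR")):
                return True
            if any(v in deleted for v in frame.slot_values("REGULATED-ENTITY")):
                return True
        if self.is_instance(frame, "History-Note"):
            if any(v in deleted for v in frame.slot_values("REFERENCED-FRAME")):
                return True
        return False

    def _scrub_references(self, deleted: set[str]) -> None:
        for frame in self.frames.values():
            for slot in list(frame.slots):
                if slot not in REFERENCE_SLOTS:
                    continue
                kept = [sv for sv in frame.slots[slot] if sv.value not in deleted]
                if len(kept) == len(frame.slots[slot]):
                    continue
                removed = [sv.value for sv in frame.slots[slot]
                           if sv.value in deleted]
                if kept:
                    frame.slots[slot] = kept
                else:
                    del frame.slots[slot]
                if slot == "REACTION-LIST" and self.is_instance(frame, "Pathway"):
                    frame.revisions.append(RevisionRecord(
                        self.clock(), None,
                        "removed deleted reactions: " + ", ".join(removed)))
                if slot in self.name_slots_for(frame):
                    self._reindex(frame)

    # -- transactions --------------------------------------------------------

    @property
    def in_transaction(self) -> bool:
        return self._snapshot is not None

    def begin(self) -> None:
        """Open a (single-level) transaction by snapshotting the full state."""
        if self._snapshot is not None:
            raise TransactionError("nested-transaction: begin inside begin")
        self._snapshot = {
            "frames": copy.deepcopy(self.frames),
            "name_index": copy.deepcopy(self._name_index),
            "indexed": copy.deepcopy(self._indexed),
            "seq": dict(self._seq),
            "meta": (self.orgid, self.name, self.version, self.saved),
        }

    def rollback(self) -> None:
        """Undo every change since begin; the restored state serializes
        identically to the pre-begin state."""
        if self._snapshot is None:
            raise TransactionError("rollback without begin")
        snap = self._snapshot
        self.frames = snap["frames"]
        self._name_index = snap["name_index"]
        self._indexed = snap["indexed"]
        self._seq = snap["seq"]
        self.orgid, self.name, self.version, self.saved = snap["meta"]
        self._snapshot = None

    def commit(self) -> None:
        if self._snapshot is None:
            raise TransactionError("commit without begin")
        self._snapshot = None
        self.saved = True

    # -- integrity ----------------------------------------------------------

    def integrity_check(self) -> list[str]:
        """Scan for dangling frame references and name-index inconsistencies.

        Returns a list of human-readable violations; an intact database
        returns an empty list.
        """
        violations: list[str] = []
        for fid, frame in self.frames.items():
            if fid != frame.id:
                violations.append(f"frames map key {fid!r} != frame id {frame.id!r}")
            for cls in frame.classes:
                if cls not in self.taxonomy:
                    violations.append(f"frame {fid}: unknown class {cls}")
            for slot, svs in frame.slots.items():
                if slot not in REFERENCE_SLOTS:
                    continue
                for sv in svs:
                    if sv.value not in self.frames:
                        violations.append(
                            f"frame {fid}: slot {slot} has dangling reference "
                            f"{sv.value!r}")
        expected: dict[str, set[str]] = {}
        for frame in self.frames.values():
            for label in self.name_slots_for(frame):
                for value in frame.slot_values(label):
                    if value:
                        expected.setdefault(normalize_name(value), set()).add(frame.id)
        if expected != self._name_index:
            for key in set(expected) ^ set(self._name_index):
                violations.append(f"name index out of sync for {key!r}")
            for key in set(expected) & set(self._name_index):
                if expected[key] != self._name_index[key]:
                    violations.append(f"name index out of sync for {key!r}")
        return violations

    # -- copying -------------------------------------------------------------

    def copy(self) -> "Database":
        """An independent deep copy (shares nothing mutable with the source)."""
        new = Database(self.orgid, self.name, self.version,
                       taxonomy=copy.deepcopy(self.taxonomy),
                       clock=copy.deepcopy(self.clock))
        new.frames = copy.deepcopy(self.frames)
        new._name_index = copy.deepcopy(self._name_index)
        new._indexed = copy.deepcopy(self._indexed)
        new._seq = dict(self._seq)
        new.saved = self.saved
        return new
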