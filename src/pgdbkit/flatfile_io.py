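"""Readers and writers for the toolkit's on-disk formats.

Four families of files:

* PGDB content as attribute-value flat files (the de-facto convention for
  frame databases): one record per frame, ``UNIQUE-ID``/``TYPES`` lines,
  ``<LABEL> - <value>`` slot lines, ``^<LABEL> - <value>`` lines attaching an
  annotation to the immediately preceding slot value, ``/``-prefixed
  continuation lines for multi-line text, records separated by ``//``.
* Comma-separated import files, one column dialect per import type.
* A GO-term reference (OBO 1.2, parsed with obonet, or a 4-column TSV).
* Tab-separated change logs and migration reports.

The attribute-value writer and reader are exact inverses on canonical
serialization: ``read(write(db))`` renders identically to ``db``.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .frame_store import (
    Database,
    Frame,
    PgdbError,
    SlotValue,
)

__all__ = [
    "ParseError",
    "ImportFileError",
    "MalformedGoIdError",
    "ImportRow",
    "GoTerm",
    "IMPORT_COLUMNS",
    "render_record",
    "render_database",
    "read_attr_value",
    "write_attr_value",
    "read_database_dir",
    "write_database_dir",
    "read_import_csv",
    "read_go_reference",
    "normalize_go_id",
    "write_change_log",
    "write_migration_report",
]

PathLike = Union[str, Path]


class ParseError(PgdbError):
    """Malformed attribute-value file; message carries the line number."""


class ImportFileError(PgdbError):
    """Malformed CSV import file (missing column, bad arity, empty file)."""


class MalformedGoIdError(PgdbError):
    pass


# ---------------------------------------------------------------------------
# Attribute-value flat files
# ---------------------------------------------------------------------------

_RECORD_SEP = "//"
_DB_FILE = "frames.dat"


def _emit_value(label: str, sv: SlotValue, prefix: str = "") -> list[str]:
    lines = str(sv.value).split("\n")
    out = [f"{prefix}{label} - {lines[0]}"]
    out.extend(f"/{cont}" for cont in lines[1:])
    for ann_label, ann_values in sv.annotations.items():
        for ann in ann_values:
            ann_lines = str(ann).split("\n")
            out.append(f"^{ann_label} - {ann_lines[0]}")
            out.extend(f"/{cont}" for cont in ann_lines[1:])
    return out


def render_record(frame: Frame) -> str:
    """Canonical attribute-value text of one frame (no trailing separator)."""
    lines = [f"UNIQUE-ID - {frame.id}"]
    lines.extend(f"TYPES - {cls}" for cls in frame.classes)
    for label, svs in frame.slots.items():
        for sv in svs:
            lines.extend(_emit_value(label, sv))
    return "\n".join(lines)


def render_database(db: Database) -> str:
    """Canonical serialization of a whole database, header comments included.

    Frames and slots appear in insertion order, which makes the rendering
    deterministic and usable for byte-identity checks (round trips,
    transaction rollback).
    """
    out = [
        f"# ORGID: {db.orgid}",
        f"# NAME: {db.name}",
        f"# VERSION: {db.version}",
    ]
    for frame in db.frames.values():
        out.append(render_record(frame))
        out.append(_RECORD_SEP)
    return "\n".join(out) + "\n"


def write_attr_value(db: Database, path: PathLike) -> None:
    Path(path).write_text(render_database(db), encoding="utf-8")


_META_RE = re.compile(r"^#\s*(ORGID|NAME|VERSION):\s*(.*)$")
_SLOT_RE = re.compile(r"^([^\s/^#][^ ]*) - (.*)$", re.DOTALL)


def read_attr_value(path_or_text: PathLike, *, text: Optional[str] = None) -> Database:
    """Parse an attribute-value flat file into a fresh Database.

    Unknown class tokens are registered into the taxonomy so that files from
    databases with extended taxonomies load cleanly.  Raises ParseError (with
    a 1-based line number) for records missing UNIQUE-ID or TYPES, annotation
    lines with no preceding slot value, and unparseable lines.
    """
    if text is None:
        text = Path(path_or_text).read_text(encoding="utf-8")
    db = Database()
    record_lines: list[tuple[int, str]] = []

    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.rstrip("\r")
        if line.startswith("#"):
            m = _META_RE.match(line)
            if m:
                key, value = m.group(1), m.group(2)
                if key == "ORGID":
                    db.orgid = value
                elif key == "NAME":
                    db.name = value
                elif key == "VERSION":
                    db.version = value
            continue
        if line == _RECORD_SEP:
            if record_lines:
                _build_frame(db, record_lines)
                record_lines = []
            continue
        if not line.strip():
            if record_lines:
                record_lines.append((lineno, line))
            continue
        record_lines.append((lineno, line))
    if any(l.strip() for _, l in record_lines):
        _build_frame(db, record_lines)
    db.saved = True
    return db


def _build_frame(db: Database, record_lines: Sequence[tuple[int, str]]) -> None:
    record_lines = [(n, l) for n, l in record_lines if l.strip()]
    first_no, first = record_lines[0]
    if not first.startswith("UNIQUE-ID - "):
        raise ParseError(f"line {first_no}: record does not start with UNIQUE-ID")
    frame_id = first[len("UNIQUE-ID - "):].strip()
    classes: list[str] = []
    slots: dict[str, list[SlotValue]] = {}
    last_sv: Optional[SlotValue] = None
    last_scalar: Optional[tuple] = None  # ("slot", sv) or ("ann", sv, label)

    for lineno, line in record_lines[1:]:
        if line.startswith("TYPES - "):
            classes.append(line[len("TYPES - "):].strip())
            last_scalar = None
            continue
        if line.startswith("/"):
            cont = line[1:]
            if last_scalar is None:
                raise ParseError(f"line {lineno}: continuation with no preceding value")
            if last_scalar[0] == "slot":
                sv = last_scalar[1]
                sv.value = sv.value + "\n" + cont
            else:
                _, sv, label = last_scalar
                sv.annotations[label][-1] = sv.annotations[label][-1] + "\n" + cont
            continue
        if line.startswith("^"):
            if last_sv is None:
                raise ParseError(
                    f"line {lineno}: annotation line with no preceding slot value")
            m = _SLOT_RE.match(line[1:])
            if not m:
                raise ParseError(f"line {lineno}: malformed annotation line")
            label, value = m.group(1).upper(), m.group(2)
            last_sv.annotations.setdefault(label, []).append(value)
            last_scalar = ("ann", last_sv, label)
            continue
        m = _SLOT_RE.match(line)
        if not m:
            raise ParseError(f"line {lineno}: unparseable line: {line!r}")
        label, value = m.group(1).upper(), m.group(2)
        if label == "UNIQUE-ID":
            raise ParseError(f"line {lineno}: UNIQUE-ID repeated within a record")
        sv = SlotValue(value)
        slots.setdefault(label, []).append(sv)
        last_sv = sv
        last_scalar = ("slot", sv)

    if not classes:
        raise ParseError(f"line {first_no}: record {frame_id} has no TYPES line")
    for cls in classes:
        if cls not in db.taxonomy:
            db.taxonomy.add_class(cls)
    frame = db.create_frame(frame_id, classes)
    frame.slots = slots
    db._reindex(frame)


def read_database_dir(path: PathLike) -> Database:
    """Load a database stored as a directory containing ``frames.dat``."""
    return read_attr_value(Path(path) / _DB_FILE)


def write_database_dir(db: Database, path: PathLike) -> Path:
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    target = d / _DB_FILE
    write_attr_value(db, target)
    return target


# ---------------------------------------------------------------------------
# CSV import files
# ---------------------------------------------------------------------------

#: Required columns per import type.
IMPORT_COLUMNS: dict[str, tuple[str, ...]] = {
    "slot-data": ("object-class", "identifier", "slot", "value"),
    "slot-value-annotation": (
        "object-class", "identifier", "slot", "value",
        "annotation-label", "annotation-value"),
    "go-annotation": ("identifier", "go-id", "evidence-code", "citation", "curator"),
    "delete-frames": ("object-class", "identifier"),
    "create-regulation": ("regulator-identifier", "target-identifier", "mode"),
}


@dataclass
class ImportRow:
    """One data row of an import file; ``row_index`` is 1-based and counts
    data rows only (blank and ``#`` comment lines are skipped)."""

    row_index: int
    fields: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> str:
        return self.fields[key]


def read_import_csv(path_or_text: PathLike, import_type: str, *,
                    text: Optional[str] = None) -> list[ImportRow]:
    if import_type not in IMPORT_COLUMNS:
        raise ImportFileError(f"unknown import type: {import_type}")
    if text is None:
        text = Path(path_or_text).read_text(encoding="utf-8")
    required = IMPORT_COLUMNS[import_type]
    reader = csv.reader(io.StringIO(text))
    header: Optional[list[str]] = None
    rows: list[ImportRow] = []
    for physical_no, cells in enumerate(reader, start=1):
        if not cells or all(not c.strip() for c in cells):
            continue
        if cells[0].lstrip().startswith("#"):
            continue
        if header is None:
            header = [c.strip() for c in cells]
            missing = [c for c in required if c not in header]
            if missing:
                raise ImportFileError(
                    f"{import_type} import file is missing required column(s): "
                    + ", ".join(missing))
            continue
        if len(cells) != len(header):
            raise ImportFileError(
                f"row {len(rows) + 1} (file line {physical_no}): expected "
                f"{len(header)} fields, got {len(cells)}")
        rows.append(ImportRow(
            row_index=len(rows) + 1,
            fields={h: c.strip() for h, c in zip(header, cells)}))
    if header is None:
        raise ImportFileError("empty import file (no header row)")
    return rows


# ---------------------------------------------------------------------------
# GO reference
# ---------------------------------------------------------------------------

@dataclass
class GoTerm:
    id: str
    name: str
    namespace: str
    definition: str = ""
    obsolete: bool = False


_GO_ID_RE = re.compile(r"^GO:(\d{1,7})$", re.IGNORECASE)


def normalize_go_id(raw: str) -> str:
    """Normalize a GO identifier to ``GO:`` + 7 digits; reject bare numbers."""
    m = _GO_ID_RE.match(raw.strip())
    if not m:
        raise MalformedGoIdError(f"malformed GO id: {raw!r}")
    return f"GO:{int(m.group(1)):07d}"


def read_go_reference(path: PathLike) -> dict[str, GoTerm]:
    """Load a GO-term reference from an OBO 1.2 file or a 4-column TSV
    (id, name, namespace, definition).  Obsolete terms are flagged, not
    dropped."""
    p = Path(path)
    head = p.read_text(encoding="utf-8", errors="replace")[:4096].lstrip()
    if head.startswith("format-version") or head.startswith("["):
        return _read_go_obo(p)
    return _read_go_tsv(p)


def _read_go_obo(path: Path) -> dict[str, GoTerm]:
    import obonet  # deferred: import cost only paid when OBO is actually read

    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    ref: dict[str, GoTerm] = {}
    for node, data in graph.nodes(data=True):
        try:
            go_id = normalize_go_id(node)
        except MalformedGoIdError:
            continue  # non-GO node in a mixed ontology
        ref[go_id] = GoTerm(
            id=go_id,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            definition=data.get("def", ""),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    return ref


def _read_go_tsv(path: Path) -> dict[str, GoTerm]:
    ref: dict[str, GoTerm] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").split("\n"),
                                  start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ImportFileError(
                f"GO reference TSV line {lineno}: expected at least "
                f"id, name, namespace")
        go_id = normalize_go_id(parts[0])
        name = parts[1].strip()
        ref[go_id] = GoTerm(
            id=go_id,
            name=name,
            namespace=parts[2].strip(),
            definition=parts[3].strip() if len(parts) > 3 else "",
            obsolete=name.lower().startswith("obsolete"),
        )
    return ref


# ---------------------------------------------------------------------------
# Change logs and reports
# ---------------------------------------------------------------------------

def write_change_log(entries: Iterable, path: PathLike) -> None:
    """Write a change log as TSV: timestamp, row_index, status, frame_id,
    message."""
    lines = ["timestamp\trow_index\tstatus\tframe_id\tmessage"]
    for e in entries:
        ts = e.timestamp.isoformat() if hasattr(e.timestamp, "isoformat") else str(e.timestamp)
        msg = str(e.message).replace("\t", " ").replace("\n", " | ")
        lines.append(f"{ts}\t{e.row_index}\t{e.status}\t{e.frame or ''}\t{msg}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_migration_report(report, path: PathLike) -> None:
    """Write a migration match report as TSV: gene-model name, outcome,
    target frame id(s), number of annotations migrated."""
    lines = ["gene_model_name\toutcome\ttarget_frame_ids\tn_annotations_migrated"]
    for match in report.matches:
        lines.append("\t".join([
            match.gene_model_name or "(missing-name)",
            match.outcome,
            ",".join(match.targets),
            str(match.n_annotations_migrated),
        ]))
    lines.append("")
    lines.append(f"# proteins: exact={report.n_exact} "
                 f"relaxed_only={report.n_relaxed_only} "
                 f"unmatched={report.n_unmatched}")
    lines.append(f"# annotation records: exact={report.n_records_exact} "
                 f"relaxed_only={report.n_records_relaxed_only} "
                 f"unmatched={report.n_records_unmatched}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
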