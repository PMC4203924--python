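"""Resolution of alternate identifiers to frame IDs.

Every operation on a frame database must ultimately address frames by their
internal frame ID, but curators work with the identifiers used in literature:
accessions, common names, synonyms, gene-model names.  This module maps those
alternate identifiers onto frame IDs under a strict policy:

1. A query equal to an existing frame ID (case-sensitive, and of the
   requested class) resolves directly, bypassing search.
2. Otherwise an indexed substring search over the class's name slots finds
   candidates, and candidates are kept only when the query matches a name
   value *exactly and entirely* (case-insensitive) — a partial hit such as a
   query for a gene-model stem against a splice-variant-suffixed synonym is
   rejected.
3. The match must be unique: two frames sharing a synonym yield ``ambiguous``
   and nothing is resolved.

Batch resolution mirrors the import pipeline: when every identifier in a
batch is already a valid frame ID the search step is skipped entirely, and
unresolvable identifiers are either skipped (with a report) or abort the
whole batch before anything is mapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .frame_store import Database, PgdbError, normalize_name

__all__ = [
    "OK",
    "INVALID_QUERY",
    "STATUS_FRAME_ID",
    "STATUS_UNIQUE",
    "STATUS_AMBIGUOUS",
    "STATUS_NONE",
    "STATUS_INVALID",
    "ResolutionResult",
    "BatchReport",
    "BatchAbortedError",
    "validate_query",
    "substring_search",
    "resolve",
    "resolve_batch",
]

OK = "ok"
INVALID_QUERY = "invalid-query"

STATUS_FRAME_ID = "frame-id"
STATUS_UNIQUE = "unique"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NONE = "none"
STATUS_INVALID = "invalid-query"

#: Minimum search-term length inherited from the indexed-search backend.
MIN_QUERY_LENGTH = 3


class BatchAbortedError(PgdbError):
    """Raised by resolve_batch(on_fail="abort"); carries the offending terms."""

    def __init__(self, failures: list["ResolutionResult"]) -> None:
        self.failures = failures
        terms = ", ".join(f"{r.query!r} ({r.status})" for r in failures)
        super().__init__(f"batch aborted; unresolvable identifiers: {terms}")


@dataclass
class ResolutionResult:
    query: str
    status: str
    matches: list[str] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        return self.status in (STATUS_FRAME_ID, STATUS_UNIQUE)

    @property
    def frame_id(self) -> Optional[str]:
        return self.matches[0] if self.resolved else None


def validate_query(term: str, compat: bool = False) -> str:
    """Check a search term; returns ``ok`` or ``invalid-query``.

    All searches require at least 3 characters.  Strict-compat mode
    additionally rejects commas and spaces, mirroring backends whose text
    index cannot search multi-word strings; native mode allows them so that
    multi-word synonyms ("pyruvic acid") remain searchable.
    """
    if len(term) < MIN_QUERY_LENGTH:
        return INVALID_QUERY
    if compat and ("," in term or " " in term):
        return INVALID_QUERY
    return OK


def substring_search(db: Database, term: str, class_name: str) -> set[str]:
    """Frames of the class (or a subclass) whose frame ID equals the term or
    whose name-slot values contain it as a substring; case-insensitive."""
    needle = normalize_name(term)
    hits: set[str] = set()
    for key, ids in db.name_index.items():
        if needle in key:
            hits.update(ids)
    for fid in db.frames:
        if fid.lower() == needle:
            hits.add(fid)
    return {
        fid for fid in hits
        if db.is_instance(db.frames[fid], class_name)
    }


def _entire_name_match(db: Database, fid: str, term: str) -> bool:
    frame = db.frames[fid]
    needle = normalize_name(term)
    for label in db.name_slots_for(frame):
        for value in frame.slot_values(label):
            if normalize_name(value) == needle:
                return True
    return False


def resolve(db: Database, term: str, class_name: str,
            compat: bool = False) -> ResolutionResult:
    """Resolve one alternate identifier to a frame ID.

    Direct frame-ID hits (case-sensitive, class-checked) short-circuit the
    search.  Search hits survive only with an entire-string name match, and
    only a unique survivor resolves.
    """
    if term in db.frames and db.is_instance(db.frames[term], class_name):
        return ResolutionResult(term, STATUS_FRAME_ID, [term])
    if validate_query(term, compat=compat) != OK:
        return ResolutionResult(term, STATUS_INVALID, [])
    candidates = substring_search(db, term, class_name)
    survivors = sorted(
        fid for fid in candidates if _entire_name_match(db, fid, term))
    if len(survivors) == 1:
        return ResolutionResult(term, STATUS_UNIQUE, survivors)
    if len(survivors) >= 2:
        return ResolutionResult(term, STATUS_AMBIGUOUS, survivors)
    return ResolutionResult(term, STATUS_NONE, [])


@dataclass
class BatchReport:
    search_skipped: bool = False
    results: list[ResolutionResult] = field(default_factory=list)
    skipped: list[ResolutionResult] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def resolve_batch(db: Database, terms: Sequence[str], class_name: str,
                  on_fail: str = "skip",
                  compat: bool = False) -> tuple[dict[str, str], BatchReport]:
    """Resolve a batch of identifiers.

    When every term is already a valid frame ID of the class, no search is
    performed at all (``report.search_skipped``).  Otherwise each term is
    resolved; with ``on_fail="skip"`` unresolvable terms are reported and the
    rest are mapped, with ``on_fail="abort"`` a BatchAbortedError is raised
    before any mapping is returned.
    """
    if on_fail not in ("skip", "abort"):
        raise PgdbError(f"unknown on_fail policy: {on_fail}")
    report = BatchReport()
    if all(t in db.frames and db.is_instance(db.frames[t], class_name)
           for t in terms):
        report.search_skipped = True
        report.results = [
            ResolutionResult(t, STATUS_FRAME_ID, [t]) for t in terms]
        return {t: t for t in terms}, report
    mapping: dict[str, str] = {}
    failures: list[ResolutionResult] = []
    for term in terms:
        result = resolve(db, term, class_name, compat=compat)
        report.results.append(result)
        if result.resolved:
            mapping[term] = result.matches[0]
        else:
            failures.append(result)
    if failures and on_fail == "abort":
        raise BatchAbortedError(failures)
    report.skipped = failures
    return mapping, report
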