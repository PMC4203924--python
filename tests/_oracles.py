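"""Independent brute-force oracle for cascading deletion.

Computes the deletion closure from a dependency-edge view of the database
(gene->product, enzyme->enzymatic-reaction, enzymatic-reaction->reaction
when orphaned, and any deleted frame -> linked regulation / history notes),
iterating full scans until a fixed point.  Kept deliberately separate from
the store's own cascade implementation: the oracle precomputes plain edge
maps up front and knows nothing about indexes, scrubbing, or transactions.
"""

from __future__ import annotations

PROTEIN_CLASSES = {"Protein", "Polypeptide", "Protein-Complex"}


def _classes(frame) -> set[str]:
    return set(frame.classes)


def cascade_closure(db, seed_id: str) -> set[str]:
    """Expected deleted set for delete_frame_and_dependents(seed_id),
    computed on the database *before* the deletion runs."""
    gene_of: dict[str, list[str]] = {}
    er_edges: list[tuple[str, list[str]]] = []  # (er, enzyme+reaction refs)
    catalysts: dict[str, set[str]] = {}  # reaction -> ERs citing it
    link_edges: list[tuple[str, list[str]]] = []  # (reg/note, referenced ids)

    for fid, frame in db.frames.items():
        cls = _classes(frame)
        if cls & PROTEIN_CLASSES:
            gene_of[fid] = frame.slot_values("GENE")
        if "Enzymatic-Reaction" in cls:
            refs = frame.slot_values("ENZYME") + frame.slot_values("REACTION")
            er_edges.append((fid, refs))
            for rxn in frame.slot_values("REACTION"):
                catalysts.setdefault(rxn, set()).add(fid)
        if "Regulation" in cls:
            link_edges.append((fid, frame.slot_values("REGULATOR")
                               + frame.slot_values("REGULATED-ENTITY")))
        if "History-Note" in cls:
            link_edges.append((fid, frame.slot_values("REFERENCED-FRAME")))

    reactions = [fid for fid, f in db.frames.items()
                 if "Reaction" in _classes(f)]

    dead = {seed_id}
    while True:
        size = len(dead)
        for pid, genes in gene_of.items():
            if genes and all(g in dead for g in genes):
                dead.add(pid)
        for er, refs in er_edges:
            if any(r in dead for r in refs):
                dead.add(er)
        for rxn in reactions:
            ers = catalysts.get(rxn, set())
            if ers and ers <= dead:
                dead.add(rxn)
        for fid, refs in link_edges:
            if any(r in dead for r in refs):
                dead.add(fid)
        if len(dead) == size:
            return dead
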