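"""Deterministic synthetic PGDB generator.

Real pathway/genome databases are large, licensed, and tied to external
gene-model releases, so every stage of this toolkit is exercised against
synthetic databases generated here.  The generator emulates the structural
features the toolkit's operations depend on:

* genes with one or more protein products (splice variants), carrying
  gene-model synonyms with numeric ``_P`` suffixes;
* enzymes wired to reactions through enzymatic-reaction frames, with a mix
  of reactions catalyzed by one enzyme, by several, or by none;
* transcription factors with regulation frames;
* compounds with multi-word synonyms (the hard case for synonym search);
* a subset of proteins GO-annotated with a mix of experimental (``EV-EXP``)
  and computational (``EV-COMP``) evidence codes;
* pathways referencing reactions, history notes, curator/organization
  frames, and an organism summary frame.

``generate_paired_pgdbs`` produces two databases over a shared gene-model
namespace but with different internal frame-ID prefixes, together with the
ground truth of intended cross-database match outcomes (exact /
relaxed-only / absent) for migration-recovery testing.

Everything is a pure function of (params, seed): the same inputs always
produce byte-identical serializations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

from .flatfile_io import GoTerm
from .frame_store import Database, PgdbError

__all__ = [
    "FixtureParams",
    "GroundTruth",
    "PYRUVATE_SYNONYMS",
    "BUILTIN_GO_TERMS",
    "TickClock",
    "builtin_go_reference",
    "write_builtin_go_reference_tsv",
    "pyruvate_compound_db",
    "generate_pgdb",
    "generate_paired_pgdbs",
    "write_ground_truth",
]


#: The nine alternate identifiers of pyruvate as curated in a reference
#: E. coli database; used to exercise multi-word, case- and unicode-bearing
#: synonym resolution.
PYRUVATE_SYNONYMS: tuple[str, ...] = (
    "alpha-ketopropionic acid",
    "BTS",
    "α-ketopropionic acid",
    "acetylformic acid",
    "pyroracemic acid",
    "2-oxopropanoic acid",
    "pyruvic acid",
    "2-oxopropanoate",
    "2-oxo-propionic acid",
)

#: Small built-in GO reference so GO imports need no download.
BUILTIN_GO_TERMS: tuple[tuple[str, str, str], ...] = (
    ("GO:0005737", "cytoplasm", "cellular_component"),
    ("GO:0005634", "nucleus", "cellular_component"),
    ("GO:0005886", "plasma membrane", "cellular_component"),
    ("GO:0005840", "ribosome", "cellular_component"),
    ("GO:0016020", "membrane", "cellular_component"),
    ("GO:0003824", "catalytic activity", "molecular_function"),
    ("GO:0016301", "kinase activity", "molecular_function"),
    ("GO:0016740", "transferase activity", "molecular_function"),
    ("GO:0016787", "hydrolase activity", "molecular_function"),
    ("GO:0005524", "ATP binding", "molecular_function"),
    ("GO:0046872", "metal ion binding", "molecular_function"),
    ("GO:0003677", "DNA binding", "molecular_function"),
    ("GO:0003700", "DNA-binding transcription factor activity",
     "molecular_function"),
    ("GO:0003735", "structural constituent of ribosome", "molecular_function"),
    ("GO:0008152", "metabolic process", "biological_process"),
    ("GO:0006096", "glycolytic process", "biological_process"),
    ("GO:0005975", "carbohydrate metabolic process", "biological_process"),
    ("GO:0006412", "translation", "biological_process"),
    ("GO:0006355", "regulation of DNA-templated transcription",
     "biological_process"),
    ("GO:0006629", "lipid metabolic process", "biological_process"),
)


def builtin_go_reference() -> dict[str, GoTerm]:
    return {go_id: GoTerm(go_id, name, namespace)
            for go_id, name, namespace in BUILTIN_GO_TERMS}


def write_builtin_go_reference_tsv(path: Union[str, Path]) -> None:
    lines = [f"{g}\t{n}\t{ns}\t" for g, n, ns in BUILTIN_GO_TERMS]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


class TickClock:
    """Deterministic injectable clock: starts at a fixed instant and
    advances one second per call."""

    def __init__(self, start: Optional[datetime] = None) -> None:
        self._t = start or datetime(2020, 1, 1, tzinfo=timezone.utc)

    def __call__(self) -> datetime:
        self._t += timedelta(seconds=1)
        return self._t


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class FixtureParams:
    """Knobs for the single-database generator; defaults give a small but
    structurally complete database (every cascade rule reachable)."""

    n_genes: int = 30
    variants_per_gene: int = 1  # or (lo, hi) inclusive range
    fraction_enzymes: float = 0.5
    fraction_tfs: float = 0.15
    n_compounds: int = 20
    n_reactions: int = 12
    n_pathways: int = 3
    synonyms_per_object: int = 2
    go_fraction: float = 0.4
    evidence_experimental: float = 0.5
    seed: int = 0
    orgid: str = "SYN"
    id_prefix: str = "SYN"

    def validate(self) -> None:
        for attr in ("n_genes", "n_compounds", "n_reactions", "n_pathways",
                     "synonyms_per_object"):
            if getattr(self, attr) < 0:
                raise PgdbError(f"invalid params: {attr} must be >= 0")
        for attr in ("fraction_enzymes", "fraction_tfs", "go_fraction",
                     "evidence_experimental"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise PgdbError(f"invalid params: {attr} must be in [0, 1]")
        lo, hi = self._variant_range()
        if lo < 1 or hi < lo:
            raise PgdbError("invalid params: variants_per_gene must be >= 1")

    def _variant_range(self) -> tuple[int, int]:
        v = self.variants_per_gene
        if isinstance(v, int):
            return v, v
        return int(v[0]), int(v[1])


@dataclass
class GroundTruth:
    """Intended cross-database match outcome per gene-model stem."""

    outcomes: dict[str, str] = field(default_factory=dict)  # stem -> outcome
    suffixes_a: dict[str, list[int]] = field(default_factory=dict)
    suffixes_b: dict[str, list[int]] = field(default_factory=dict)
    a_protein: dict[str, str] = field(default_factory=dict)  # stem -> frame id in A
    b_protein: dict[str, str] = field(default_factory=dict)  # stem -> expected target in B

    def stems(self, outcome: str) -> list[str]:
        return [s for s, o in self.outcomes.items() if o == outcome]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.stems("exact")), len(self.stems("relaxed-only")),
                len(self.stems("absent")))


def write_ground_truth(gt: GroundTruth, path: Union[str, Path]) -> None:
    lines = ["stem\toutcome\ta_protein\tb_protein\ta_suffixes\tb_suffixes"]
    for stem, outcome in gt.outcomes.items():
        lines.append("\t".join([
            stem, outcome,
            gt.a_protein.get(stem, ""), gt.b_protein.get(stem, ""),
            ",".join(map(str, gt.suffixes_a.get(stem, []))),
            ",".join(map(str, gt.suffixes_b.get(stem, []))),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Name generators
# ---------------------------------------------------------------------------

_SYLLABLES = ("ba", "do", "fa", "gi", "ka", "lo", "ma", "ne", "pi", "ra",
              "su", "ta", "ve", "xo", "zu")


def _word(rng: random.Random, n_syll: int = 3) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))


def _gene_symbol(rng: random.Random, used: set[str]) -> str:
    while True:
        sym = _word(rng, 2)[:3] + rng.choice("ABCDEFGHJKLMNPQRSTUVWXYZ")
        if sym not in used:
            used.add(sym)
            return sym


def _stems(rng: random.Random, n: int) -> list[str]:
    numbers = rng.sample(range(100000, 999999), n)
    return [f"GM2G{num}" for num in numbers]


# ---------------------------------------------------------------------------
# Single database
# ---------------------------------------------------------------------------

def pyruvate_compound_db() -> Database:
    """A minimal compound database whose PYRUVATE frame carries the nine
    curated alternate identifiers; the canonical resolution test bed."""
    db = Database(orgid="PYR", name="Pyruvate resolution fixture",
                  clock=TickClock())
    db.create_frame("PYRUVATE", ["Compound"])
    db.edit_slot("PYRUVATE", "COMMON-NAME", ["pyruvate"])
    db.edit_slot("PYRUVATE", "SYNONYMS", list(PYRUVATE_SYNONYMS))
    return db


def generate_pgdb(params: Optional[FixtureParams] = None, *,
                  seed: Optional[int] = None) -> Database:
    """Generate a structurally complete synthetic database; deterministic in
    (params, seed) and guaranteed to pass ``integrity_check``."""
    params = params or FixtureParams()
    if seed is not None:
        params = FixtureParams(**{**params.__dict__, "seed": seed})
    params.validate()
    rng = random.Random(params.seed)
    pre = params.id_prefix
    db = Database(orgid=params.orgid,
                  name=f"Synthetic PGDB {params.orgid}",
                  version="1.0", clock=TickClock())

    db.create_frame(f"{pre}-ORGANISM", ["Organism"])
    db.edit_slot(f"{pre}-ORGANISM", "COMMON-NAME", [db.name])
    db.create_frame("CURATOR-0001", ["Person"])
    db.edit_slot("CURATOR-0001", "COMMON-NAME", ["Ada Curator"])
    db.create_frame("ORG-0001", ["Organization"])
    db.edit_slot("ORG-0001", "COMMON-NAME", ["Synthetic Genome Initiative"])

    # compounds with multi-word synonyms
    compounds = []
    for i in range(1, params.n_compounds + 1):
        cid = f"{pre}-CPD-{i:04d}"
        word = _word(rng)
        db.create_frame(cid, ["Compound"])
        db.edit_slot(cid, "COMMON-NAME", [word])
        synonyms = [f"{word} acid", f"2-oxo{word}ate"][:params.synonyms_per_object]
        if synonyms:
            db.edit_slot(cid, "SYNONYMS", synonyms)
        compounds.append(cid)

    # genes and their products (splice variants)
    lo, hi = params._variant_range()
    used_symbols: set[str] = set()
    stems = _stems(rng, params.n_genes)
    genes, proteins = [], []
    for i, stem in enumerate(stems, start=1):
        gid = f"{pre}-G-{i:04d}"
        symbol = _gene_symbol(rng, used_symbols)
        db.create_frame(gid, ["Gene"])
        db.edit_slot(gid, "COMMON-NAME", [symbol])
        db.edit_slot(gid, "ACCESSION", [stem])
        genes.append(gid)
        n_var = rng.randint(lo, hi)
        for v in range(1, n_var + 1):
            pid = f"{pre}-P-{i:04d}-{v}"
            db.create_frame(pid, ["Polypeptide"])
            db.edit_slot(pid, "COMMON-NAME", [f"{symbol} protein {v}"])
            db.edit_slot(pid, "SYNONYMS", [f"{stem}_P{v:02d}"])
            db.edit_slot(pid, "GENE", [gid])
            db.edit_slot(gid, "PRODUCT", [pid], "append")
            proteins.append(pid)

    # enzymes wired to reactions via enzymatic-reaction frames
    n_enzymes = round(params.fraction_enzymes * len(proteins))
    enzymes = rng.sample(proteins, n_enzymes) if n_enzymes else []
    reactions = []
    er_count = 0
    for i in range(1, params.n_reactions + 1):
        rid = f"{pre}-RXN-{i:04d}"
        db.create_frame(rid, ["Reaction"])
        if compounds:
            db.edit_slot(rid, "LEFT", rng.sample(compounds, min(2, len(compounds))))
            db.edit_slot(rid, "RIGHT", [rng.choice(compounds)])
        reactions.append(rid)
        # ~1/4 spontaneous, ~1/4 doubly catalyzed, rest single-enzyme
        n_cat = 0 if not enzymes else rng.choice((0, 1, 1, 2))
        for enzyme in rng.sample(enzymes, min(n_cat, len(enzymes))):
            er_count += 1
            eid = f"{pre}-ENZRXN-{er_count:04d}"
            db.create_frame(eid, ["Enzymatic-Reaction"])
            db.edit_slot(eid, "ENZYME", [enzyme])
            db.edit_slot(eid, "REACTION", [rid])

    # transcription factors regulating genes
    non_enzymes = [p for p in proteins if p not in set(enzymes)]
    n_tfs = round(params.fraction_tfs * len(proteins))
    tfs = rng.sample(non_enzymes, min(n_tfs, len(non_enzymes)))
    for tf in tfs:
        for gene in rng.sample(genes, min(rng.randint(1, 2), len(genes))):
            rid = db.new_id("REG")
            db.create_frame(rid, ["Regulation"])
            db.edit_slot(rid, "REGULATOR", [tf])
            db.edit_slot(rid, "REGULATED-ENTITY", [gene])
            db.edit_slot(rid, "MODE", [rng.choice(("+", "-"))])

    # history notes on a few frames
    notable = genes + proteins + reactions
    for target in rng.sample(notable, min(3, len(notable))):
        hid = db.new_id("HNOTE")
        db.create_frame(hid, ["History-Note"])
        db.edit_slot(hid, "REFERENCED-FRAME", [target])
        db.edit_slot(hid, "NOTE-TEXT", [f"curation note on {target}"])

    # GO annotations on a subset of proteins, mixed evidence
    go_ref = builtin_go_reference()
    go_pool = [g for g, _, _ in BUILTIN_GO_TERMS]
    n_go = round(params.go_fraction * len(proteins))
    for pid in rng.sample(proteins, min(n_go, len(proteins))):
        for go_id in rng.sample(go_pool, rng.randint(1, 2)):
            _annotate_go(db, rng, go_ref, pid, go_id,
                         experimental=rng.random() < params.evidence_experimental)

    # pathways hold reaction lists; never cascade-deleted themselves
    for i in range(1, params.n_pathways + 1):
        pwy = f"{pre}-PWY-{i:04d}"
        db.create_frame(pwy, ["Pathway"])
        db.edit_slot(pwy, "COMMON-NAME", [f"{_word(rng)} pathway"])
        if reactions:
            k = rng.randint(1, min(4, len(reactions)))
            db.edit_slot(pwy, "REACTION-LIST", rng.sample(reactions, k))

    db.saved = True
    return db


def _annotate_go(db: Database, rng: random.Random, go_ref, protein_id: str,
                 go_id: str, experimental: bool) -> None:
    if go_id not in db.frames:
        term = go_ref[go_id]
        db.create_frame(go_id, ["GO-Term"])
        db.edit_slot(go_id, "COMMON-NAME", [term.name])
        db.edit_slot(go_id, "NAMESPACE", [term.namespace])
    db.edit_slot(protein_id, "GO-TERMS", [go_id], "append-ignore-duplicates")
    evidence = (rng.choice(("EV-EXP-IDA", "EV-EXP-IMP", "EV-EXP-IGI"))
                if experimental else rng.choice(("EV-COMP-AINF", "EV-COMP-HINF")))
    db.annotate_value(protein_id, "GO-TERMS", go_id, "CITATIONS",
                      [f"PMID:{rng.randint(10000, 99999)}"], "append")
    db.annotate_value(protein_id, "GO-TERMS", go_id, "EVIDENCE",
                      [evidence], "append")
    db.annotate_value(protein_id, "GO-TERMS", go_id, "CURATOR",
                      ["CURATOR-0001"], "append")


# ---------------------------------------------------------------------------
# Paired databases with ground truth
# ---------------------------------------------------------------------------

def generate_paired_pgdbs(split: tuple[int, int, int] = (40, 10, 50),
                          prefixes: tuple[str, str] = ("GBWI", "GDQC"),
                          seed: int = 0
                          ) -> tuple[Database, Database, GroundTruth]:
    """Two databases over a shared gene-model stem namespace.

    ``split`` = (n_exact, n_relaxed_only, n_absent) stems.  Database A
    carries experimentally backed GO annotations (plus computational noise)
    on one protein per stem; database B realizes the intended outcome per
    stem: same splice-variant suffix (exact), different suffixes only
    (relaxed-only), or stem absent.  Internal frame IDs use the two prefixes
    so no frame ID is shared even where gene-model synonyms overlap.
    """
    if any(n < 0 for n in split):
        raise PgdbError("invalid split: counts must be >= 0")
    rng = random.Random(seed)
    n_total = sum(split)
    stems = _stems(rng, n_total + split[2])  # extras are B-only filler stems
    shared, filler = stems[:n_total], stems[n_total:]
    outcomes = (["exact"] * split[0] + ["relaxed-only"] * split[1]
                + ["absent"] * split[2])
    rng.shuffle(outcomes)

    clock_a, clock_b = TickClock(), TickClock()
    db_a = Database(orgid="SYNA", name="Synthetic source PGDB", clock=clock_a)
    db_b = Database(orgid="SYNB", name="Synthetic target PGDB", clock=clock_b)
    for db in (db_a, db_b):
        db.create_frame("CURATOR-0001", ["Person"])
        db.edit_slot("CURATOR-0001", "COMMON-NAME", ["Ada Curator"])

    gt = GroundTruth()
    go_ref = builtin_go_reference()
    go_pool = [g for g, _, _ in BUILTIN_GO_TERMS]

    for i, (stem, outcome) in enumerate(zip(shared, outcomes), start=1):
        gt.outcomes[stem] = outcome
        a_suffix = 1
        gid_a = f"{prefixes[0]}-G{i:04d}"
        pid_a = f"{prefixes[0]}-{i:04d}"
        db_a.create_frame(gid_a, ["Gene"])
        db_a.edit_slot(gid_a, "ACCESSION", [stem])
        db_a.create_frame(pid_a, ["Polypeptide"])
        db_a.edit_slot(pid_a, "GENE", [gid_a])
        db_a.edit_slot(gid_a, "PRODUCT", [pid_a])
        db_a.edit_slot(pid_a, "SYNONYMS", [f"{stem}_P{a_suffix:02d}"])
        gt.suffixes_a[stem] = [a_suffix]
        gt.a_protein[stem] = pid_a
        # every stem gets one experimental annotation (so it appears in the
        # filtered export) plus occasional computational noise
        go_exp = rng.choice(go_pool)
        _annotate_go(db_a, rng, go_ref, pid_a, go_exp, experimental=True)
        if rng.random() < 0.3:
            others = [g for g in go_pool if g != go_exp]
            _annotate_go(db_a, rng, go_ref, pid_a, rng.choice(others),
                         experimental=False)

        if outcome == "absent":
            continue
        b_suffixes = ([a_suffix] if outcome == "exact"
                      else sorted(rng.sample((2, 3, 4), rng.randint(1, 2))))
        gid_b = f"{prefixes[1]}-G{i:04d}"
        db_b.create_frame(gid_b, ["Gene"])
        db_b.edit_slot(gid_b, "ACCESSION", [stem])
        expected = None
        for v in b_suffixes:
            pid_b = f"{prefixes[1]}-{i:04d}-{v}"
            db_b.create_frame(pid_b, ["Polypeptide"])
            db_b.edit_slot(pid_b, "GENE", [gid_b])
            db_b.edit_slot(gid_b, "PRODUCT", [pid_b], "append")
            db_b.edit_slot(pid_b, "SYNONYMS", [f"{stem}_P{v:02d}"])
            if expected is None:  # exact suffix, or lowest-numbered variant
                expected = pid_b
        gt.suffixes_b[stem] = list(b_suffixes)
        gt.b_protein[stem] = expected

    # B-only filler proteins: realistic target content that must never match
    for j, stem in enumerate(filler, start=1):
        pid = f"{prefixes[1]}-X{j:04d}"
        db_b.create_frame(pid, ["Polypeptide"])
        db_b.edit_slot(pid, "SYNONYMS", [f"{stem}_P01"])

    db_a.saved = True
    db_b.saved = True
    return db_a, db_b, gt
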