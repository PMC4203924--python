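import pytest
from hypothesis import HealthCheck, settings

from pgdbkit import Database, builtin_go_reference, generate_paired_pgdbs, generate_pgdb
from pgdbkit.fixture_gen import FixtureParams, TickClock, pyruvate_compound_db

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture
def empty_db():
    return Database(clock=TickClock())


@pytest.fixture
def wired_db():
    """Minimal dependency web: gene G codes enzyme P, sole catalyst of
    reaction R (via ER); gene G2 codes P2 which shares reaction R2 with P;
    gene GT codes transcription factor T regulating G2 via REG-0001."""
    db = Database(clock=TickClock())
    frames = [
        ("G", "Gene"), ("G2", "Gene"), ("GT", "Gene"),
        ("P", "Polypeptide"), ("P2", "Polypeptide"), ("T", "Polypeptide"),
        ("ER", "Enzymatic-Reaction"), ("ER2a", "Enzymatic-Reaction"),
        ("ER2b", "Enzymatic-Reaction"),
        ("R", "Reaction"), ("R2", "Reaction"),
        ("PWY", "Pathway"), ("HN", "History-Note"),
        ("CURATOR-0001", "Person"), ("ORG-0001", "Organization"),
    ]
    for fid, cls in frames:
        db.create_frame(fid, [cls])
    db.edit_slot("G", "PRODUCT", ["P"])
    db.edit_slot("P", "GENE", ["G"])
    db.edit_slot("G2", "PRODUCT", ["P2"])
    db.edit_slot("P2", "GENE", ["G2"])
    db.edit_slot("GT", "PRODUCT", ["T"])
    db.edit_slot("T", "GENE", ["GT"])
    db.edit_slot("ER", "ENZYME", ["P"])
    db.edit_slot("ER", "REACTION", ["R"])
    db.edit_slot("ER2a", "ENZYME", ["P"])
    db.edit_slot("ER2a", "REACTION", ["R2"])
    db.edit_slot("ER2b", "ENZYME", ["P2"])
    db.edit_slot("ER2b", "REACTION", ["R2"])
    db.edit_slot("PWY", "REACTION-LIST", ["R", "R2"])
    db.edit_slot("HN", "REFERENCED-FRAME", ["P"])
    reg = db.new_id("REG")
    db.create_frame(reg, ["Regulation"])
    db.edit_slot(reg, "REGULATOR", ["T"])
    db.edit_slot(reg, "REGULATED-ENTITY", ["G2"])
    db.edit_slot("G", "COMMON-NAME", ["fadD"])
    db.edit_slot("G2", "COMMON-NAME", ["poxB"])
    db.edit_slot("GT", "COMMON-NAME", ["arcA"])
    db.edit_slot("P", "SYNONYMS", ["GM2G100001_P01"])
    db.edit_slot("P2", "SYNONYMS", ["GM2G100002_P01"])
    return db


@pytest.fixture
def pyruvate_db():
    return pyruvate_compound_db()


@pytest.fixture(scope="session")
def gen_db():
    return generate_pgdb(FixtureParams(seed=0))


@pytest.fixture(scope="session")
def paired():
    return generate_paired_pgdbs(split=(40, 10, 50), seed=0)


@pytest.fixture(scope="session")
def go_ref():
    return builtin_go_reference()
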