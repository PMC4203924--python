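"""Frame store: CRUD semantics, cascade deletion, transactions, integrity."""

import pytest
from hypothesis import given, strategies as st

from pgdbkit import (
    AuthorClassError,
    Database,
    DuplicateFrameIdError,
    TransactionError,
    UnknownClassError,
    UnknownFrameError,
    ValueNotInSlotError,
    render_database,
)
from pgdbkit.fixture_gen import FixtureParams, TickClock, generate_pgdb
from pgdbkit.frame_store import SlotValue

from _oracles import cascade_closure


class TestCreateFrame:
    def test_creates_frame_with_creation_revision(self, empty_db):
        frame = empty_db.create_frame("PYRUVATE", ["Compound"])
        assert len(empty_db) == 1
        assert frame.slots == {}
        assert [r.action for r in frame.revisions] == ["created"]

    def test_duplicate_id_rejected(self, empty_db):
        empty_db.create_frame("PYRUVATE", ["Compound"])
        with pytest.raises(DuplicateFrameIdError):
            empty_db.create_frame("PYRUVATE", ["Compound"])

    def test_unknown_class_rejected(self, empty_db):
        with pytest.raises(UnknownClassError):
            empty_db.create_frame("X-0001", ["No-Such-Class"])
        with pytest.raises(UnknownClassError):
            empty_db.create_frame("X-0001", [])


class TestEditSlot:
    @pytest.mark.parametrize("initial,mode,new,expected", [
        # a duplicate value is not re-added ...
        (["GO:0005737"], "append-ignore-duplicates", ["GO:0005737"], ["GO:0005737"]),
        # ... but a pre-existing duplication is never removed
        (["X", "X"], "append-ignore-duplicates", ["X"], ["X", "X"]),
        # overwrite deletes the existing data first
        (["X1", "X2"], "overwrite", ["Y"], ["Y"]),
        (["A"], "append", ["A", "B"], ["A", "A", "B"]),
    ])
    def test_write_modes(self, empty_db, initial, mode, new, expected):
        empty_db.create_frame("F", ["Compound"])
        empty_db.edit_slot("F", "S", initial)
        empty_db.edit_slot("F", "S", new, mode)
        assert empty_db.get("F").slot_values("S") == expected

    def test_append_ignore_duplicates_idempotent(self, empty_db):
        empty_db.create_frame("F", ["Compound"])
        empty_db.edit_slot("F", "S", ["a", "b"])
        empty_db.edit_slot("F", "S", ["b", "c"], "append-ignore-duplicates")
        once = empty_db.get("F").slot_values("S")
        empty_db.edit_slot("F", "S", ["b", "c"], "append-ignore-duplicates")
        assert empty_db.get("F").slot_values("S") == once == ["a", "b", "c"]

    def test_unknown_frame(self, empty_db):
        with pytest.raises(UnknownFrameError):
            empty_db.edit_slot("NOPE", "S", ["x"])

    def test_name_slot_edit_refreshes_index(self, empty_db):
        empty_db.create_frame("F", ["Compound"])
        empty_db.edit_slot("F", "SYNONYMS", ["pyruvic acid"])
        assert empty_db.name_index["pyruvic acid"] == {"F"}
        empty_db.edit_slot("F", "SYNONYMS", ["acetylformic acid"], "overwrite")
        assert "pyruvic acid" not in empty_db.name_index
        assert empty_db.integrity_check() == []


class TestAnnotateValue:
    def test_annotation_attaches_to_that_value_only(self, empty_db):
        empty_db.create_frame("P", ["Polypeptide"])
        empty_db.create_frame("GO:0005737", ["GO-Term"])
        empty_db.create_frame("GO:0005634", ["GO-Term"])
        empty_db.edit_slot("P", "GO-TERMS", ["GO:0005737", "GO:0005634"])
        empty_db.annotate_value("P", "GO-TERMS", "GO:0005737",
                                "CITATIONS", ["PMID:12345"])
        svs = empty_db.get("P").slots["GO-TERMS"]
        assert svs[0].annotations == {"CITATIONS": ["PMID:12345"]}
        assert svs[1].annotations == {}

    def test_value_not_in_slot(self, empty_db):
        empty_db.create_frame("P", ["Polypeptide"])
        empty_db.edit_slot("P", "GO-TERMS", ["GO:0005737"])
        with pytest.raises(ValueNotInSlotError):
            empty_db.annotate_value("P", "GO-TERMS", "GO:0099999",
                                    "CITATIONS", ["PMID:1"])

    def test_ignore_duplicates_keeps_annotation_list_unchanged(self, empty_db):
        empty_db.create_frame("P", ["Polypeptide"])
        empty_db.edit_slot("P", "GO-TERMS", ["GO:0005737"])
        empty_db.annotate_value("P", "GO-TERMS", "GO:0005737",
                                "CITATIONS", ["PMID:1"])
        empty_db.annotate_value("P", "GO-TERMS", "GO:0005737",
                                "CITATIONS", ["PMID:1"], "append-ignore-duplicates")
        sv = empty_db.get("P").get_slot_value("GO-TERMS", "GO:0005737")
        assert sv.annotations["CITATIONS"] == ["PMID:1"]


class TestAddCredit:
    def test_first_credit_and_revision(self, wired_db):
        before = len(wired_db.get("P").revisions)
        wired_db.add_credit("P", "CURATOR-0001")
        assert wired_db.get("P").slot_values("CREDITS") == ["CURATOR-0001"]
        assert len(wired_db.get("P").revisions) == before + 1

    def test_credit_order_preserved(self, wired_db):
        wired_db.add_credit("P", "CURATOR-0001")
        wired_db.add_credit("P", "ORG-0001")
        assert wired_db.get("P").slot_values("CREDITS") == [
            "CURATOR-0001", "ORG-0001"]

    def test_author_must_be_person_or_organization(self, wired_db):
        with pytest.raises(AuthorClassError):
            wired_db.add_credit("P", "G")


class TestCascadeDeletion:
    def test_gene_product_sole_enzyme_reaction(self, wired_db):
        # P also catalyzes shared R2, but R2 keeps catalyst P2 and survives
        deleted = wired_db.delete_frame_and_dependents("G")
        assert deleted == {"G", "P", "ER", "R", "ER2a", "HN"}
        assert "R2" in wired_db.frames
        assert wired_db.get("PWY").slot_values("REACTION-LIST") == ["R2"]
        assert wired_db.integrity_check() == []

    def test_shared_reaction_survives_partial_catalyst_loss(self, wired_db):
        wired_db.delete_frame_and_dependents("G2")
        assert "R2" in wired_db.frames  # still catalyzed by P via ER2a
        assert "ER2b" not in wired_db.frames

    def test_transcription_factor_deletion_removes_regulation(self, wired_db):
        deleted = wired_db.delete_frame_and_dependents("GT")
        assert deleted == {"GT", "T", "REG-0001"}
        assert "G2" in wired_db.frames  # regulated gene itself survives

    def test_unknown_frame(self, wired_db):
        with pytest.raises(UnknownFrameError):
            wired_db.delete_frame_and_dependents("NOPE")

    def test_multi_gene_product_survives_until_last_gene(self, empty_db):
        db = empty_db
        for fid in ("GA", "GB"):
            db.create_frame(fid, ["Gene"])
        db.create_frame("P", ["Polypeptide"])
        db.edit_slot("P", "GENE", ["GA", "GB"])
        db.edit_slot("GA", "PRODUCT", ["P"])
        db.edit_slot("GB", "PRODUCT", ["P"])
        assert db.delete_frame_and_dependents("GA") == {"GA"}
        assert db.get("P").slot_values("GENE") == ["GB"]
        assert db.delete_frame_and_dependents("GB") == {"GB", "P"}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_reachability_oracle(self, seed):
        db = generate_pgdb(FixtureParams(
            n_genes=8, variants_per_gene=(1, 2), n_reactions=6,
            n_compounds=6, n_pathways=2, seed=seed))
        import random
        rng = random.Random(seed)
        candidates = [f.id for f in db.frames.values()
                      if set(f.classes) & {"Gene", "Polypeptide", "Reaction"}]
        target = rng.choice(candidates)
        expected = cascade_closure(db, target)
        assert db.delete_frame_and_dependents(target) == expected
        assert db.integrity_check() == []


class TestTransactions:
    def test_rollback_restores_serialization(self, wired_db):
        before = render_database(wired_db)
        wired_db.begin()
        wired_db.edit_slot("P", "COMMON-NAME", ["mutant"])
        wired_db.delete_frame_and_dependents("G2")
        wired_db.create_frame("NEW-0001", ["Compound"])
        wired_db.rollback()
        assert render_database(wired_db) == before

    def test_commit_without_edits_is_identity(self, wired_db):
        before = render_database(wired_db)
        wired_db.begin()
        wired_db.commit()
        assert render_database(wired_db) == before
        assert wired_db.saved

    def test_nested_begin_rejected(self, wired_db):
        wired_db.begin()
        with pytest.raises(TransactionError):
            wired_db.begin()

    @pytest.mark.parametrize("op", ["rollback", "commit"])
    def test_rollback_commit_require_begin(self, wired_db, op):
        with pytest.raises(TransactionError):
            getattr(wired_db, op)()

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 10**6)),
                    max_size=12))
    def test_random_edit_sequences_roll_back_cleanly(self, ops):
        db = generate_pgdb(FixtureParams(n_genes=5, n_reactions=3,
                                         n_compounds=4, seed=99))
        before = render_database(db)
        db.begin()
        ids = list(db.frames)
        for i, (kind, r) in enumerate(ops):
            fid = ids[r % len(ids)]
            if kind == 0 and fid in db.frames:
                db.edit_slot(fid, "COMMON-NAME", [f"name-{r}"], "overwrite")
            elif kind == 1 and fid in db.frames:
                db.edit_slot(fid, "SYNONYMS", [f"syn {r}"], "append")
            elif kind == 2 and fid in db.frames:
                db.delete_frame_and_dependents(fid)
            else:
                db.create_frame(f"TMP-{i}", ["Compound"])
        db.rollback()
        assert render_database(db) == before


class TestIntegrity:
    def test_fresh_fixture_is_clean(self, gen_db):
        assert gen_db.integrity_check() == []

    def test_dangling_reference_is_reported_with_frame_and_slot(self, wired_db):
        wired_db.get("G").slots["PRODUCT"].append(SlotValue("GHOST"))
        violations = wired_db.integrity_check()
        assert len(violations) == 1
        assert "G" in violations[0] and "PRODUCT" in violations[0]

    def test_operations_preserve_integrity(self, wired_db):
        wired_db.edit_slot("P", "SYNONYMS", ["extra synonym"], "append")
        wired_db.add_credit("P", "ORG-0001")
        wired_db.delete_frame_and_dependents("G")
        wired_db.begin()
        wired_db.delete_frame_and_dependents("GT")
        wired_db.rollback()
        assert wired_db.integrity_check() == []


class TestSequentialIds:
    def test_ids_are_zero_padded_and_monotone(self, empty_db):
        assert empty_db.new_id("REG") == "REG-0001"
        empty_db.create_frame("REG-0002", ["Regulation"])
        assert empty_db.new_id("REG") == "REG-0003"
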