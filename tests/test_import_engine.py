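"""Import lifecycle: plan, preview, apply, credit, change log."""

import pytest

from pgdbkit import (
    ImportOptions,
    ImportRow,
    TransactionError,
    apply_plan,
    create_regulation_frames,
    delete_frames_import,
    import_go_annotations,
    plan_import,
    preview_plan,
    render_database,
    render_frame,
)
from pgdbkit.id_resolution import BatchAbortedError


def rows_for(import_type, *field_tuples):
    from pgdbkit.flatfile_io import IMPORT_COLUMNS
    cols = IMPORT_COLUMNS[import_type]
    return [ImportRow(i + 1, dict(zip(cols, t)))
            for i, t in enumerate(field_tuples)]


def go_rows(*triples):
    return rows_for("go-annotation",
                    *[(p, g, e, "PMID:1", "CURATOR-0001") for p, g, e in triples])


class TestPlanImport:
    def test_valid_rows_one_action_each(self, wired_db):
        plan = plan_import(wired_db, go_rows(
            ("P", "GO:0005737", "EV-EXP-IDA"),
            ("P2", "GO:0005634", "EV-EXP-IDA"),
            ("T", "GO:0003700", "EV-EXP-IMP")), "go-annotation")
        assert len(plan.actions) == 3 and not plan.skipped
        assert plan.search_skipped  # all identifiers were frame IDs

    def test_unresolvable_row_skipped_and_reported(self, wired_db):
        plan = plan_import(wired_db, go_rows(
            ("P", "GO:0005737", "EV-EXP-IDA"),
            ("NO_SUCH_P77", "GO:0005737", "EV-EXP-IDA"),
            ("P2", "GO:0005634", "EV-EXP-IDA")), "go-annotation",
            ImportOptions(on_unresolved="skip"))
        assert len(plan.actions) == 2
        assert [(row, term) for row, term, _ in plan.skipped] == [(2, "NO_SUCH_P77")]

    def test_abort_propagates(self, wired_db):
        with pytest.raises(BatchAbortedError):
            plan_import(wired_db, go_rows(("NO_SUCH_P77", "GO:0005737", "x")),
                        "go-annotation", ImportOptions(on_unresolved="abort"))

    def test_empty_rows_empty_plan(self, wired_db):
        plan = plan_import(wired_db, [], "slot-data")
        assert plan.actions == [] and plan.skipped == []

    def test_db_untouched_by_planning(self, wired_db):
        before = render_database(wired_db)
        plan_import(wired_db, go_rows(("P", "GO:0005737", "EV-EXP-IDA")),
                    "go-annotation")
        assert render_database(wired_db) == before


class TestPreview:
    def test_insert_spans_contain_new_go_id(self, wired_db, go_ref):
        plan = plan_import(wired_db, go_rows(("P", "GO:0005737", "EV-EXP-IDA")),
                           "go-annotation")
        diffs = preview_plan(wired_db, plan, go_ref=go_ref)
        p_diff = next(d for d in diffs if d.frame_id == "P")
        inserted = "".join(t for op, t in p_diff.edit_script if op == "insert")
        assert "GO:0005737" in inserted
        assert render_database(wired_db) == render_database(wired_db)

    def test_noop_action_yields_empty_edit_script(self, wired_db, go_ref):
        opts = ImportOptions(ignore_duplicates=True)
        rows = go_rows(("P", "GO:0005737", "EV-EXP-IDA"))
        wired_db.begin()
        import_go_annotations(wired_db, rows, go_ref, opts)
        wired_db.commit()
        plan = plan_import(wired_db, rows, "go-annotation", opts)
        diffs = preview_plan(wired_db, plan, go_ref=go_ref)
        p_diff = next(d for d in diffs if d.frame_id == "P")
        assert p_diff.edit_script == []

    def test_deletion_preview_has_empty_after_text(self, wired_db):
        plan = plan_import(wired_db, rows_for("delete-frames", ("Gene", "G")),
                           "delete-frames")
        diffs = preview_plan(wired_db, plan)
        by_id = {d.frame_id: d for d in diffs}
        for fid in ("G", "P", "ER", "R"):
            assert by_id[fid].after == ""

    def test_preview_fidelity_edit_script_reconstructs_after(self, wired_db, go_ref):
        plan = plan_import(wired_db, go_rows(
            ("P", "GO:0005737", "EV-EXP-IDA"),
            ("P2", "GO:0016301", "EV-COMP-AINF")), "go-annotation")
        diffs = preview_plan(wired_db, plan, go_ref=go_ref)
        for diff in diffs:
            assert diff.apply() == diff.after
        # applying for real reproduces each predicted after-text
        wired_db.begin()
        apply_plan(wired_db, plan, go_ref=go_ref)
        for diff in diffs:
            got = (render_frame(wired_db.frames[diff.frame_id])
                   if diff.frame_id in wired_db.frames else "")
            assert got == diff.after


class TestApplyPlan:
    def test_requires_open_transaction(self, wired_db, go_ref):
        plan = plan_import(wired_db, go_rows(("P", "GO:0005737", "EV-EXP-IDA")),
                           "go-annotation")
        with pytest.raises(TransactionError):
            apply_plan(wired_db, plan, go_ref=go_ref)

    def test_author_credited_on_every_modified_frame(self, wired_db, go_ref):
        opts = ImportOptions(author="ORG-0001")
        log = import_go_annotations(wired_db, go_rows(
            ("P", "GO:0005737", "EV-EXP-IDA"),
            ("P2", "GO:0005634", "EV-EXP-IDA")), go_ref, opts)
        assert log.n_success == 2 and log.n_fail == 0
        for fid in ("P", "P2"):
            assert wired_db.get(fid).slot_values("CREDITS") == ["ORG-0001"]

    def test_failed_row_does_not_halt_others(self, wired_db):
        # row 1 deletes gene G (and its product P); row 2 then targets P
        rows = rows_for("delete-frames", ("Gene", "G"), ("Polypeptide", "P"),
                        ("Gene", "G2"))
        log = delete_frames_import(wired_db, rows)
        statuses = [e.status for e in log.entries]
        assert statuses == ["success", "fail", "success"]

    def test_log_accounts_for_every_row(self, wired_db, go_ref):
        rows = go_rows(("P", "GO:0005737", "EV-EXP-IDA"),
                       ("GHOST_P42", "GO:0005737", "EV-EXP-IDA"),
                       ("P2", "GO:0099999", "EV-EXP-IDA"))  # absent from ref
        log = import_go_annotations(wired_db, rows, go_ref)
        assert log.n_success + log.n_fail + len(log.skipped) == len(rows)
        assert (log.n_success, log.n_fail, len(log.skipped)) == (1, 1, 1)


class TestIdempotence:
    @pytest.mark.parametrize("import_type,field_tuples", [
        ("slot-data", [("Compound", "PYRUVATE", "SYNONYMS", "2-oxopropanoate")]),
        ("slot-value-annotation",
         [("Compound", "PYRUVATE", "SYNONYMS", "pyruvic acid",
           "CITATIONS", "PMID:777")]),
    ])
    def test_reimport_with_ignore_duplicates_is_noop(self, pyruvate_db,
                                                     import_type, field_tuples):
        opts = ImportOptions(ignore_duplicates=True)
        rows = rows_for(import_type, *field_tuples)
        pyruvate_db.begin()
        apply_plan(pyruvate_db, plan_import(pyruvate_db, rows, import_type, opts))
        pyruvate_db.commit()
        once = render_database(pyruvate_db)
        pyruvate_db.begin()
        log = apply_plan(pyruvate_db,
                         plan_import(pyruvate_db, rows, import_type, opts))
        pyruvate_db.commit()
        assert log.n_fail == 0
        assert render_database(pyruvate_db) == once

    def test_go_reimport_is_noop(self, wired_db, go_ref):
        opts = ImportOptions(ignore_duplicates=True, author="ORG-0001")
        rows = go_rows(("P", "GO:0005737", "EV-EXP-IDA"))
        import_go_annotations(wired_db, rows, go_ref, opts)
        wired_db.commit()
        once = render_database(wired_db)
        log = import_go_annotations(wired_db, rows, go_ref, opts)
        wired_db.commit()
        assert log.n_success == 1
        assert render_database(wired_db) == once


class TestGoImport:
    def test_unseen_go_id_creates_exactly_one_frame(self, wired_db, go_ref):
        assert "GO:0005737" not in wired_db.frames
        import_go_annotations(wired_db, go_rows(("P", "GO:0005737", "EV-EXP-IDA")),
                              go_ref)
        frame = wired_db.get("GO:0005737")
        assert frame.classes == ["GO-Term"]
        assert frame.slot_values("COMMON-NAME") == ["cytoplasm"]
        assert wired_db.get("P").slot_values("GO-TERMS") == ["GO:0005737"]

    def test_shared_go_id_created_once(self, wired_db, go_ref):
        import_go_annotations(wired_db, go_rows(
            ("P", "GO:0005737", "EV-EXP-IDA"),
            ("P2", "GO:0005737", "EV-EXP-IMP")), go_ref)
        assert sum(1 for f in wired_db.frames_of_class("GO-Term")) == 1

    def test_annotations_attached_to_go_value(self, wired_db, go_ref):
        import_go_annotations(wired_db, go_rows(("P", "GO:0005737", "EV-EXP-IDA")),
                              go_ref)
        sv = wired_db.get("P").get_slot_value("GO-TERMS", "GO:0005737")
        assert sv.annotations["CITATIONS"] == ["PMID:1"]
        assert sv.annotations["EVIDENCE"] == ["EV-EXP-IDA"]
        assert sv.annotations["CURATOR"] == ["CURATOR-0001"]
        assert len(sv.annotations["TIMESTAMP"]) == 1

    def test_go_id_missing_from_reference_fails_row(self, wired_db, go_ref):
        log = import_go_annotations(wired_db,
                                    go_rows(("P", "GO:0099999", "EV-EXP-IDA")),
                                    go_ref)
        assert log.n_fail == 1
        assert "GO:0099999" not in wired_db.frames
        assert wired_db.get("P").slot_values("GO-TERMS") == []


class TestRegulationImport:
    def test_sequential_ids_in_input_order(self, wired_db):
        rows = rows_for("create-regulation",
                        ("T", "G", "+"), ("T", "G2", "-"))
        log = create_regulation_frames(wired_db, rows)
        assert log.n_success == 2
        assert wired_db.get("REG-0002").slot_values("REGULATED-ENTITY") == ["G"]
        assert wired_db.get("REG-0003").slot_values("MODE") == ["-"]

    def test_duplicate_interaction_creates_two_frames(self, wired_db):
        rows = rows_for("create-regulation", ("T", "G", "+"), ("T", "G", "+"))
        log = create_regulation_frames(wired_db, rows)
        assert log.n_success == 2
        regs = [f for f in wired_db.frames_of_class("Regulation")
                if f.slot_values("REGULATED-ENTITY") == ["G"]]
        assert len(regs) == 2

    def test_unknown_regulator_fails_row(self, wired_db):
        rows = rows_for("create-regulation", ("NOBODY_P9", "G", "+"))
        log = create_regulation_frames(wired_db, rows)
        assert [e.status for e in log.entries] == ["fail"]
        assert "REG-0002" not in wired_db.frames


class TestDeleteImport:
    def test_log_lists_full_deleted_set(self, wired_db):
        log = delete_frames_import(wired_db, rows_for("delete-frames",
                                                      ("Gene", "fadD")))
        assert log.n_success == 1
        for fid in ("G", "P", "ER", "R"):
            assert fid in log.entries[0].message

    def test_unresolvable_identifier_skipped(self, wired_db):
        log = delete_frames_import(wired_db, rows_for("delete-frames",
                                                      ("Gene", "no-such-gene")))
        assert log.entries == [] and len(log.skipped) == 1

    def test_empty_input_empty_log(self, wired_db):
        log = delete_frames_import(wired_db, [])
        assert log.entries == [] and log.skipped == []
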