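"""Dynamic views, CSV export, bulk import and the substance info page."""

import csv

import pytest

from knowsub import (
    FactHistory,
    Memo,
    MemoLog,
    ResultTable,
    SubstanceStore,
    add_memo,
    evaluate,
    export_table,
    import_substances,
    info_page,
    load_bundled_views,
    mirror_decisions,
    render_view,
    retract,
)
from knowsub.errors import FormatError, NotFoundError, ViewError
from knowsub.fixtures import FixtureSpec, generate_substances, kryptonite_facts
from knowsub.views import ViewDefinition, export_substances, format_table

from conftest import KRYPTONITE


class TestRenderView:
    def test_screening_view_after_derivation(self, store, registry, answers):
        mirror_decisions(store, KRYPTONITE, evaluate(registry, answers))
        table = render_view(store, load_bundled_views()["pbt_screening"])
        assert len(table.rows) == 1
        assert table.rows[0][0] == "Kryptonite"

    def test_view_on_empty_store_is_header_only(self):
        table = render_view(SubstanceStore(), load_bundled_views()["pbt_screening"])
        assert table.columns == ["label", "ec", "cas"] and table.rows == []

    def test_rerender_after_retraction_is_empty(self, store, registry, answers):
        mirror_decisions(store, KRYPTONITE, evaluate(registry, answers))
        reduced = retract(answers, "chronic_NOEC")
        mirror_decisions(store, KRYPTONITE, evaluate(registry, reduced))
        table = render_view(store, load_bundled_views()["pbt_screening"])
        assert table.rows == []

    def test_broken_view_names_itself(self, store):
        with pytest.raises(ViewError, match="bad_view"):
            render_view(store, ViewDefinition("bad_view", "SELECT WHERE {"))

    def test_repeated_render_is_byte_identical(self, store, registry, answers):
        mirror_decisions(store, KRYPTONITE, evaluate(registry, answers))
        view = load_bundled_views()["decision_overview"]
        a = format_table(render_view(store, view))
        b = format_table(render_view(store, view))
        assert a == b


class TestExportTable:
    def test_one_row_view_golden_csv(self, store, tmp_path):
        table = render_view(store, load_bundled_views()["pbt_class"])
        path = tmp_path / "out.csv"
        export_table(table, path)
        assert path.read_bytes() == b"label\r\nKryptonite\r\n"

    def test_empty_table_is_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        export_table(ResultTable(columns=["a", "b"], rows=[]), path)
        assert path.read_bytes() == b"a,b\r\n"

    def test_commas_and_quotes_are_rfc4180_quoted(self, tmp_path):
        table = ResultTable(columns=["v"], rows=[('say "hi", ok',)])
        path = tmp_path / "quoted.csv"
        export_table(table, path)
        assert path.read_bytes() == b'v\r\n"say ""hi"", ok"\r\n'
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        assert rows == [["v"], ['say "hi", ok']]

    def test_tsv_export(self, tmp_path):
        table = ResultTable(columns=["a", "b"], rows=[(1, 2)])
        path = tmp_path / "out.tsv"
        export_table(table, path, "tsv")
        assert path.read_bytes() == b"a\tb\r\n1\t2\r\n"


class TestImportSubstances:
    @pytest.fixture()
    def csv_path(self, tmp_path):
        path = tmp_path / "substances.csv"
        generate_substances(FixtureSpec(n_substances=10, seed=3), csv_path=path)
        return path

    def test_ten_valid_rows_create_ten_substances(self, csv_path):
        store, history = SubstanceStore(), FactHistory()
        summary = import_substances(store, history, csv_path)
        assert summary.created == 10 and summary.merged == 0
        assert len(store.substances()) == 10

    def test_reimport_merges_instead_of_duplicating(self, csv_path):
        store, history = SubstanceStore(), FactHistory()
        import_substances(store, history, csv_path)
        summary = import_substances(store, history, csv_path)
        assert summary.created == 0 and summary.merged == 10
        assert len(store.substances()) == 10

    def test_bad_cas_checksum_rejected_with_reason(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("label,cas\nGood,7732-18-5\nBad,7732-18-4\n")
        store, history = SubstanceStore(), FactHistory()
        summary = import_substances(store, history, path)
        assert summary.created == 1
        assert len(summary.rejected) == 1
        assert "bad_checksum" in summary.rejected[0][1]

    def test_question_columns_become_import_facts(self, tmp_path):
        path = tmp_path / "with_facts.csv"
        path.write_text("label,cas,ThCO2\nA,7732-18-5,45\n")
        store, history = SubstanceStore(), FactHistory()
        summary = import_substances(store, history, path)
        assert summary.facts_recorded == 1
        fact = history.all_facts()[0]
        assert fact.question == "ThCO2" and fact.value == 45
        assert fact.source.value == "import"

    def test_missing_label_header(self, tmp_path):
        path = tmp_path / "noheader.csv"
        path.write_text("name,cas\nA,7732-18-5\n")
        with pytest.raises(FormatError):
            import_substances(SubstanceStore(), FactHistory(), path)

    def test_import_export_lossless_for_identifiers(self, csv_path, tmp_path):
        store, history = SubstanceStore(), FactHistory()
        import_substances(store, history, csv_path)
        out = tmp_path / "export.csv"
        export_substances(store, out)
        with open(csv_path, newline="") as fh:
            original = {
                (r["label"], r["ec"], r["cas"]) for r in csv.DictReader(fh)
            }
        with open(out, newline="") as fh:
            exported = {
                (r["label"], r["ec"], r["cas"]) for r in csv.DictReader(fh)
            }
        assert exported == original


class TestInfoPage:
    def test_kryptonite_page_sections(self, store, registry):
        history = FactHistory()
        for fact in kryptonite_facts():
            history.record_fact(fact)
        memos = MemoLog()
        add_memo(store, memos, Memo(id="m1", substance="Kryptonite", title="Toxic",
                                    attached_decision="T"), registry)
        page = info_page(store, registry, history, "Kryptonite", memos)
        assert "bioaccumulative, persistent, toxic" in page
        assert "PBT: **established**" in page
        assert "Toxic" in page
        # combining module (PBT) section comes before the per-criterion ones
        assert page.index("### PBT") < page.index("### Persistence")

    def test_substance_without_facts(self, store, registry):
        page = info_page(store, registry, FactHistory(), "Kryptonite", MemoLog())
        assert "none derived" in page
        assert "no facts recorded" in page

    def test_new_memo_appears_first(self, store, registry):
        memos = MemoLog()
        add_memo(store, memos, Memo(id="m1", substance="Kryptonite", title="older"), registry)
        add_memo(store, memos, Memo(id="m2", substance="Kryptonite", title="newer"), registry)
        page = info_page(store, registry, FactHistory(), "Kryptonite", memos)
        assert page.index("newer") < page.index("older")

    def test_unknown_substance(self, store, registry):
        with pytest.raises(NotFoundError):
            info_page(store, registry, FactHistory(), "Adamantium", MemoLog())
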