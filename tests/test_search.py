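"""Query parsing, full-text matching vs the brute-force oracle, SQL, conversion."""

import random

import pytest

from _oracle import brute_force_search, grammar_queries
from sramine import synth
from sramine.errors import QuerySyntaxError, ReadOnlyError, UnknownColumnError
from sramine.metastore import MetaStore
from sramine.search import (And, ColumnQualified, Near, Or, Phrase, Prefix,
                            Term, convert_accessions, full_text_search,
                            parse_query, sql_query)
from sramine.sra_xml import ExperimentRecord, RunRecord, StudyRecord


class TestParseQuery:
    @pytest.mark.parametrize("text, expected", [
        ("breast cancer", And((Term("breast"), Term("cancer")))),
        ("Carcino*", Prefix("Carcino")),
        ('"breast cancer"', Phrase(("breast", "cancer"))),
        ("breast OR cancer", Or((Term("breast"), Term("cancer")))),
        ("breast NEAR/3 cancer", Near(Term("breast"), Term("cancer"), 3)),
        ("breast NEAR cancer", Near(Term("breast"), Term("cancer"), 10)),
        ("study_abstract:cancer", ColumnQualified("study_abstract", Term("cancer"))),
        ('study_abstract:"breast cancer"',
         ColumnQualified("study_abstract", Phrase(("breast", "cancer")))),
        # lowercase 'or' is an ordinary term, not the operator
        ("breast or cancer", And((Term("breast"), Term("or"), Term("cancer")))),
        ('"breast cancer" profiling',
         And((Phrase(("breast", "cancer")), Term("profiling")))),
    ])
    def test_grammar(self, text, expected):
        assert parse_query(text) == expected

    @pytest.mark.parametrize("bad", ['"unbalanced', "", "   ", "OR cancer",
                                     "breast OR", "NEAR/2 cancer", "!!!"])
    def test_syntax_errors(self, bad):
        with pytest.raises(QuerySyntaxError):
            parse_query(bad)


class TestFullTextSearch:
    def test_phrase_query_returns_linked_runs_with_study_columns(self, paper_store):
        result = full_text_search(paper_store, "breast cancer", ["run", "study"])
        assert len(result) == 6
        assert "study_abstract" in result.columns and "run_accession" in result.columns
        frame = result.to_frame()
        assert set(frame["study_accession"]) == {"DRP000001"}

    def test_phrase_does_not_match_split_words(self):
        store = MetaStore.create(":memory:")
        store.load_records([StudyRecord(study_accession="SRP000001",
                                        study_abstract="breast ductal cancer"),
                            ExperimentRecord(experiment_accession="SRX000001",
                                             study_accession="SRP000001")])
        store.build_denormalized()
        assert len(full_text_search(store, '"breast cancer"', ["study"])) == 0
        assert len(full_text_search(store, "breast cancer", ["study"])) == 1

    def test_no_match_keeps_full_header(self, paper_store):
        result = full_text_search(paper_store, "zzznosuchtoken", ["run", "study"])
        assert result.rows == []
        assert "run_accession" in result.columns
        assert "study_accession" in result.columns

    def test_empty_out_types_rejected(self, paper_store):
        with pytest.raises(ValueError):
            full_text_search(paper_store, "breast", [])

    def test_unknown_column_named_in_error(self, paper_store):
        with pytest.raises(UnknownColumnError, match="no_such_col"):
            full_text_search(paper_store, "no_such_col:breast", ["study"])

    @pytest.mark.parametrize("seed", [3, 17, 42])
    def test_matches_brute_force_oracle(self, seed):
        """FTS execution equals the stated matching rules on random fixtures."""
        store = synth.build_store(synth.SynthSpec(
            seed=seed, n_studies=3,
            planted_phrases=[("study", "study_abstract", "breast cancer"),
                             ("run", "run_attribute", "note: breast ductal cancer")]))
        rng = random.Random(seed)
        for expr in grammar_queries(store, rng):
            for out_types in (["run", "study"], ["study"], ["sample", "run"]):
                columns, expected = brute_force_search(store, expr, out_types)
                got = full_text_search(store, expr, out_types)
                assert got.columns == columns
                assert set(got.rows) == expected, f"mismatch for {expr!r}"

    @pytest.mark.parametrize("seed", [5, 23])
    def test_monotonicity(self, seed):
        """Phrase results are a subset of And; Term of a matching Prefix."""
        store = synth.build_store(synth.SynthSpec(seed=seed, n_studies=2))
        word = "sequencing"
        phrase_rows = set(full_text_search(
            store, Phrase(("cancer", word)), ["run"]).rows)
        and_rows = set(full_text_search(
            store, And((Term("cancer"), Term(word))), ["run"]).rows)
        assert phrase_rows <= and_rows
        term_rows = set(full_text_search(store, Term(word), ["run"]).rows)
        prefix_rows = set(full_text_search(store, Prefix(word[:4]), ["run"]).rows)
        assert term_rows <= prefix_rows

    def test_projection_consistency(self, paper_store):
        """Study set is the same whether or not run columns are projected."""
        both = full_text_search(paper_store, "breast cancer", ["run", "study"])
        only = full_text_search(paper_store, "breast cancer", ["study"])
        frame = both.to_frame()
        assert set(frame["study_accession"]) == {r[0] for r in only.rows}


class TestSqlQuery:
    def test_group_by_library_strategy(self):
        store = MetaStore.create(":memory:")
        store.load_records(
            [ExperimentRecord(experiment_accession=f"SRX00000{i}",
                              library_strategy="WGS") for i in range(1, 4)]
            + [ExperimentRecord(experiment_accession=f"SRX00010{i}",
                                library_strategy="RNA-Seq") for i in range(1, 3)])
        result = sql_query(
            store, "SELECT library_strategy, count(*) AS Runs FROM experiment "
                   "GROUP BY library_strategy ORDER BY Runs DESC")
        assert result.columns == ["library_strategy", "Runs"]
        assert result.rows == [("WGS", 3), ("RNA-Seq", 2)]

    def test_count_on_empty_store(self):
        store = MetaStore.create(":memory:")
        assert sql_query(store, "SELECT count(*) FROM run").rows == [(0,)]

    @pytest.mark.parametrize("stmt", ["DROP TABLE run", "DELETE FROM run",
                                      "INSERT INTO run (run_accession) "
                                      "VALUES ('SRR000001')"])
    def test_writes_refused(self, stmt):
        store = MetaStore.create(":memory:")
        with pytest.raises(ReadOnlyError):
            sql_query(store, stmt)
        # store untouched and still queryable
        assert sql_query(store, "SELECT count(*) FROM run").rows == [(0,)]


class TestConvertAccessions:
    @pytest.fixture()
    def graph_store(self):
        store = MetaStore.create(":memory:")
        store.load_records([
            StudyRecord(study_accession="SRP000001"),
            ExperimentRecord(experiment_accession="SRX000001",
                             study_accession="SRP000001"),
            ExperimentRecord(experiment_accession="SRX000002",
                             study_accession="SRP000001"),
            RunRecord(run_accession="SRR000001", experiment_accession="SRX000001"),
            RunRecord(run_accession="SRR000002", experiment_accession="SRX000001"),
            RunRecord(run_accession="SRR000003", experiment_accession="SRX000002"),
        ])
        store.build_denormalized()
        return store

    def test_study_expands_to_all_runs(self, graph_store):
        frame = convert_accessions(graph_store, ["SRP000001"])
        assert len(frame) == 3
        assert set(frame["study"]) == {"SRP000001"}
        assert set(frame["run"]) == {"SRR000001", "SRR000002", "SRR000003"}

    def test_run_resolves_ancestry(self, graph_store):
        frame = convert_accessions(graph_store, ["SRR000002"])
        assert len(frame) == 1
        assert frame.iloc[0]["experiment"] == "SRX000001"
        assert frame.iloc[0]["study"] == "SRP000001"

    def test_malformed_accession_is_an_error(self, graph_store):
        with pytest.raises(ValueError, match="BAD1"):
            convert_accessions(graph_store, ["BAD1"])

    def test_unknown_accession_warns_and_yields_nothing(self, graph_store):
        with pytest.warns(UserWarning, match="SRR999999"):
            frame = convert_accessions(graph_store, ["SRR999999"])
        assert len(frame) == 0

    def test_closure_idempotent_extensive_monotone(self, graph_store):
        first = convert_accessions(graph_store, ["SRP000001"])
        accessions = sorted({a for col in first.columns
                             for a in first[col] if a is not None})
        second = convert_accessions(graph_store, accessions)
        assert sorted(map(tuple, first.values.tolist())) == \
            sorted(set(map(tuple, second.values.tolist())))
        # extensive: a run input appears in its own closure
        one = convert_accessions(graph_store, ["SRR000003"])
        assert "SRR000003" in set(one["run"])
        # monotone: closure of a subset is a subset of the closure
        sub = convert_accessions(graph_store, ["SRX000001"])
        assert set(map(tuple, sub.values.tolist())) <= \
            set(map(tuple, first.values.tolist()))
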