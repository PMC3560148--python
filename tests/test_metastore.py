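"""Store schema, ingestion semantics, and denormalization correctness."""

import pytest

from sramine import metastore, synth
from sramine.errors import StoreError
from sramine.metastore import MetaStore, TABLE_COLUMNS
from sramine.sra_xml import (ExperimentRecord, KINDS, RunRecord, SampleRecord,
                             StudyRecord, SubmissionRecord)


def _graph(n_exp_runs=((2,), (1,))):
    """A small hand-built record graph: 1 study, experiments with given runs."""
    records = [SubmissionRecord(submission_accession="SRA000001"),
               StudyRecord(study_accession="SRP000001",
                           study_abstract="breast cancer study",
                           submission_accession="SRA000001"),
               SampleRecord(sample_accession="SRS000001", taxon_id=9606)]
    run_no = 0
    for i, runs in enumerate(n_exp_runs, 1):
        records.append(ExperimentRecord(
            experiment_accession=f"SRX{i:06d}", study_accession="SRP000001",
            sample_accession="SRS000001", library_strategy="WGS"))
        for _ in range(runs[0] if runs else 0):
            run_no += 1
            records.append(RunRecord(run_accession=f"SRR{run_no:06d}",
                                     experiment_accession=f"SRX{i:06d}"))
    return records


class TestCreateSchema:
    def test_fresh_store_has_eight_tables(self, tmp_path):
        store = MetaStore.create(tmp_path / "t.db")
        assert sorted(store.tables()) == sorted(
            ["submission", "study", "sample", "experiment", "run",
             "sra", "col_desc", "meta_info"])
        for kind in KINDS:
            assert store.conn.execute(
                f"SELECT count(*) FROM {kind}").fetchone()[0] == 0
        assert store.schema_version == 1

    def test_existing_file_refused_without_overwrite(self, tmp_path):
        path = tmp_path / "t.db"
        MetaStore.create(path).close()
        with pytest.raises(StoreError, match="exists"):
            MetaStore.create(path)
        MetaStore.create(path, overwrite=True)  # explicit overwrite allowed

    def test_col_desc_covers_every_entity_column(self, tmp_path):
        store = MetaStore.create(tmp_path / "t.db")
        expected = sum(len(cols) for cols in TABLE_COLUMNS.values())
        assert store.conn.execute(
            "SELECT count(*) FROM col_desc").fetchone()[0] == expected

    def test_unwritable_path_raises(self):
        with pytest.raises(StoreError):
            MetaStore.create("/nonexistent-dir/sub/t.db")


class TestLoad:
    def test_counts_per_kind(self):
        store = MetaStore.create(":memory:")
        report = store.load_records(
            [RunRecord(run_accession=f"SRR00000{i}") for i in range(1, 4)]
            + [ExperimentRecord(experiment_accession="SRX000001")])
        assert report.counts == {"run": 3, "experiment": 1}

    def test_reload_same_accession_replaces(self):
        store = MetaStore.create(":memory:")
        store.load_records([RunRecord(run_accession="SRR000001", run_alias="a")])
        store.load_records([RunRecord(run_accession="SRR000001", run_alias="b")])
        rows = store.conn.execute("SELECT run_alias FROM run").fetchall()
        assert rows == [("b",)]

    def test_bad_accession_rejected_but_load_continues(self):
        store = MetaStore.create(":memory:")
        report = store.load_records([RunRecord(run_accession="XX1"),
                                     RunRecord(run_accession="SRR000002")])
        assert report.counts == {"run": 1}
        assert len(report.rejected) == 1
        assert report.rejected[0][1] == "XX1"


class TestDenormalized:
    def test_one_row_per_run(self):
        store = MetaStore.create(":memory:")
        store.load_records(_graph(((2,), (1,))))
        assert store.build_denormalized() == 3
        study_cols = store.conn.execute(
            "SELECT DISTINCT study_accession FROM sra").fetchall()
        assert study_cols == [("SRP000001",)]

    def test_runless_experiment_kept_with_null_run(self):
        store = MetaStore.create(":memory:")
        store.load_records(_graph(((2,), (0,))))
        assert store.build_denormalized() == 3  # 2 runs + 1 run-less experiment
        row = store.conn.execute(
            "SELECT run_accession, experiment_accession FROM sra "
            "WHERE run_accession IS NULL").fetchone()
        assert row == (None, "SRX000002")

    def test_orphan_run_reported_with_null_experiment_side(self):
        store = MetaStore.create(":memory:")
        store.load_records([RunRecord(run_accession="SRR000099",
                                      experiment_accession="SRX999999")])
        assert store.build_denormalized() == 1
        row = store.conn.execute(
            "SELECT run_accession, study_accession FROM sra").fetchone()
        assert row == ("SRR000099", None)
        assert store.orphan_report() == {"run_without_experiment": ["SRR000099"]}

    def test_idempotent(self):
        store = MetaStore.create(":memory:")
        store.load_records(_graph())
        first = store.build_denormalized()
        second = store.build_denormalized()
        assert first == second
        assert store.conn.execute("SELECT count(*) FROM sra").fetchone()[0] == first

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_row_conservation(self, seed):
        """rows(sra) == rows(run) + experiments with zero runs."""
        store = synth.build_store(synth.SynthSpec(seed=seed, n_studies=3))
        n_sra, n_run, n_runless = [store.conn.execute(q).fetchone()[0] for q in (
            "SELECT count(*) FROM sra", "SELECT count(*) FROM run",
            "SELECT count(*) FROM experiment WHERE experiment_accession NOT IN "
            "(SELECT experiment_accession FROM run "
            " WHERE experiment_accession IS NOT NULL)")]
        assert n_sra == n_run + n_runless

    @pytest.mark.parametrize("seed", [2, 7])
    def test_join_matches_dictionary_oracle(self, seed):
        """Each denormalized row equals the brute-force dict join of its parts."""
        spec = synth.SynthSpec(seed=seed, n_studies=3)
        records = synth.generate_records(spec)
        store = synth.build_store(spec)
        by_acc = {kind: {getattr(r, f"{kind}_accession"): r
                         for r in records[kind]} for kind in KINDS}
        for row in store.conn.execute(
                "SELECT run_accession, experiment_accession, study_accession, "
                "sample_accession, submission_accession, run_alias, "
                "library_strategy, study_abstract, scientific_name, "
                "submission_center_name FROM sra"):
            (run_acc, exp_acc, study_acc, sample_acc, sub_acc,
             run_alias, strategy, abstract, sci_name, sub_center) = row
            run = by_acc["run"].get(run_acc)
            exp = by_acc["experiment"].get(exp_acc)
            assert exp_acc == (run.experiment_accession if run else exp.experiment_accession)
            assert study_acc == exp.study_accession
            assert sample_acc == exp.sample_accession
            assert run_alias == (run.run_alias if run else None)
            assert strategy == exp.library_strategy
            assert abstract == by_acc["study"][study_acc].study_abstract
            assert sci_name == by_acc["sample"][sample_acc].scientific_name
            assert sub_center == by_acc["submission"][sub_acc].center_name


class TestColDescriptions:
    def test_inventory(self):
        store = MetaStore.create(":memory:")
        descs = store.col_descriptions()
        keyed = {(d.table_name, d.field_name): d.description for d in descs}
        assert len(keyed) == len(descs), "duplicate (table, field) pair"
        assert keyed[("experiment", "library_strategy")]  # non-empty description
        assert {d.table_name for d in descs} == set(KINDS)
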