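"""On-disk relational store for SRA metadata.

The store is a single SQLite file holding:

* five entity tables — ``submission``, ``study``, ``sample``, ``experiment``,
  ``run`` — one row per accession, columns mirroring the record types;
* ``sra`` — a denormalized run-granularity join of all five entities, the
  unit of full-text matching (one row per run, plus one row per experiment
  that has no runs so run-less studies are never silently lost);
* ``sra_ft`` — an FTS5 full-text index over every ``sra`` column;
* ``col_desc`` — human-readable description of every entity-table column;
* ``meta_info`` — schema version and creation timestamp.

Being plain SQLite, the file is usable from any client (python, R, perl,
java, a shell) independently of this package.
"""

from __future__ import annotations

import datetime
import os
import sqlite3
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import sra_xml
from .errors import StoreError
from .sra_xml import KINDS, RECORD_TYPES, record_fields, record_kind, validate_accession

SCHEMA_VERSION = 1

_INT_FIELDS = {"taxon_id", "spot_length", "spots", "bases"}

#: entity order used when assembling the denormalized row
_JOIN_ORDER = ("run", "experiment", "study", "sample", "submission")

#: columns that act as graph keys; they appear once in `sra`, coalesced
#: across every table that carries them.
_KEY_COLUMNS = ("run_accession", "experiment_accession", "study_accession",
                "sample_accession", "submission_accession")


def _column_type(name: str) -> str:
    return "INTEGER" if name in _INT_FIELDS else "TEXT"


TABLE_COLUMNS: Dict[str, List[str]] = {kind: record_fields(kind) for kind in KINDS}

COLUMN_DESCRIPTIONS: Dict[Tuple[str, str], str] = {
    ("submission", "submission_accession"): "SRA submission accession ({S,E,D}RA#)",
    ("submission", "submission_alias"): "Submitter-assigned alias of the submission",
    ("submission", "center_name"): "Sequencing center that made the submission",
    ("submission", "broker_name"): "Broker that deposited the submission, if any",
    ("submission", "lab_name"): "Laboratory within the submitting center",
    ("submission", "submission_date"): "Date the submission was made (as submitted)",
    ("submission", "submission_comment"): "Free-text comment attached to the submission",
    ("submission", "submission_attribute"): "Delimited tag: value submission attributes",
    ("study", "study_accession"): "SRA study accession ({S,E,D}RP#)",
    ("study", "study_alias"): "Submitter-assigned alias of the study",
    ("study", "study_title"): "Short descriptive study title",
    ("study", "study_type"): "Controlled-vocabulary study type",
    ("study", "study_abstract"): "Free-text abstract describing the study",
    ("study", "center_name"): "Center that owns the study",
    ("study", "center_project_name"): "Center-internal project name",
    ("study", "study_description"): "Longer free-text study description",
    ("study", "study_url_link"): "Delimited label: URL links for the study",
    ("study", "study_attribute"): "Delimited tag: value study attributes",
    ("study", "submission_accession"): "Submission this study arrived in",
    ("sample", "sample_accession"): "SRA sample accession ({S,E,D}RS#)",
    ("sample", "sample_alias"): "Submitter-assigned alias of the sample",
    ("sample", "taxon_id"): "NCBI taxonomy identifier of the organism",
    ("sample", "scientific_name"): "Scientific (Latin) name of the organism",
    ("sample", "common_name"): "Common name of the organism",
    ("sample", "description"): "Free-text sample description",
    ("sample", "sample_attribute"): "Delimited tag: value sample attributes",
    ("sample", "submission_accession"): "Submission this sample arrived in",
    ("experiment", "experiment_accession"): "SRA experiment accession ({S,E,D}RX#)",
    ("experiment", "experiment_alias"): "Submitter-assigned alias of the experiment",
    ("experiment", "title"): "Short descriptive experiment title",
    ("experiment", "study_accession"): "Study the experiment belongs to",
    ("experiment", "sample_accession"): "Sample the library was constructed from",
    ("experiment", "design_description"): "Free-text description of the design",
    ("experiment", "library_name"): "Submitter's name for the sequencing library",
    ("experiment", "library_strategy"): "Controlled vocabulary: WGS, WXS, RNA-Seq, ...",
    ("experiment", "library_source"): "Source material: GENOMIC, TRANSCRIPTOMIC, ...",
    ("experiment", "library_selection"): "Selection/enrichment method for the library",
    ("experiment", "library_layout"): "SINGLE or PAIRED read layout",
    ("experiment", "library_construction_protocol"): "Free-text library protocol",
    ("experiment", "spot_length"): "Number of bases per spot (read plus technical)",
    ("experiment", "platform"): "Sequencing platform family (ILLUMINA, LS454, ...)",
    ("experiment", "instrument_model"): "Specific instrument model used",
    ("experiment", "platform_parameters"): "Delimited platform-specific parameters",
    ("experiment", "experiment_attribute"): "Delimited tag: value experiment attributes",
    ("experiment", "submission_accession"): "Submission this experiment arrived in",
    ("run", "run_accession"): "SRA run accession ({S,E,D}RR#)",
    ("run", "run_alias"): "Submitter-assigned alias of the run",
    ("run", "run_date"): "Date the run was performed (as submitted)",
    ("run", "updated_date"): "Date the run record was last updated",
    ("run", "spots"): "Number of spots (sequenced clusters/reads) in the run",
    ("run", "bases"): "Total number of bases in the run",
    ("run", "run_center"): "Center that performed the run",
    ("run", "experiment_accession"): "Experiment this run belongs to",
    ("run", "run_attribute"): "Delimited tag: value run attributes",
    ("run", "submission_accession"): "Submission this run arrived in",
}


def _sra_column_plan():
    """Plan the denormalized table: [(sra_column, entity, entity_column)].

    Graph-key accessions appear once (coalesced across carriers); any other
    column name shared by several entity tables is disambiguated with the
    entity prefix (e.g. study_center_name / submission_center_name).
    """
    occurrences: Dict[str, List[str]] = {}
    for entity in _JOIN_ORDER:
        for col in TABLE_COLUMNS[entity]:
            occurrences.setdefault(col, []).append(entity)
    plan = []
    emitted_keys = set()
    for entity in _JOIN_ORDER:
        for col in TABLE_COLUMNS[entity]:
            if col in _KEY_COLUMNS:
                if col not in emitted_keys:
                    emitted_keys.add(col)
                    plan.append((col, None, col))  # coalesced key
            elif len(occurrences[col]) > 1:
                plan.append((f"{entity}_{col}", entity, col))
            else:
                plan.append((col, entity, col))
    return plan


SRA_COLUMN_PLAN = _sra_column_plan()
SRA_COLUMNS = [c for c, _, _ in SRA_COLUMN_PLAN]

#: which `sra` columns belong to each entity's projection (keys included)
ENTITY_SRA_COLUMNS: Dict[str, List[str]] = {}
for _kind in KINDS:
    cols = []
    for sra_col, entity, col in SRA_COLUMN_PLAN:
        if entity == _kind:
            cols.append(sra_col)
        elif entity is None:
            # graph keys: a kind projects its own accession plus the keys its
            # own table carries (e.g. run carries experiment + submission).
            if col in TABLE_COLUMNS[_kind]:
                cols.append(sra_col)
    # lead with the entity's own accession so projections (and the result
    # ordering derived from the leading column) start from it
    own = f"{_kind}_accession"
    cols.remove(own)
    ENTITY_SRA_COLUMNS[_kind] = [own] + cols


@dataclass
class ColumnDescription:
    table_name: str
    field_name: str
    description: str


@dataclass
class LoadReport:
    counts: Dict[str, int] = field(default_factory=dict)
    rejected: List[Tuple[str, Optional[str], str]] = field(default_factory=list)

    def __getitem__(self, kind):
        return self.counts.get(kind, 0)


class MetaStore:
    """Handle on the SQLite metadata store."""

    def __init__(self, path, conn: sqlite3.Connection):
        self.path = path
        self.conn = conn
        self.orphans: Dict[str, List[str]] = {}

    # -- lifecycle ---------------------------------------------------------

    @classmethod
    def create(cls, path, overwrite: bool = False) -> "MetaStore":
        """Create a fresh store with the full schema at ``path``.

        ``path`` may be ``":memory:"`` for an ephemeral store.  An existing
        file is refused unless ``overwrite`` is set.
        """
        if path != ":memory:":
            if os.path.exists(path):
                if not overwrite:
                    raise StoreError(
                        f"{path} already exists; pass overwrite=True to replace it")
                os.remove(path)
        try:
            conn = sqlite3.connect(path)
        except sqlite3.OperationalError as exc:
            raise StoreError(f"cannot create store at {path}: {exc}") from exc
        store = cls(path, conn)
        store._create_schema()
        return store

    @classmethod
    def open(cls, path) -> "MetaStore":
        if path != ":memory:" and not os.path.exists(path):
            raise StoreError(f"no such store: {path}")
        return cls(path, sqlite3.connect(path))

    def close(self):
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- schema ------------------------------------------------------------

    def _create_schema(self):
        cur = self.conn.cursor()
        for kind in KINDS:
            cols = ",\n  ".join(
                f"{c} {_column_type(c)}"
                + (" PRIMARY KEY" if c == f"{kind}_accession" else "")
                for c in TABLE_COLUMNS[kind])
            cur.execute(f"CREATE TABLE {kind} (\n  {cols}\n)")
        sra_cols = ",\n  ".join(f"{sra_col} {_column_type(col)}"
                                for sra_col, _, col in SRA_COLUMN_PLAN)
        cur.execute(f"CREATE TABLE sra (\n  {sra_cols}\n)")
        cur.execute(
            "CREATE VIRTUAL TABLE sra_ft USING fts5({}, content='sra', "
            "content_rowid='rowid')".format(", ".join(SRA_COLUMNS)))
        cur.execute("CREATE TABLE col_desc ("
                    "table_name TEXT, field_name TEXT, description TEXT, "
                    "ordinal INTEGER, PRIMARY KEY (table_name, field_name))")
        for kind in KINDS:
            for i, col in enumerate(TABLE_COLUMNS[kind]):
                cur.execute(
                    "INSERT INTO col_desc VALUES (?,?,?,?)",
                    (kind, col, COLUMN_DESCRIPTIONS[(kind, col)], i))
        cur.execute("CREATE TABLE meta_info (name TEXT PRIMARY KEY, value TEXT)")
        now = datetime.datetime.now(datetime.timezone.utc).isoformat()
        cur.executemany("INSERT INTO meta_info VALUES (?,?)",
                        [("schema_version", str(SCHEMA_VERSION)), ("created", now)])
        self.conn.commit()

    @property
    def schema_version(self) -> int:
        row = self.conn.execute(
            "SELECT value FROM meta_info WHERE name='schema_version'").fetchone()
        return int(row[0])

    def tables(self):
        """User-facing tables (the FTS index and its shadows are internal)."""
        return [r[0] for r in self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type IN ('table','view') "
            "AND name NOT LIKE 'sqlite_%' AND name NOT LIKE 'sra_ft%'")]

    # -- ingestion ----------------------------------------------------------

    def load_records(self, records) -> LoadReport:
        """Upsert parsed records into their entity tables.

        Re-loading an accession replaces the previous row.  Records with an
        invalid accession are rejected (and reported) without aborting the
        load.  The denormalized table is left stale; call
        :meth:`build_denormalized` afterwards.
        """
        report = LoadReport()
        cur = self.conn.cursor()
        for record in records:
            kind = record_kind(record)
            acc = sra_xml.accession_of(record)
            if not validate_accession(kind, acc):
                report.rejected.append((kind, acc, f"invalid {kind} accession {acc!r}"))
                continue
            cols = TABLE_COLUMNS[kind]
            cur.execute(
                f"INSERT OR REPLACE INTO {kind} ({', '.join(cols)}) "
                f"VALUES ({', '.join('?' * len(cols))})",
                [getattr(record, c) for c in cols])
            report.counts[kind] = report.counts.get(kind, 0) + 1
        self.conn.commit()
        return report

    # -- denormalization -----------------------------------------------------

    def _select_exprs(self, with_run: bool):
        exprs = []
        carriers = {
            "run_accession": ["run"],
            "experiment_accession": ["run", "experiment"],
            "study_accession": ["experiment", "study"],
            "sample_accession": ["experiment", "sample"],
            "submission_accession": ["run", "experiment", "study", "sample",
                                     "submission"],
        }
        for sra_col, entity, col in SRA_COLUMN_PLAN:
            if entity is None:
                parts = [f"{t}.{col}" for t in carriers[col]
                         if with_run or t != "run"]
                if not parts:
                    expr = "NULL"
                elif len(parts) == 1:
                    expr = parts[0]
                else:
                    expr = f"COALESCE({', '.join(parts)})"
            elif entity == "run" and not with_run:
                expr = "NULL"
            else:
                expr = f"{entity}.{col}"
            exprs.append(f"{expr} AS {sra_col}")
        return ",\n  ".join(exprs)

    def build_denormalized(self) -> int:
        """(Re)build the ``sra`` join table and its full-text index.

        One row per run (left-joined through experiment to study, sample and
        submission) plus one row per experiment with no runs.  Orphan foreign
        keys yield rows with nulls on the missing side and are listed in
        :attr:`orphans`.  Idempotent.  Returns the ``sra`` row count.
        """
        cur = self.conn.cursor()
        cur.execute("DELETE FROM sra")
        join_tail = (
            "LEFT JOIN study ON experiment.study_accession = study.study_accession\n"
            "LEFT JOIN sample ON experiment.sample_accession = sample.sample_accession\n")
        cur.execute(
            f"INSERT INTO sra ({', '.join(SRA_COLUMNS)})\n"
            f"SELECT\n  {self._select_exprs(with_run=True)}\n"
            "FROM run\n"
            "LEFT JOIN experiment "
            "ON run.experiment_accession = experiment.experiment_accession\n"
            + join_tail +
            "LEFT JOIN submission ON COALESCE(run.submission_accession, "
            "experiment.submission_accession, study.submission_accession, "
            "sample.submission_accession) = submission.submission_accession")
        cur.execute(
            f"INSERT INTO sra ({', '.join(SRA_COLUMNS)})\n"
            f"SELECT\n  {self._select_exprs(with_run=False)}\n"
            "FROM experiment\n"
            + join_tail +
            "LEFT JOIN submission ON COALESCE(experiment.submission_accession, "
            "study.submission_accession, sample.submission_accession) "
            "= submission.submission_accession\n"
            "WHERE experiment.experiment_accession NOT IN "
            "(SELECT experiment_accession FROM run "
            " WHERE experiment_accession IS NOT NULL)")
        cur.execute("INSERT INTO sra_ft(sra_ft) VALUES ('rebuild')")
        self.orphans = self._find_orphans()
        self.conn.commit()
        return cur.execute("SELECT count(*) FROM sra").fetchone()[0]

    def _find_orphans(self):
        queries = {
            "run_without_experiment":
                "SELECT run_accession FROM run WHERE experiment_accession IS NOT NULL "
                "AND experiment_accession NOT IN "
                "(SELECT experiment_accession FROM experiment)",
            "experiment_without_study":
                "SELECT experiment_accession FROM experiment "
                "WHERE study_accession IS NOT NULL "
                "AND study_accession NOT IN (SELECT study_accession FROM study)",
            "experiment_without_sample":
                "SELECT experiment_accession FROM experiment "
                "WHERE sample_accession IS NOT NULL "
                "AND sample_accession NOT IN (SELECT sample_accession FROM sample)",
        }
        found = {}
        for name, sql in queries.items():
            hits = [r[0] for r in self.conn.execute(sql)]
            if hits:
                found[name] = hits
        return found

    def orphan_report(self):
        return dict(self.orphans)

    # -- introspection -------------------------------------------------------

    def col_descriptions(self) -> List[ColumnDescription]:
        """Full column inventory of the entity tables, in stable order."""
        rows = self.conn.execute(
            "SELECT table_name, field_name, description FROM col_desc "
            "ORDER BY table_name, ordinal")
        return [ColumnDescription(*r) for r in rows]

    def export_records(self, kind: str):
        """Read an entity table back as typed records (inverse of load)."""
        cols = TABLE_COLUMNS[kind]
        rows = self.conn.execute(
            f"SELECT {', '.join(cols)} FROM {kind} ORDER BY {kind}_accession")
        return [RECORD_TYPES[kind](**dict(zip(cols, row))) for row in rows]


# convenience wrappers mirroring the functional interface -------------------

def create_schema(path, overwrite: bool = False) -> MetaStore:
    return MetaStore.create(path, overwrite=overwrite)


def load_records(store: MetaStore, records) -> LoadReport:
    return store.load_records(records)


def build_denormalized(store: MetaStore) -> int:
    return store.build_denormalized()


def col_descriptions(store: MetaStore) -> List[ColumnDescription]:
    return store.col_descriptions()
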