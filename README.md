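# sramine

Query and use public next-generation sequencing metadata from the Sequence
Read Archive (SRA) — the repository mirrored by NCBI, EBI (ENA) and DDBJ —
from Python or the shell.

The SRA describes every deposit with five linked metadata objects, each with
its own accession:

| object     | accession | relation                                  |
|------------|-----------|-------------------------------------------|
| submission | `{S,E,D}RA#` | owns everything below                   |
| study      | `{S,E,D}RP#` | groups experiments                      |
| sample     | `{S,E,D}RS#` | biological material of an experiment    |
| experiment | `{S,E,D}RX#` | one sequencing library (study + sample) |
| run        | `{S,E,D}RR#` | one instrument run of an experiment     |

`sramine` parses SRA-format XML object sets faithfully (no curation or
recoding) into a five-table SQLite store, adds a **denormalized run-level
join** of all five entities, and indexes every column of that join with
SQLite FTS5.  On top of the store it provides:

- **Full-text search** with a Google-like syntax — terms, `"exact phrases"`,
  `prefix*`, uppercase `OR`, proximity `NEAR/k`, and `column:term`
  qualifiers — projected onto whichever entities you ask for;
- **Arbitrary read-only SQL** (the store is a plain SQLite file, usable from
  any other client too), with per-column documentation via
  `col_descriptions`;
- **Accession resolution** across the entity graph (give it a study, get its
  runs and everything in between);
- **File location and bulk download**: deterministic ENA fastq paths
  (`vol1/fastq/` keyed by the first six accession characters) and NCBI
  `ByRun` SRA-container paths, optional server probing for size/date, and a
  resumable, idempotent downloader;
- **IGV remote control** over the genome browser's TCP command port
  (`genome`, `load`, `goto`, `snapshot`, ...), plus IGV session-file writing;
- A **synthetic submission generator** so the whole pipeline is testable
  offline and reproducibly (same seed, byte-identical XML).

## Worked example

Build a small demonstration store — one DDBJ breast-cancer transcriptome
study with six runs of known content — and search it:

```python
from sramine import synth, full_text_search, sql_query

store = synth.paper_example_fixture("sra.db")
rs = full_text_search(store, '"breast cancer"', ["run", "study"]).to_frame()
print(rs[["run_accession", "run_alias", "spots"]])
```

or, from the shell:

```
$ sramine search '"breast cancer"' --out-types run,study --db sra.db | cut -f1-5,7
run_accession  run_alias      run_date    updated_date  spots     run_center
DRR000093      MCF7_1_paired  2008-12-22  2012-09-06    6141309   KUGSPS
DRR000095      MDAMB231_1     2008-12-22  2012-09-06    6110876   KUGSPS
DRR000103      MDAMB231_2     2008-12-22  2012-06-23    6447854   KUGSPS
DRR000106      T47D_I         2008-12-22  2012-06-23    6272361   KUGSPS
DRR000109      HMEC_2         2008-12-22  2012-06-23    19300723  KUGSPS
DRR000110      MCF7_3         2008-12-22  2012-06-23    5396205   KUGSPS
```

All six runs of the study match the exact phrase `"breast cancer"` (it
appears in the study abstract; the join carries study text to every run
row).  `spots` is the SRA unit for sequenced clusters/reads per run — e.g.
run `DRR000109` has 19,300,723 spots.  The same store answers SQL directly:

```
$ sramine sql 'SELECT library_strategy, count(*) AS Runs FROM experiment
               GROUP BY library_strategy ORDER BY Runs DESC' --db sra.db
library_strategy        Runs
RNA-Seq                 6
```

Accessions resolve across the graph, and runs map to remote files without
any network traffic:

```
$ sramine convert DRX000005 --db sra.db
submission      study      sample     experiment  run
DRA000001       DRP000001  DRS000001  DRX000005   DRR000093

$ sramine files DRR000093 --db sra.db --type fastq | cut -f1,6
run_accession   file_name
DRR000093       DRR000093_1.fastq.gz
DRR000093       DRR000093_2.fastq.gz
```

(`DRR000093` belongs to a paired-layout experiment, hence two mates.)
`sramine download` fetches the files; `sramine igv goto chr1:1-1000` drives
a running IGV instance.

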