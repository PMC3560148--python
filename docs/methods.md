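# Methods

## The metadata model

SRA metadata is submitted as XML object sets for five entity kinds —
submission, study, sample, experiment, run — linked by accession references
(run → experiment → study/sample; everything → submission).  `sramine` maps
each kind to one relational table whose columns mirror the fields a consumer
actually queries (identifiers, aliases, titles, abstracts, library
descriptors, platform, spot/base counts, dates, and free-form attributes).
Parsing is faithful by design: values are stored verbatim — no case-folding,
trimming beyond standard XML whitespace handling, or semantic recoding — and
absent or empty elements become SQL `NULL`.  Only the documented subset of
schema elements is mapped; unrecognized elements are ignored with a debug
log line.

Two linkage fields have no home in the official object schemas:
`submission_accession` on study/sample/experiment/run, and `updated_date` on
run.  The XML dialect written and parsed here carries them as attributes of
the object element so that records round-trip exactly; real SRA documents
simply parse with those fields null.

### Multi-valued fields

Children that repeat (tag/value attributes, URL links, platform parameters)
are flattened to delimited text: pairs joined as `tag: value` with `" || "`
between pairs, preserving document order.  Literal `||` inside a tag or
value is escaped to `¦¦`, which makes the flattening injective on
escape-free inputs and the splitting unambiguous.  The delimiter itself is a
convention of this package (upstream practice only establishes *that*
multi-valued fields are delimited text).

## The denormalized table and full-text index

Queries overwhelmingly want run-level answers annotated with study/sample
context, so the store materializes `sra`: a left join
run → experiment → (study, sample) → submission with **one row per run plus
one row per experiment that has no runs** (run columns null), so run-less
studies are never silently lost.  Graph-key accessions appear once
(coalesced across the tables that carry them); the only non-key column name
shared between entities (`center_name`, in study and submission) is
disambiguated by entity prefix (`study_center_name`,
`submission_center_name`).  Rebuilding is idempotent and recomputes the
orphan report (foreign keys that resolve to no row; the joined rows are kept
with nulls).

Row conservation holds by construction:
`rows(sra) = rows(run) + |{experiments with zero runs}|`.

Every `sra` column is indexed with SQLite FTS5 (external-content table,
rebuilt after each denormalization).  The matching contract is pinned
independently of the backend:

- tokens are case-insensitive maximal `[A-Za-z0-9]+` runs;
- a **term** matches a row if any field contains the token;
- a **phrase** needs its tokens consecutive within a single field;
- a **prefix** `stem*` matches any token starting with the stem;
- **NEAR/k** requires both operands in one field with at most *k*
  intervening tokens (`NEAR` alone means `NEAR/10`);
- `column:term` restricts matching to one column of the denormalized table.

FTS5 under the default unicode61 tokenizer satisfies this contract for
ASCII content (verified: NEAR counts intervening tokens exactly as above;
phrases cannot span columns; matching is case-folded).  The test suite
enforces the contract with an independent brute-force scan oracle over
randomized fixtures, for every grammar production, so any backend change
must preserve these semantics bit-for-bit.

Query-language choices: `OR` is recognized only in uppercase (lowercase
`or` is an ordinary term, mirroring the referenced query-syntax convention);
results are deduplicated after projection onto the requested entities'
columns and ordered ascending by the leading entity's accession — upstream
returned unordered frames, but determinism is required for testing; each
entity's projection leads with its own accession column.

`sql_query` is read-only, enforced with an SQLite authorizer (refuses
INSERT/UPDATE/DELETE/DDL while leaving SELECT, functions and recursive CTEs
available); this works identically for file-backed and in-memory stores.

`convert_accessions` resolves any accession through the `sra` graph and
returns one row per related run (null run if none).  It is a closure
operator: idempotent, extensive and monotone on accession sets within one
store.

## File location, probing, download

ENA hosts run fastq files at deterministic paths:
`vol1/fastq/{acc[:6]}/{acc}/` for 9-character accessions, with an extra
zero-padded numeric subdirectory `{acc[9:]:0>3}` for longer ones (the current
public convention; any modern implementation must handle both).  Single
layout yields `{acc}.fastq.gz`, paired `{acc}_1/_2.fastq.gz` — the layout is
read from the owning experiment.  NCBI SRA containers use a configurable
`ByRun/{sra_type}/{acc3}/{acc6}/{acc}/` template, since that hierarchy has
shifted over the years.  Listing is pure path construction (no network);
probing is an explicit second step that HEADs each URL (with bounded
retries) and drops absent files with a warning, so the probed set is always
a subset of the listed set.  Endpoints are injectable, which is how the
tests exercise the network path against a local server.  Default protocol is
https with ftp available; the fasp/aspera protocol is recognized in the
interface but deliberately unimplemented (it requires third-party software).

The downloader streams to disk, skips files already present at the
server-reported size (so repeated invocations are idempotent and
byte-stable), resumes partial files via range requests when the server
supports them (a 200 response restarts cleanly), verifies completed files by
byte length, and isolates per-file network failures in the report
(`requested == completed + skipped + failed` always).  Checksums are not
used: the public endpoints of this era do not expose them uniformly, so
length is the strongest uniform check.  HTTP is done with the standard
library; no extra client dependency is warranted for HEAD/GET with ranges.

## IGV control

IGV accepts newline-terminated commands on a TCP port (60151 by default —
IGV's documented listener) and answers one line per command, `OK` on
success.  The connection object enforces one in-flight command; helpers emit
the exact wire forms (`genome <name>`, `load <path>` one per path,
`goto <locus>`, `snapshot <file>`, ...) and raise on a non-`OK`
acknowledgement.  Loci are validated client-side as `chr:start-end`, 1-based
inclusive, before anything is sent.  Track files are opaque paths — no
alignment parsing.  Protocol fidelity is tested against a scripted mock
server with a pinned golden transcript; launching a real IGV is guarded
behind a feature-unavailable error when no launcher is present.

## Synthetic fixtures

The generator emulates the *structure* of real submissions: multi-study
submissions, linked experiments/runs with valid sequential accessions (zero
orphans by construction), controlled-vocabulary library descriptors,
multi-valued attributes, and free text drawn from a small biomedical
vocabulary (which includes "breast", "cancer", "Carcinoma" so the canonical
query examples are exercisable).  Phrases can be planted verbatim in a named
field of exactly one entity, and whole records can be embedded unmodified.
Identical seeds produce byte-identical XML.  Default sizes (3 studies, 1–3
experiments each, 1–3 runs each) keep a fixture in the tens of denormalized
rows — large enough to exercise joins and search, small enough that the
oracle-equivalence sweep over 100 seeded fixtures runs in seconds.

What the generator does **not** model: the statistical texture of real SRA
content (field length and vocabulary distributions, missing-data patterns,
center-specific conventions, schema drift across submission eras).  Passing
tests therefore demonstrate the correctness of parsing, storage, matching
semantics and plumbing — not robustness to every document variant in the
wild archive.

The worked-example fixture pins one study (abstract containing the exact
phrase "breast cancer") with six runs of fixed aliases, accessions, dates,
spot counts and run centers, ingested through the full XML pipeline, so
search results over it have exact expected values.

## Numerical and degenerate-input choices

- Dates are stored as verbatim text, never parsed (fidelity over
  convenience; real submissions contain malformed dates).
- Ingestion upserts by accession (replace), since the archive is
  continuously updated and replacement is the simplest auditable semantics;
  invalid accessions are rejected per record without aborting a load.
- Integer fields (`spots`, `bases`, `taxon_id`, `spot_length`) accept null;
  negative values are never generated and not range-checked on parse.
- Empty query, empty phrase, unbalanced quotes, `OR`/`NEAR` without
  operands, and qualifier-without-operand are syntax errors; an unknown
  column in a qualifier is reported at execution with the column named.
- Result tie-break: rows sort by the projected tuple (nulls last,
  stringified comparison), making output order fully deterministic.

## Known limitations

- The shipped column inventory is a documented, faithful subset of the SRA
  schemas, not the complete historical column list; byte-compatibility with
  previously distributed SQLite snapshots is not promised.
- Only ASCII content is guaranteed to satisfy the pinned tokenization
  contract exactly (FTS5's unicode61 folds accented letters; the brute-force
  contract does not).
- `NEAR` operands must be plain terms/phrases/prefixes (no nesting of
  qualifiers inside NEAR).
- No relevance ranking, stemming, or query expansion — matching is exact by
  design.
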