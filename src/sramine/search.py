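"""Full-text and SQL querying of the metadata store.

The full-text layer accepts a Google-like query language over the
denormalized run-level table:

* bare words conjoin:            ``breast cancer``
* double quotes form a phrase:   ``"breast cancer"``
* a trailing ``*`` is a prefix:  ``Carcino*``
* uppercase ``OR`` disjoins:     ``RNA OR ChIP`` (lowercase ``or`` is a term)
* ``NEAR/k`` is proximity:       ``breast NEAR/3 cancer`` (``NEAR`` = ``NEAR/10``)
* ``column:term`` restricts a term (or phrase/prefix) to one column.

Matching semantics are pinned independently of the backend: tokens are
case-insensitive maximal alphanumeric runs; a term matches a row if any field
contains the token; a phrase requires consecutive tokens within a single
field; ``NEAR/k`` allows at most *k* intervening tokens between its operands
in one field.  Execution is delegated to the store's FTS5 index, whose
semantics were verified against these rules.
"""

from __future__ import annotations

import re
import sqlite3
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .errors import QuerySyntaxError, ReadOnlyError, UnknownColumnError
from .metastore import ENTITY_SRA_COLUMNS, MetaStore, SRA_COLUMNS
from .sra_xml import ANY_ACCESSION, KINDS

TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

DEFAULT_NEAR_DISTANCE = 10  # fts3's default for a bare NEAR


# ---------------------------------------------------------------------------
# AST

@dataclass(frozen=True)
class Term:
    token: str


@dataclass(frozen=True)
class Phrase:
    tokens: Tuple[str, ...]


@dataclass(frozen=True)
class Prefix:
    stem: str


@dataclass(frozen=True)
class ColumnQualified:
    column: str
    node: object


@dataclass(frozen=True)
class And:
    nodes: Tuple[object, ...]


@dataclass(frozen=True)
class Or:
    nodes: Tuple[object, ...]


@dataclass(frozen=True)
class Near:
    a: object
    b: object
    k: int


@dataclass
class QueryResult:
    columns: List[str]
    rows: List[tuple]

    def __len__(self):
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns)


# ---------------------------------------------------------------------------
# parsing

_NEAR_RE = re.compile(r"^NEAR(?:/(\d+))?$")


def _primary_from_word(word: str):
    """A bare word becomes Term, Prefix (trailing *) or Phrase (multi-token)."""
    is_prefix = word.endswith("*") or word.endswith("⋆")
    core = word.rstrip("*⋆")
    tokens = TOKEN_RE.findall(core)
    if not tokens:
        raise QuerySyntaxError(f"no searchable tokens in {word!r}")
    if is_prefix:
        if len(tokens) > 1:
            return Phrase(tuple(tokens[:-1]) + (tokens[-1],))  # trailing * ignored mid-phrase
        return Prefix(tokens[0])
    if len(tokens) > 1:
        return Phrase(tuple(tokens))
    return Term(tokens[0])


def _lex(text: str):
    """Yield ('OR',), ('NEAR', k), ('NODE', node) tokens."""
    pos, n = 0, len(text)
    pending_column: Optional[str] = None
    while pos < n:
        while pos < n and text[pos].isspace():
            pos += 1
        if pos >= n:
            break
        if text[pos] == '"':
            end = text.find('"', pos + 1)
            if end < 0:
                raise QuerySyntaxError("unbalanced double quote in query")
            tokens = TOKEN_RE.findall(text[pos + 1:end])
            if not tokens:
                raise QuerySyntaxError("empty phrase in query")
            node = Phrase(tuple(tokens)) if len(tokens) > 1 else Term(tokens[0])
            if pending_column is not None:
                node = ColumnQualified(pending_column, node)
                pending_column = None
            yield ("NODE", node)
            pos = end + 1
            continue
        start = pos
        while pos < n and not text[pos].isspace() and text[pos] != '"':
            pos += 1
        word = text[start:pos]
        if pending_column is not None:
            yield ("NODE", ColumnQualified(pending_column, _primary_from_word(word)))
            pending_column = None
            continue
        if word == "OR":
            yield ("OR",)
            continue
        m = _NEAR_RE.match(word)
        if m:
            yield ("NEAR", int(m.group(1)) if m.group(1) else DEFAULT_NEAR_DISTANCE)
            continue
        qual = re.match(r"^([A-Za-z_][A-Za-z0-9_]*):(.*)$", word)
        if qual:
            column, rest = qual.group(1), qual.group(2)
            if rest:
                yield ("NODE", ColumnQualified(column, _primary_from_word(rest)))
            else:
                pending_column = column  # applies to the next word/phrase
            continue
        yield ("NODE", _primary_from_word(word))
    if pending_column is not None:
        raise QuerySyntaxError(f"column qualifier {pending_column!r}: has no operand")


def parse_query(text: str):
    """Parse query text into a :class:`SearchExpression` AST."""
    if not text or not text.strip():
        raise QuerySyntaxError("empty query")
    groups: List[List[object]] = [[]]
    tokens = list(_lex(text))
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok[0] == "OR":
            if not groups[-1]:
                raise QuerySyntaxError("OR with no left operand")
            groups.append([])
        elif tok[0] == "NEAR":
            if not groups[-1] or i + 1 >= len(tokens) or tokens[i + 1][0] != "NODE":
                raise QuerySyntaxError("NEAR requires an operand on each side")
            left = groups[-1].pop()
            right = tokens[i + 1][1]
            for operand in (left, right):
                if not isinstance(operand, (Term, Phrase, Prefix)):
                    raise QuerySyntaxError(
                        "NEAR operands must be plain terms, phrases or prefixes")
            groups[-1].append(Near(left, right, tok[1]))
            i += 1
        else:
            groups[-1].append(tok[1])
        i += 1
    if not groups[-1]:
        raise QuerySyntaxError("OR with no right operand")
    nodes = [g[0] if len(g) == 1 else And(tuple(g)) for g in groups]
    return nodes[0] if len(nodes) == 1 else Or(tuple(nodes))


# ---------------------------------------------------------------------------
# FTS5 compilation

def _compile_primary(node) -> str:
    if isinstance(node, Term):
        return f'"{node.token}"'
    if isinstance(node, Phrase):
        return '"' + " ".join(node.tokens) + '"'
    if isinstance(node, Prefix):
        return f'"{node.stem}" *'
    raise TypeError(f"not a primary node: {node!r}")


def compile_fts(node) -> str:
    """Compile an AST to an FTS5 MATCH expression."""
    if isinstance(node, (Term, Phrase, Prefix)):
        return _compile_primary(node)
    if isinstance(node, Near):
        return f"NEAR({_compile_primary(node.a)} {_compile_primary(node.b)}, {node.k})"
    if isinstance(node, ColumnQualified):
        return f"{node.column} : ({compile_fts(node.node)})"
    if isinstance(node, And):
        return "(" + " AND ".join(compile_fts(n) for n in node.nodes) + ")"
    if isinstance(node, Or):
        return "(" + " OR ".join(compile_fts(n) for n in node.nodes) + ")"
    raise TypeError(f"unknown query node: {node!r}")


def _check_columns(node, valid):
    if isinstance(node, ColumnQualified):
        if node.column not in valid:
            raise UnknownColumnError(
                f"unknown column {node.column!r} in query "
                f"(not a column of the denormalized table)")
        _check_columns(node.node, valid)
    elif isinstance(node, (And, Or)):
        for child in node.nodes:
            _check_columns(child, valid)
    elif isinstance(node, Near):
        _check_columns(node.a, valid)
        _check_columns(node.b, valid)


# ---------------------------------------------------------------------------
# execution

def _sort_key(row):
    return tuple((v is None, str(v)) for v in row)


def full_text_search(store: MetaStore, expr, out_types=("run", "study")) -> QueryResult:
    """Full-text search over all fields of the denormalized table.

    ``expr`` may be a query string or a pre-parsed AST.  ``out_types`` selects
    which entities' columns appear in the result (their union, in the given
    order); rows are deduplicated after projection and ordered by the leading
    entity's accession.
    """
    if isinstance(expr, str):
        expr = parse_query(expr)
    out_types = list(dict.fromkeys(out_types))
    if not out_types:
        raise ValueError("out_types must name at least one entity kind")
    unknown = [t for t in out_types if t not in KINDS]
    if unknown:
        raise ValueError(f"unknown out_types: {unknown}; expected subset of {KINDS}")
    _check_columns(expr, set(SRA_COLUMNS))

    columns: List[str] = []
    for kind in out_types:
        for col in ENTITY_SRA_COLUMNS[kind]:
            if col not in columns:
                columns.append(col)
    match = compile_fts(expr)
    sql = (f"SELECT {', '.join(columns)} FROM sra WHERE rowid IN "
           f"(SELECT rowid FROM sra_ft WHERE sra_ft MATCH ?)")
    rows = store.conn.execute(sql, (match,)).fetchall()
    unique = sorted(set(rows), key=_sort_key)
    return QueryResult(columns=columns, rows=unique)


_READONLY_OK = {
    sqlite3.SQLITE_SELECT, sqlite3.SQLITE_READ, sqlite3.SQLITE_FUNCTION,
    getattr(sqlite3, "SQLITE_RECURSIVE", 33),
}


def _readonly_authorizer(action, *args):
    return sqlite3.SQLITE_OK if action in _READONLY_OK else sqlite3.SQLITE_DENY


def sql_query(store: MetaStore, sql: str) -> QueryResult:
    """Run an arbitrary read-only SQL statement against the store.

    Write statements are refused; engine errors are surfaced verbatim.
    """
    store.conn.set_authorizer(_readonly_authorizer)
    try:
        cur = store.conn.execute(sql)
        rows = cur.fetchall()
        columns = [d[0] for d in cur.description] if cur.description else []
    except sqlite3.DatabaseError as exc:
        if "not authorized" in str(exc):
            raise ReadOnlyError(
                f"refusing non-read-only statement: {sql!r} ({exc})") from exc
        raise
    finally:
        store.conn.set_authorizer(None)
    return QueryResult(columns=columns, rows=rows)


_KIND_BY_LETTER = {"A": "submission", "P": "study", "S": "sample",
                   "X": "experiment", "R": "run"}
_CONVERT_COLUMNS = ("submission", "study", "sample", "experiment", "run")


def convert_accessions(store: MetaStore, accessions: Sequence[str]) -> pd.DataFrame:
    """Resolve accessions to their full lineage across the entity graph.

    Returns one row per related run (or a single row with a null run when an
    accession has no runs), with columns (submission, study, sample,
    experiment, run).  Feeding the output accessions back yields the same
    closure (idempotent).
    """
    if isinstance(accessions, str):
        accessions = [accessions]
    for acc in accessions:
        if not ANY_ACCESSION.match(acc or ""):
            raise ValueError(f"malformed SRA accession: {acc!r}")
    frames: List[tuple] = []
    for acc in accessions:
        kind = _KIND_BY_LETTER[acc[2]]
        rows = store.conn.execute(
            "SELECT submission_accession, study_accession, sample_accession, "
            f"experiment_accession, run_accession FROM sra WHERE {kind}_accession = ?",
            (acc,)).fetchall()
        if not rows:
            warnings.warn(f"accession {acc} not found in store", stacklevel=2)
        frames.extend(rows)
    unique = sorted(set(frames), key=_sort_key)
    return pd.DataFrame(unique, columns=list(_CONVERT_COLUMNS))
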