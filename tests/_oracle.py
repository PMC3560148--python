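"""Brute-force full-text matching oracle, independent of the FTS backend.

Implements the pinned matching contract directly on Python values: tokens
are case-insensitive maximal alphanumeric runs; a term matches a row if any
field contains the token; a phrase needs consecutive tokens within a single
field; NEAR/k allows at most k intervening tokens between its operands in
one field; a column qualifier restricts matching to that field.
"""

import re

from sramine.search import And, ColumnQualified, Near, Or, Phrase, Prefix, Term

TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def tokenize(value):
    if value is None:
        return []
    return [t.lower() for t in TOKEN_RE.findall(str(value))]


def occurrences(tokens, node):
    """(start, end) inclusive token positions where a primary node occurs."""
    if isinstance(node, Term):
        tok = node.token.lower()
        return [(i, i) for i, t in enumerate(tokens) if t == tok]
    if isinstance(node, Prefix):
        stem = node.stem.lower()
        return [(i, i) for i, t in enumerate(tokens) if t.startswith(stem)]
    if isinstance(node, Phrase):
        want = [t.lower() for t in node.tokens]
        n = len(want)
        return [(i, i + n - 1) for i in range(len(tokens) - n + 1)
                if tokens[i:i + n] == want]
    raise TypeError(f"not a primary node: {node!r}")


def field_matches(tokens, node):
    if isinstance(node, (Term, Phrase, Prefix)):
        return bool(occurrences(tokens, node))
    if isinstance(node, Near):
        occ_a = occurrences(tokens, node.a)
        occ_b = occurrences(tokens, node.b)
        for sa, ea in occ_a:
            for sb, eb in occ_b:
                gap = sb - ea - 1 if sb > ea else sa - eb - 1
                if gap <= node.k:
                    return True
        return False
    raise TypeError(f"not a field-level node: {node!r}")


def row_matches(row, node):
    """``row`` is a mapping of sra column name -> value."""
    if isinstance(node, (Term, Phrase, Prefix, Near)):
        return any(field_matches(tokenize(v), node) for v in row.values())
    if isinstance(node, ColumnQualified):
        return field_matches(tokenize(row.get(node.column)), node.node)
    if isinstance(node, And):
        return all(row_matches(row, child) for child in node.nodes)
    if isinstance(node, Or):
        return any(row_matches(row, child) for child in node.nodes)
    raise TypeError(f"unknown node: {node!r}")


def brute_force_search(store, expr, out_types):
    """Reference result: scan every denormalized row, project, deduplicate."""
    from sramine.metastore import ENTITY_SRA_COLUMNS, SRA_COLUMNS

    columns = []
    for kind in out_types:
        for col in ENTITY_SRA_COLUMNS[kind]:
            if col not in columns:
                columns.append(col)
    rows = store.conn.execute(f"SELECT {', '.join(SRA_COLUMNS)} FROM sra").fetchall()
    hits = set()
    for values in rows:
        row = dict(zip(SRA_COLUMNS, values))
        if row_matches(row, expr):
            hits.add(tuple(row[c] for c in columns))
    return columns, hits


def grammar_queries(store, rng):
    """One query AST per grammar production, built from actual store content.

    Tokens are drawn from the denormalized rows so that matches exist, mixed
    with absent stems to exercise the no-match side as well.
    """
    from sramine.metastore import SRA_COLUMNS

    rows = store.conn.execute(
        f"SELECT {', '.join(SRA_COLUMNS)} FROM sra").fetchall()
    field_tokens = []  # (column, [tokens]) for text-bearing fields
    for values in rows:
        for col, val in zip(SRA_COLUMNS, values):
            toks = tokenize(val)
            if toks:
                field_tokens.append((col, toks))
    if not field_tokens:
        return []

    def pick_tokens(n):
        _, toks = rng.choice(field_tokens)
        if len(toks) >= n:
            start = rng.randrange(len(toks) - n + 1)
            return toks[start:start + n]
        return [rng.choice(toks) for _ in range(n)]

    t1, t2 = pick_tokens(1)[0], pick_tokens(1)[0]
    phrase = pick_tokens(2)
    col, toks = rng.choice(field_tokens)
    near_col, near_toks = rng.choice([ft for ft in field_tokens
                                      if len(ft[1]) >= 2] or field_tokens)
    return [
        Term(t1),
        Term("zzznosuchtoken"),
        And((Term(t1), Term(t2))),
        Or((Term(t1), Term("zzznosuchtoken"))),
        Phrase(tuple(phrase)),
        Phrase(("breast", "ductal", "cancer")),
        Prefix(t1[: max(1, len(t1) - 2)]),
        Near(Term(near_toks[0]), Term(near_toks[-1]), rng.randint(0, 4)),
        Near(Phrase(tuple(phrase)), Term(t2), rng.randint(0, 10)),
        ColumnQualified(col, Term(rng.choice(toks))),
        ColumnQualified(col, Phrase(tuple(toks[:2]) if len(toks) >= 2
                                    else (toks[0],))),
        And((ColumnQualified(col, Prefix(toks[0][:2])), Or((Term(t2), Term(t1))))),
    ]
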