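"""Knowledge-base analyses: per-vaccine AE variety, AE frequency across
vaccines, age-stratified occurrence, and a small SPARQL-like query matcher.

Two counting routes exist for the per-vaccine analysis: a structural one
over the association registry and a label-convention one that replays the
regex-over-labels query ("associated" leaves under "adverse event" parents).
On well-formed knowledge bases they agree; tests exercise both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .errors import EmptyKBError, QueryParseError
from .kb_model import KnowledgeBase, TermId

ROOT_VAE_LABEL = "vaccine adverse event"


@dataclass
class QueryResultTable:
    columns: tuple[str, ...]
    rows: list[tuple]
    ordering: str = ""
    meta: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=list(self.columns))

    def __len__(self) -> int:
        return len(self.rows)


def round_percent(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal place."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------


def count_vae_per_vaccine(kb: KnowledgeBase, mode: str = "structural") -> QueryResultTable:
    """AE-variety count per vaccine, descending, ties alphabetical by label.

    ``structural`` counts distinct associations per vaccine; ``label-convention``
    counts subclass edges from "associated ... AE" leaves to "... adverse event"
    parents, exactly as the regex-based query does.
    """
    if mode not in {"structural", "label-convention"}:
        raise ValueError(f"unknown mode: {mode!r}")
    counts: dict[TermId, int] = {}
    if mode == "structural":
        for assoc in kb.associations:
            parent = kb.vaccine_parent.get(assoc.vaccine)
            if parent is None:
                continue
            counts[parent] = counts.get(parent, 0) + 1
    else:
        for cls in kb.classes.values():
            if "associated" not in cls.label or "AE" not in cls.label:
                continue
            for parent_id in cls.asserted_parents:
                parent = kb.get(parent_id)
                if "adverse event" in parent.label:
                    counts[parent_id] = counts.get(parent_id, 0) + 1
    rows = [
        (str(parent), kb.get(parent).label, n) for parent, n in counts.items()
    ]
    rows.sort(key=lambda r: (-r[2], r[1]))
    return QueryResultTable(
        columns=("class_id", "label", "n_vae"),
        rows=rows,
        ordering="n_vae desc, label asc",
    )


def ae_frequency(kb: KnowledgeBase) -> QueryResultTable:
    """Per adverse event: number (and percent) of vaccines reporting it."""
    total = len(kb.vaccines)
    if total == 0:
        raise EmptyKBError("no vaccines in knowledge base")
    vaccines_by_ae: dict[TermId, set[TermId]] = {}
    for assoc in kb.associations:
        vaccines_by_ae.setdefault(assoc.ae, set()).add(assoc.vaccine)
    rows = []
    for ae, vaccines in vaccines_by_ae.items():
        label = kb.get(ae).label if ae in kb.classes else str(ae)
        n = len(vaccines)
        rows.append((str(ae), label, n, round_percent(n, total)))
    rows.sort(key=lambda r: (-r[2], r[1]))
    return QueryResultTable(
        columns=("ae_id", "label", "n_vaccines", "percent"),
        rows=rows,
        ordering="n_vaccines desc, label asc",
        meta={"total_vaccines": total},
    )


def occurrence_by_age(kb: KnowledgeBase, group_by: str = "category") -> QueryResultTable:
    """Entry counts and mean occurrence per age stratum.

    With ``group_by="category"`` the strata are the three analysis
    categories child / adult / child-adult (senior entries are folded into
    adult); ``group_by="interval"`` keeps each distinct age interval
    separate.  ``meta`` carries child/adult means and the child-exceeds-adult
    flag.
    """
    if group_by not in {"category", "interval"}:
        raise ValueError(f"unknown group_by: {group_by!r}")
    buckets: dict[str, list[float]] = {}
    if group_by == "category":
        buckets = {"child": [], "adult": [], "child-adult": []}
    for assoc in kb.associations:
        for group in assoc.groups:
            if group_by == "category":
                key = "adult" if group.category == "senior" else group.category
            else:
                hi = group.interval.max_years
                key = f"[{group.interval.min_years:g}, " + (
                    "inf)" if hi is None else f"{hi:g}]"
                )
            buckets.setdefault(key, []).append(group.occurrence)
    rows = []
    for key in sorted(buckets):
        values = buckets[key]
        mean = sum(values) / len(values) if values else float("nan")
        rows.append((key, len(values), mean))
    means = {key: (sum(v) / len(v) if v else None) for key, v in buckets.items()}
    child_mean = means.get("child")
    adult_mean = means.get("adult")
    return QueryResultTable(
        columns=("group", "n_entries", "mean_occurrence"),
        rows=rows,
        ordering="group asc",
        meta={
            "child_mean": child_mean,
            "adult_mean": adult_mean,
            "child_exceeds_adult": (
                child_mean is not None
                and adult_mean is not None
                and child_mean > adult_mean
            ),
        },
    )


def max_occurrence(kb: KnowledgeBase):
    """The globally highest (vaccine, AE, interval, occurrence) entry."""
    if not kb.associations:
        raise EmptyKBError("no associations in knowledge base")
    best = None
    for assoc in sorted(kb.associations, key=lambda a: (a.vaccine_label, a.ae_label)):
        for group in assoc.groups:
            if best is None or group.occurrence > best[3]:
                best = (assoc.vaccine_label, assoc.ae_label, group.interval, group.occurrence)
    return best


# ---------------------------------------------------------------------------
# SPARQL-lite
# ---------------------------------------------------------------------------

_PREFIX_MAP = {
    "rdfs:subClassOf": "subClassOf",
    "rdfs:label": "label",
    "a": "type",
    "rdf:type": "type",
}


@dataclass
class _TriplePattern:
    s: str
    p: str  # subClassOf | subClassOf* | label | type
    o: str


@dataclass
class _Query:
    select: list[str]
    count_var: Optional[str]
    count_alias: Optional[str]
    patterns: list[_TriplePattern]
    filters: list[tuple[str, str]]  # (variable, regex)
    group_by: list[str]
    order_by: Optional[tuple[str, bool]]  # (variable, descending)
    limit: Optional[int]


_TOKEN = re.compile(
    r"""\s+|(?P<word>[A-Za-z][\w:*]*)|(?P<var>\?\w+)|(?P<iri><[^>\s]*>)
        |(?P<string>"(?:[^"\\]|\\.)*")|(?P<num>\d+)|(?P<punct>[(){}.,;=])""",
    re.VERBOSE,
)


class _QueryTokens:
    def __init__(self, text: str):
        self.items: list[tuple[str, str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m:
                raise QueryParseError(pos, f"cannot tokenize near {text[pos:pos+15]!r}")
            if m.lastgroup:
                self.items.append((m.lastgroup, m.group(), pos))
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.items[self.i] if self.i < len(self.items) else (None, "", -1)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect_word(self, *words: str) -> str:
        kind, value, pos = self.next()
        if kind != "word" or (words and value.upper() not in words):
            raise QueryParseError(pos, f"expected {'/'.join(words)}, got {value!r}")
        return value


def _parse_query(text: str) -> _Query:
    toks = _QueryTokens(text)
    toks.expect_word("SELECT")
    select: list[str] = []
    count_var = count_alias = None
    while True:
        kind, value, pos = toks.peek()
        if kind == "var":
            select.append(toks.next()[1])
        elif kind == "punct" and value == "(":
            toks.next()
            toks.expect_word("COUNT")
            kind, value, pos = toks.next()
            if kind == "punct" and value == "(":
                kind, value, pos = toks.next()
            if kind != "var":
                raise QueryParseError(pos, "COUNT expects a variable")
            count_var = value
            kind, value, pos = toks.next()
            if kind == "punct" and value == ")":
                kind, value, pos = toks.next()
            if kind != "word" or value.upper() != "AS":
                raise QueryParseError(pos, "expected AS in COUNT clause")
            kind, value, pos = toks.next()
            if kind != "var":
                raise QueryParseError(pos, "expected alias variable after AS")
            count_alias = value
            kind, value, pos = toks.next()
            if not (kind == "punct" and value == ")"):
                raise QueryParseError(pos, "expected ) closing COUNT clause")
        else:
            break
    kind, value, pos = toks.next()
    if kind == "word" and value.upper() == "FROM":
        toks.next()  # source iri, informational only
        kind, value, pos = toks.next()
    if not (kind == "word" and value.upper() == "WHERE"):
        raise QueryParseError(pos, f"expected WHERE, got {value!r}")
    kind, value, pos = toks.next()
    if not (kind == "punct" and value == "{"):
        raise QueryParseError(pos, "expected { after WHERE")
    patterns: list[_TriplePattern] = []
    filters: list[tuple[str, str]] = []
    while True:
        kind, value, pos = toks.peek()
        if kind == "punct" and value == "}":
            toks.next()
            break
        if kind is None:
            raise QueryParseError(pos, "unterminated WHERE block")
        if kind == "word" and value.upper() == "FILTER":
            toks.next()
            toks.expect_word("REGEX")
            kind, value, pos = toks.next()
            if not (kind == "punct" and value == "("):
                raise QueryParseError(pos, "expected ( after regex")
            kind, var, pos = toks.next()
            if kind != "var":
                raise QueryParseError(pos, "regex expects a variable")
            kind, value, pos = toks.next()
            if not (kind == "punct" and value == ","):
                raise QueryParseError(pos, "expected , in regex")
            kind, pattern, pos = toks.next()
            if kind != "string":
                raise QueryParseError(pos, "regex expects a string pattern")
            kind, value, pos = toks.next()
            if not (kind == "punct" and value == ")"):
                raise QueryParseError(pos, "expected ) closing regex")
            filters.append((var, pattern[1:-1]))
        else:
            s = _parse_term(toks)
            p = _parse_predicate(toks)
            o = _parse_term(toks)
            patterns.append(_TriplePattern(s, p, o))
        kind, value, pos = toks.peek()
        if kind == "punct" and value == ".":
            toks.next()
    group_by: list[str] = []
    order_by = None
    limit = None
    while toks.peek()[0] is not None:
        kind, value, pos = toks.next()
        if kind != "word":
            raise QueryParseError(pos, f"unexpected token {value!r}")
        upper = value.upper()
        if upper == "GROUP":
            toks.expect_word("BY")
            while toks.peek()[0] == "var":
                group_by.append(toks.next()[1])
        elif upper == "ORDER":
            toks.expect_word("BY")
            kind, value, pos = toks.next()
            descending = False
            if kind == "word" and value.upper() in {"DESC", "ASC"}:
                descending = value.upper() == "DESC"
                kind, value, pos = toks.next()
                if kind == "punct" and value == "(":
                    kind, value, pos = toks.next()
                if kind != "var":
                    raise QueryParseError(pos, "ORDER BY expects a variable")
                order_by = (value, descending)
                kind2, value2, _ = toks.peek()
                if kind2 == "punct" and value2 == ")":
                    toks.next()
            elif kind == "var":
                order_by = (value, False)
            else:
                raise QueryParseError(pos, "ORDER BY expects a variable")
        elif upper == "LIMIT":
            kind, value, pos = toks.next()
            if kind != "num":
                raise QueryParseError(pos, "LIMIT expects an integer")
            limit = int(value)
        else:
            raise QueryParseError(pos, f"unsupported clause {value!r}")
    return _Query(select, count_var, count_alias, patterns, filters, group_by, order_by, limit)


def _parse_term(toks: _QueryTokens) -> str:
    kind, value, pos = toks.next()
    if kind in {"var", "iri"}:
        return value
    if kind == "word" and ":" in value:
        return value
    raise QueryParseError(pos, f"expected variable or IRI, got {value!r}")


def _parse_predicate(toks: _QueryTokens) -> str:
    kind, value, pos = toks.next()
    if kind != "word":
        raise QueryParseError(pos, f"expected predicate, got {value!r}")
    closure = value.endswith("*")
    base = value[:-1] if closure else value
    mapped = _PREFIX_MAP.get(base)
    if mapped is None:
        raise QueryParseError(pos, f"unsupported predicate {value!r}")
    if closure and mapped != "subClassOf":
        raise QueryParseError(pos, f"closure not supported on {base!r}")
    return mapped + ("*" if closure else "")


def _kb_edges(kb: KnowledgeBase):
    """(subClassOf edges over named classes, labels) used by the matcher."""
    edges = []
    for cls in kb.classes.values():
        for parent in cls.asserted_parents:
            edges.append((str(cls.id), str(parent)))
    labels = {str(cls.id): cls.label for cls in kb.classes.values()}
    return edges, labels


def sparql_lite(kb: KnowledgeBase, query: str) -> QueryResultTable:
    """Execute the supported SPARQL subset over the KB's subclass/label view.

    Supported: SELECT with variables and one (COUNT(?v) AS ?alias), WHERE
    with rdfs:subClassOf / rdfs:subClassOf* / rdfs:label patterns, FILTER
    regex (case-sensitive), GROUP BY, ORDER BY [DESC|ASC], LIMIT.
    """
    q = _parse_query(query)
    edges, labels = _kb_edges(kb)

    closure: dict[str, set[str]] = {c: {c} for c in labels}
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)

    def ancestors(node: str) -> set[str]:
        out = {node}
        stack = [node]
        while stack:
            cur = stack.pop()
            for p in parents.get(cur, ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def resolve(term: str, binding: dict) -> Optional[str]:
        if term.startswith("?"):
            return binding.get(term)
        if term.startswith("<"):
            iri = term[1:-1]
            from .owl_io import OBO

            return iri[len(OBO):] if iri.startswith(OBO) else iri
        if term.startswith("obo:"):
            return term[4:]
        return term

    bindings: list[dict] = [{}]
    for pattern in q.patterns:
        new_bindings: list[dict] = []
        for binding in bindings:
            s_val = resolve(pattern.s, binding)
            o_val = resolve(pattern.o, binding)
            if pattern.p == "label":
                candidates = (
                    [(s_val, labels.get(s_val))] if s_val is not None
                    else list(labels.items())
                )
                for subj, label in candidates:
                    if label is None:
                        continue
                    if o_val is not None and label != o_val:
                        continue
                    nb = dict(binding)
                    if pattern.s.startswith("?"):
                        nb[pattern.s] = subj
                    if pattern.o.startswith("?"):
                        nb[pattern.o] = label
                    new_bindings.append(nb)
            elif pattern.p == "subClassOf":
                for child, parent in edges:
                    if s_val is not None and child != s_val:
                        continue
                    if o_val is not None and parent != o_val:
                        continue
                    nb = dict(binding)
                    if pattern.s.startswith("?"):
                        nb[pattern.s] = child
                    if pattern.o.startswith("?"):
                        nb[pattern.o] = parent
                    new_bindings.append(nb)
            elif pattern.p == "subClassOf*":
                subjects = [s_val] if s_val is not None else list(labels)
                for subj in subjects:
                    if subj not in labels:
                        continue
                    for anc in sorted(ancestors(subj)):
                        if o_val is not None and anc != o_val:
                            continue
                        nb = dict(binding)
                        if pattern.s.startswith("?"):
                            nb[pattern.s] = subj
                        if pattern.o.startswith("?"):
                            nb[pattern.o] = anc
                        new_bindings.append(nb)
            else:
                raise QueryParseError(0, f"unsupported predicate {pattern.p!r}")
        bindings = new_bindings
    for var, pattern in q.filters:
        rx = re.compile(pattern)
        bindings = [b for b in bindings if var in b and rx.search(str(b[var]))]

    if q.count_var is not None:
        grouped: dict[tuple, int] = {}
        for b in bindings:
            key = tuple(b.get(v) for v in (q.group_by or q.select))
            grouped[key] = grouped.get(key, 0) + 1
        out_columns = tuple((q.group_by or q.select) + [q.count_alias])
        rows = [key + (count,) for key, count in grouped.items()]
        select_vars = list(q.group_by or q.select) + [q.count_alias]
    else:
        out_columns = tuple(q.select)
        seen = set()
        rows = []
        for b in bindings:
            row = tuple(b.get(v) for v in q.select)
            if row not in seen:
                seen.add(row)
                rows.append(row)
        select_vars = list(q.select)
    if q.order_by is not None:
        var, descending = q.order_by
        if var in select_vars:
            idx = select_vars.index(var)
            rows.sort(key=lambda r: tuple(str(x) for x in r))
            rows.sort(
                key=lambda r: r[idx],
                reverse=descending,
            )
    else:
        rows.sort(key=lambda r: tuple(str(x) for x in r))
    if q.limit is not None:
        rows = rows[: q.limit]
    ordering = (
        f"{q.order_by[0]} {'desc' if q.order_by[1] else 'asc'}" if q.order_by else "row asc"
    )
    # project to the SELECT clause (GROUP BY keys may be a superset)
    if q.count_var is not None:
        wanted = [v for v in q.select] + [q.count_alias]
        index = [select_vars.index(v) for v in wanted if v in select_vars]
        rows = [tuple(r[i] for i in index) for r in rows]
        out_columns = tuple(select_vars[i] for i in index)
    return QueryResultTable(columns=out_columns, rows=rows, ordering=ordering)
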