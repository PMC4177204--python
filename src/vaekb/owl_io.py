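"""RDF triple view of the knowledge base and canonical Turtle round-trip.

The serializer is canonical: fixed prefix block, subjects and predicates in
a fixed order, every blank node inlined at its single use site — identical
knowledge bases therefore serialize to identical bytes.  The reader accepts
the Turtle subset this tool emits (prefixed names, anonymous blank nodes,
collections, typed literals), which also covers hand-written test files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .errors import DanglingReferenceError, ParseError
from .kb_model import (
    And,
    ClassExpression,
    DataInterval,
    DataValue,
    KnowledgeBase,
    NamedClass,
    OntologyClass,
    ObjectSome,
    Or,
    PropertyDef,
    TermId,
    Vaccine,
)

OBO = "http://purl.obolibrary.org/obo/"
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"

PREFIXES = {"obo": OBO, "owl": OWL, "rdf": RDF, "rdfs": RDFS, "xsd": XSD}

RDF_TYPE = RDF + "type"
RDF_FIRST = RDF + "first"
RDF_REST = RDF + "rest"
RDF_NIL = RDF + "nil"
RDFS_LABEL = RDFS + "label"
RDFS_SUBCLASSOF = RDFS + "subClassOf"
RDFS_DATATYPE = RDFS + "Datatype"
OWL_CLASS = OWL + "Class"
OWL_RESTRICTION = OWL + "Restriction"
OWL_OBJECT_PROPERTY = OWL + "ObjectProperty"
OWL_DATATYPE_PROPERTY = OWL + "DatatypeProperty"
OWL_ANNOTATION_PROPERTY = OWL + "AnnotationProperty"
OWL_ON_PROPERTY = OWL + "onProperty"
OWL_SOME_VALUES_FROM = OWL + "someValuesFrom"
OWL_HAS_VALUE = OWL + "hasValue"
OWL_INTERSECTION_OF = OWL + "intersectionOf"
OWL_UNION_OF = OWL + "unionOf"
OWL_ON_DATATYPE = OWL + "onDatatype"
OWL_WITH_RESTRICTIONS = OWL + "withRestrictions"
OWL_EQUIVALENT_CLASS = OWL + "equivalentClass"
XSD_DECIMAL = XSD + "decimal"
XSD_MIN_INCLUSIVE = XSD + "minInclusive"
XSD_MAX_INCLUSIVE = XSD + "maxInclusive"
IAO_DEFINITION = OBO + "IAO_0000115"
IAO_DEFINITION_SOURCE = OBO + "IAO_0000119"


@dataclass(frozen=True)
class Iri:
    value: str


@dataclass(frozen=True)
class BNode:
    id: str


@dataclass(frozen=True)
class Literal:
    lex: str
    datatype: Optional[str] = None


Term = Union[Iri, BNode, Literal]
Triple = tuple[Union[Iri, BNode], Iri, Term]


@dataclass
class TripleView:
    triples: list[Triple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.triples)

    def add(self, s, p, o) -> None:
        self.triples.append((s, p, o))

    def objects(self, s, p) -> list[Term]:
        return [o for (s2, p2, o) in self.triples if s2 == s and p2 == p]


def term_iri(id: TermId) -> Iri:
    return Iri(OBO + str(id))


def iri_to_term_id(iri: Iri) -> Optional[TermId]:
    if iri.value.startswith(OBO):
        local = iri.value[len(OBO):]
        if re.fullmatch(r"[A-Za-z]+_\d{7}", local):
            return TermId.parse(local)
    return None


# ---------------------------------------------------------------------------
# KB -> triples
# ---------------------------------------------------------------------------


class _BNodeFactory:
    def __init__(self):
        self.n = 0

    def __call__(self) -> BNode:
        self.n += 1
        return BNode(f"b{self.n}")


def _decimal_literal(value: float) -> Literal:
    return Literal(repr(float(value)), XSD_DECIMAL)


def _rdf_list(view: TripleView, items: list[Term], bnode: _BNodeFactory) -> Term:
    head: Term = Iri(RDF_NIL)
    for item in reversed(items):
        node = bnode()
        view.add(node, Iri(RDF_FIRST), item)
        view.add(node, Iri(RDF_REST), head)
        head = node
    return head


def _expr_to_node(
    view: TripleView, expr: ClassExpression, bnode: _BNodeFactory
) -> Term:
    if isinstance(expr, NamedClass):
        return term_iri(expr.id)
    node = bnode()
    if isinstance(expr, And):
        view.add(node, Iri(RDF_TYPE), Iri(OWL_CLASS))
        items = [_expr_to_node(view, c, bnode) for c in expr.conjuncts]
        view.add(node, Iri(OWL_INTERSECTION_OF), _rdf_list(view, items, bnode))
    elif isinstance(expr, Or):
        view.add(node, Iri(RDF_TYPE), Iri(OWL_CLASS))
        items = [_expr_to_node(view, o, bnode) for o in expr.options]
        view.add(node, Iri(OWL_UNION_OF), _rdf_list(view, items, bnode))
    elif isinstance(expr, ObjectSome):
        view.add(node, Iri(RDF_TYPE), Iri(OWL_RESTRICTION))
        view.add(node, Iri(OWL_ON_PROPERTY), term_iri(expr.prop))
        view.add(
            node, Iri(OWL_SOME_VALUES_FROM), _expr_to_node(view, expr.filler, bnode)
        )
    elif isinstance(expr, DataInterval):
        view.add(node, Iri(RDF_TYPE), Iri(OWL_RESTRICTION))
        view.add(node, Iri(OWL_ON_PROPERTY), term_iri(expr.prop))
        dt = bnode()
        view.add(dt, Iri(RDF_TYPE), Iri(RDFS_DATATYPE))
        view.add(dt, Iri(OWL_ON_DATATYPE), Iri(XSD_DECIMAL))
        facets: list[Term] = []
        lo_node = bnode()
        view.add(lo_node, Iri(XSD_MIN_INCLUSIVE), _decimal_literal(expr.lo))
        facets.append(lo_node)
        if expr.hi is not None:
            hi_node = bnode()
            view.add(hi_node, Iri(XSD_MAX_INCLUSIVE), _decimal_literal(expr.hi))
            facets.append(hi_node)
        view.add(dt, Iri(OWL_WITH_RESTRICTIONS), _rdf_list(view, facets, bnode))
        view.add(node, Iri(OWL_SOME_VALUES_FROM), dt)
    elif isinstance(expr, DataValue):
        view.add(node, Iri(RDF_TYPE), Iri(OWL_RESTRICTION))
        view.add(node, Iri(OWL_ON_PROPERTY), term_iri(expr.prop))
        view.add(node, Iri(OWL_HAS_VALUE), _decimal_literal(expr.value))
    else:
        raise TypeError(f"not a class expression: {expr!r}")
    return node


def to_triples(kb: KnowledgeBase) -> TripleView:
    """Render the knowledge base as OWL-style RDF triples."""
    view = TripleView()
    bnode = _BNodeFactory()
    kind_iri = {
        "object": OWL_OBJECT_PROPERTY,
        "datatype": OWL_DATATYPE_PROPERTY,
        "annotation": OWL_ANNOTATION_PROPERTY,
    }
    for prop_id in sorted(kb.properties, key=str):
        prop = kb.properties[prop_id]
        s = term_iri(prop_id)
        view.add(s, Iri(RDF_TYPE), Iri(kind_iri[prop.kind]))
        view.add(s, Iri(RDFS_LABEL), Literal(prop.label))
    for cls_id in sorted(kb.classes, key=str):
        cls = kb.classes[cls_id]
        s = term_iri(cls_id)
        view.add(s, Iri(RDF_TYPE), Iri(OWL_CLASS))
        view.add(s, Iri(RDFS_LABEL), Literal(cls.label))
        for parent in sorted(cls.asserted_parents, key=str):
            view.add(s, Iri(RDFS_SUBCLASSOF), term_iri(parent))
        if cls.defining_expression is not None:
            node = _expr_to_node(view, cls.defining_expression, bnode)
            pred = (
                OWL_EQUIVALENT_CLASS if cls.definition_is_equivalence
                else RDFS_SUBCLASSOF
            )
            view.add(s, Iri(pred), node)
        if cls.definition is not None:
            view.add(s, Iri(IAO_DEFINITION), Literal(cls.definition))
        if cls.definition_source is not None:
            view.add(s, Iri(IAO_DEFINITION_SOURCE), Literal(cls.definition_source))
    return view


# ---------------------------------------------------------------------------
# Canonical Turtle writer
# ---------------------------------------------------------------------------

_PRED_ORDER = [
    RDF_TYPE,
    RDFS_LABEL,
    RDFS_SUBCLASSOF,
    OWL_EQUIVALENT_CLASS,
    OWL_ON_PROPERTY,
    OWL_SOME_VALUES_FROM,
    OWL_HAS_VALUE,
    OWL_INTERSECTION_OF,
    OWL_UNION_OF,
    OWL_ON_DATATYPE,
    OWL_WITH_RESTRICTIONS,
    IAO_DEFINITION,
    IAO_DEFINITION_SOURCE,
]
_PRED_RANK = {p: i for i, p in enumerate(_PRED_ORDER)}


def _curie(iri: str) -> str:
    for prefix, ns in PREFIXES.items():
        if iri.startswith(ns):
            local = iri[len(ns):]
            if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.\-]*", local):
                return f"{prefix}:{local}"
    return f"<{iri}>"


def _escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


class _Writer:
    def __init__(self, view: TripleView):
        self.by_subject: dict[Term, list[tuple[Iri, Term]]] = {}
        for s, p, o in view.triples:
            self.by_subject.setdefault(s, []).append((p, o))

    def _is_list_node(self, node: BNode) -> bool:
        preds = {p.value for p, _ in self.by_subject.get(node, [])}
        return preds == {RDF_FIRST, RDF_REST}

    def _list_items(self, node: Term) -> list[Term]:
        items = []
        while not (isinstance(node, Iri) and node.value == RDF_NIL):
            pairs = dict(
                (p.value, o) for p, o in self.by_subject.get(node, [])
            )
            items.append(pairs[RDF_FIRST])
            node = pairs[RDF_REST]
        return items

    def term_text(self, term: Term, indent: int) -> str:
        if isinstance(term, Iri):
            if term.value == RDF_TYPE:
                return "a"
            return _curie(term.value)
        if isinstance(term, Literal):
            text = f'"{_escape(term.lex)}"'
            if term.datatype:
                text += f"^^{_curie(term.datatype)}"
            return text
        # blank node: collection or property list
        if self._is_list_node(term):
            items = self._list_items(term)
            inner = " ".join(self.term_text(i, indent + 1) for i in items)
            return f"( {inner} )"
        pairs = self.by_subject.get(term, [])
        body = self._predicate_object_text(pairs, indent + 1)
        pad = "    " * indent
        return f"[ {body} {pad}]"

    def _predicate_object_text(self, pairs, indent: int) -> str:
        grouped: dict[str, list[Term]] = {}
        for p, o in pairs:
            grouped.setdefault(p.value, []).append(o)
        keys = sorted(
            grouped, key=lambda p: (_PRED_RANK.get(p, len(_PRED_ORDER)), _curie(p))
        )
        pad = "    " * indent
        chunks = []
        for p in keys:
            objects = sorted(
                (self.term_text(o, indent) for o in grouped[p]), key=str
            )
            chunks.append(
                f"{self.term_text(Iri(p), indent)} " + " , ".join(objects)
            )
        return (" ;\n" + pad).join(chunks)

    def document(self) -> str:
        lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(PREFIXES.items())]
        lines.append("")
        subjects = sorted(
            (s for s in self.by_subject if isinstance(s, Iri)),
            key=lambda s: s.value,
        )
        referenced_bnodes = set()
        for pairs in self.by_subject.values():
            for _, o in pairs:
                if isinstance(o, BNode):
                    referenced_bnodes.add(o)
        for s in subjects:
            body = self._predicate_object_text(self.by_subject[s], 1)
            lines.append(f"{_curie(s.value)} {body} .")
            lines.append("")
        # orphan blank subjects (not referenced anywhere) would be lost;
        # the views produced by to_triples never contain them
        for s in self.by_subject:
            if isinstance(s, BNode) and s not in referenced_bnodes:
                raise ParseError(f"unrooted blank node cannot be serialized: {s}")
        return "\n".join(lines)


def write_turtle(view: TripleView, path) -> None:
    text = _Writer(view).document()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def turtle_text(view: TripleView) -> str:
    return _Writer(view).document()


# ---------------------------------------------------------------------------
# Turtle reader (subset)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+|\#[^\n]*)
  | (?P<iriref><[^<>\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<prefixdecl>@prefix\b)
  | (?P<dtype>\^\^)
  | (?P<pname>[A-Za-z][\w\-]*:[\w\-.]*|:[\w\-.]+)
  | (?P<bnodelabel>_:[\w\-]+)
  | (?P<number>[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
  | (?P<kw_a>\ba\b)
  | (?P<punct>[\[\]();,.])
    """,
    re.VERBOSE,
)


class _Tokenizer:
    def __init__(self, text: str):
        self.tokens: list[tuple[str, str, int]] = []  # (kind, value, line)
        pos = 0
        line = 1
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m:
                raise ParseError(f"line {line}: cannot tokenize near {text[pos:pos+20]!r}")
            kind = m.lastgroup
            value = m.group()
            if kind != "ws":
                self.tokens.append((kind, value, line))
            line += value.count("\n")
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, -1)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, kind=None, value=None):
        tok_kind, tok_value, line = self.next()
        if kind is not None and tok_kind != kind:
            raise ParseError(f"line {line}: expected {kind}, got {tok_value!r}")
        if value is not None and tok_value != value:
            raise ParseError(f"line {line}: expected {value!r}, got {tok_value!r}")
        return tok_value


class _Parser:
    def __init__(self, text: str):
        self.toks = _Tokenizer(text)
        self.prefixes: dict[str, str] = {}
        self.view = TripleView()
        self.bnode = _BNodeFactory()
        self.label_nodes: dict[str, BNode] = {}

    def parse(self) -> TripleView:
        while self.toks.peek()[0] is not None:
            kind, value, line = self.toks.peek()
            if kind == "prefixdecl":
                self.toks.next()
                pname = self.toks.expect("pname")
                if not pname.endswith(":"):
                    raise ParseError(f"line {line}: bad prefix declaration {pname!r}")
                iri = self.toks.expect("iriref")
                self.prefixes[pname[:-1]] = iri[1:-1]
                self.toks.expect("punct", ".")
            else:
                subject = self._subject()
                self._predicate_object_list(subject)
                self.toks.expect("punct", ".")
        return self.view

    def _resolve_pname(self, pname: str, line: int) -> Iri:
        prefix, _, local = pname.partition(":")
        if prefix not in self.prefixes:
            raise ParseError(f"line {line}: unknown prefix {prefix!r}")
        return Iri(self.prefixes[prefix] + local)

    def _subject(self):
        kind, value, line = self.toks.peek()
        if kind in {"iriref", "pname", "bnodelabel"}:
            return self._term()
        if kind == "punct" and value == "[":
            return self._bnode_property_list()
        raise ParseError(f"line {line}: bad subject {value!r}")

    def _predicate_object_list(self, subject) -> None:
        while True:
            kind, value, line = self.toks.peek()
            if kind == "kw_a":
                self.toks.next()
                predicate = Iri(RDF_TYPE)
            elif kind == "iriref":
                predicate = Iri(self.toks.next()[1][1:-1])
            elif kind == "pname":
                predicate = self._resolve_pname(self.toks.next()[1], line)
            else:
                raise ParseError(f"line {line}: expected predicate, got {value!r}")
            while True:
                obj = self._object()
                self.view.add(subject, predicate, obj)
                kind, value, _ = self.toks.peek()
                if kind == "punct" and value == ",":
                    self.toks.next()
                    continue
                break
            kind, value, _ = self.toks.peek()
            if kind == "punct" and value == ";":
                self.toks.next()
                kind, value, _ = self.toks.peek()
                if kind == "punct" and value in {".", "]"}:
                    return  # trailing semicolon
                continue
            return

    def _object(self):
        kind, value, line = self.toks.peek()
        if kind == "punct" and value == "[":
            return self._bnode_property_list()
        if kind == "punct" and value == "(":
            return self._collection()
        return self._term()

    def _term(self):
        kind, value, line = self.toks.next()
        if kind == "iriref":
            return Iri(value[1:-1])
        if kind == "pname":
            return self._resolve_pname(value, line)
        if kind == "bnodelabel":
            return self.label_nodes.setdefault(value, self.bnode())
        if kind == "kw_a":
            return Iri(RDF_TYPE)
        if kind == "string":
            lex = _unescape(value[1:-1])
            next_kind, _, _ = self.toks.peek()
            if next_kind == "dtype":
                self.toks.next()
                dt_kind, dt_value, dt_line = self.toks.next()
                if dt_kind == "iriref":
                    dt = dt_value[1:-1]
                elif dt_kind == "pname":
                    dt = self._resolve_pname(dt_value, dt_line).value
                else:
                    raise ParseError(f"line {dt_line}: bad datatype {dt_value!r}")
                return Literal(lex, dt)
            return Literal(lex)
        if kind == "number":
            dt = XSD_DECIMAL if ("." in value or "e" in value.lower()) else XSD + "integer"
            return Literal(value, dt)
        raise ParseError(f"line {line}: unexpected token {value!r}")

    def _bnode_property_list(self) -> BNode:
        self.toks.expect("punct", "[")
        node = self.bnode()
        kind, value, _ = self.toks.peek()
        if not (kind == "punct" and value == "]"):
            self._predicate_object_list(node)
        self.toks.expect("punct", "]")
        return node

    def _collection(self) -> Term:
        self.toks.expect("punct", "(")
        items = []
        while True:
            kind, value, _ = self.toks.peek()
            if kind == "punct" and value == ")":
                self.toks.next()
                break
            items.append(self._object())
        return _rdf_list(self.view, items, self.bnode)


def _unescape(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            mapping = {"n": "\n", "t": "\t", "r": "\r", '"': '"', "\\": "\\"}
            if nxt in mapping:
                out.append(mapping[nxt])
                i += 2
                continue
            if nxt == "u" and i + 6 <= len(text):
                out.append(chr(int(text[i + 2:i + 6], 16)))
                i += 6
                continue
        out.append(ch)
        i += 1
    return "".join(out)


def read_turtle(path) -> TripleView:
    with open(path, encoding="utf-8") as fh:
        return parse_turtle(fh.read())


def parse_turtle(text: str) -> TripleView:
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Isomorphism (blank-node renaming allowed)
# ---------------------------------------------------------------------------


def _signatures(view: TripleView) -> set:
    by_subject: dict[Term, list[tuple[str, Term]]] = {}
    for s, p, o in view.triples:
        by_subject.setdefault(s, []).append((p.value, o))

    def sig(term: Term, depth=0) -> tuple:
        if isinstance(term, Iri):
            return ("iri", term.value)
        if isinstance(term, Literal):
            return ("lit", term.lex, term.datatype)
        if depth > 50:
            raise ParseError("blank-node structure too deep (cycle?)")
        return (
            "bnode",
            tuple(sorted((p, sig(o, depth + 1)) for p, o in by_subject.get(term, []))),
        )

    grounded = set()
    for s, p, o in view.triples:
        if isinstance(s, Iri):
            grounded.add((("iri", s.value), p.value, sig(o)))
    return grounded


def isomorphic(a: TripleView, b: TripleView) -> bool:
    """True when the two views differ at most by blank-node renaming."""
    return _signatures(a) == _signatures(b)


# ---------------------------------------------------------------------------
# Triples -> KB
# ---------------------------------------------------------------------------


def _node_to_expr(view_index, node: Term) -> ClassExpression:
    if isinstance(node, Iri):
        term = iri_to_term_id(node)
        if term is None:
            raise ParseError(f"cannot map IRI to a term id: {node.value}")
        return NamedClass(term)
    pairs = dict((p.value, o) for p, o in view_index.get(node, []))
    if OWL_INTERSECTION_OF in pairs:
        items = _read_list(view_index, pairs[OWL_INTERSECTION_OF])
        return And(tuple(_node_to_expr(view_index, i) for i in items))
    if OWL_UNION_OF in pairs:
        items = _read_list(view_index, pairs[OWL_UNION_OF])
        return Or(tuple(_node_to_expr(view_index, i) for i in items))
    if OWL_ON_PROPERTY in pairs:
        prop = iri_to_term_id(pairs[OWL_ON_PROPERTY])
        if prop is None:
            raise ParseError("restriction on unknown property IRI")
        if OWL_HAS_VALUE in pairs:
            lit = pairs[OWL_HAS_VALUE]
            return DataValue(prop, float(lit.lex))
        filler = pairs.get(OWL_SOME_VALUES_FROM)
        if filler is None:
            raise ParseError("restriction without someValuesFrom/hasValue")
        if isinstance(filler, BNode):
            fpairs = dict((p.value, o) for p, o in view_index.get(filler, []))
            if OWL_ON_DATATYPE in fpairs:
                lo, hi = None, None
                for facet in _read_list(view_index, fpairs[OWL_WITH_RESTRICTIONS]):
                    fdict = dict(
                        (p.value, o) for p, o in view_index.get(facet, [])
                    )
                    if XSD_MIN_INCLUSIVE in fdict:
                        lo = float(fdict[XSD_MIN_INCLUSIVE].lex)
                    if XSD_MAX_INCLUSIVE in fdict:
                        hi = float(fdict[XSD_MAX_INCLUSIVE].lex)
                if lo is None:
                    raise ParseError("interval facet without minInclusive")
                return DataInterval(prop, lo, hi)
        return ObjectSome(prop, _node_to_expr(view_index, filler))
    raise ParseError(f"cannot interpret blank node as class expression: {node}")


def _read_list(view_index, node: Term) -> list[Term]:
    items = []
    while not (isinstance(node, Iri) and node.value == RDF_NIL):
        pairs = dict((p.value, o) for p, o in view_index.get(node, []))
        if RDF_FIRST not in pairs:
            raise ParseError("malformed RDF collection")
        items.append(pairs[RDF_FIRST])
        node = pairs[RDF_REST]
    return items


def kb_from_triples(view: TripleView) -> KnowledgeBase:
    """Rebuild a knowledge base from a triple view produced by this tool.

    Associations are recovered from the pattern axioms on leaf classes; the
    VAE location is inferred from the adverse-event label ("injection-site"
    substring), mirroring how the curation encodes location in term names.
    """
    from .kb_model import OCCURS_IN_POPULATION
    from .template_io import categorize_age

    index: dict[Term, list[tuple[Iri, Term]]] = {}
    for s, p, o in view.triples:
        index.setdefault(s, []).append((p, o))

    kb = KnowledgeBase()
    kind_map = {
        OWL_OBJECT_PROPERTY: "object",
        OWL_DATATYPE_PROPERTY: "datatype",
        OWL_ANNOTATION_PROPERTY: "annotation",
    }
    classes: dict[TermId, dict] = {}
    for s, pairs in index.items():
        if not isinstance(s, Iri):
            continue
        term = iri_to_term_id(s)
        if term is None:
            continue
        pmap: dict[str, list[Term]] = {}
        for p, o in pairs:
            pmap.setdefault(p.value, []).append(o)
        types = {o.value for o in pmap.get(RDF_TYPE, []) if isinstance(o, Iri)}
        labels = [o.lex for o in pmap.get(RDFS_LABEL, []) if isinstance(o, Literal)]
        label = labels[0] if labels else str(term)
        prop_kinds = types & set(kind_map)
        if prop_kinds:
            kind = kind_map[sorted(prop_kinds)[0]]
            if term not in kb.properties:
                kb.register_property(PropertyDef(term, label, kind))
            continue
        if OWL_CLASS not in types:
            continue
        entry = {
            "label": label,
            "parents": [],
            "expr": None,
            "equivalence": False,
            "definition": None,
            "definition_source": None,
        }
        for o in pmap.get(RDFS_SUBCLASSOF, []):
            if isinstance(o, Iri):
                parent = iri_to_term_id(o)
                if parent is not None:
                    entry["parents"].append(parent)
            elif isinstance(o, BNode):
                entry["expr"] = _node_to_expr(index, o)
        for o in pmap.get(OWL_EQUIVALENT_CLASS, []):
            if isinstance(o, BNode):
                entry["expr"] = _node_to_expr(index, o)
                entry["equivalence"] = True
        for o in pmap.get(IAO_DEFINITION, []):
            entry["definition"] = o.lex
        for o in pmap.get(IAO_DEFINITION_SOURCE, []):
            entry["definition_source"] = o.lex
        classes[term] = entry

    for term in sorted(classes, key=str):
        e = classes[term]
        kb.register_class(
            OntologyClass(
                id=term,
                label=e["label"],
                asserted_parents=set(),
                definition=e["definition"],
                definition_source=e["definition_source"],
                defining_expression=e["expr"],
                definition_is_equivalence=e["equivalence"],
            )
        )
    for term in sorted(classes, key=str):
        for parent in classes[term]["parents"]:
            kb.add_parent(term, parent)

    _rebuild_registries(kb)
    return kb


def _rebuild_registries(kb: KnowledgeBase) -> None:
    from .kb_model import (
        HAS_AGE_IN_YEAR,
        HAS_VAE_OCCURRENCE,
        OCCURS_IN_POPULATION,
        AgeInterval,
        VAEAssociation,
        VaccineeGroup,
    )
    from .template_io import categorize_age

    vaccine_root = kb.id_for_label("vaccine")
    if vaccine_root is not None:
        for child in kb.descendants(vaccine_root):
            kb.register_vaccine(Vaccine(id=child, label=kb.get(child).label))
    label_to_vaccine = {v.label: v.id for v in kb.vaccines.values()}
    suffix = " vaccine adverse event"
    for cls in kb.classes.values():
        if cls.label.endswith(suffix):
            vaccine_label = cls.label[: -len(suffix)]
            if vaccine_label in label_to_vaccine:
                kb.vaccine_parent[label_to_vaccine[vaccine_label]] = cls.id
        if cls.label.startswith("vaccination with "):
            vaccine_label = cls.label[len("vaccination with "):]
            if vaccine_label in label_to_vaccine:
                kb.vaccination_class[label_to_vaccine[vaccine_label]] = cls.id

    parent_to_vaccine = {p: v for v, p in kb.vaccine_parent.items()}
    for cls in sorted(kb.classes.values(), key=lambda c: c.label):
        expr = cls.defining_expression
        if expr is None or not isinstance(expr, And):
            continue
        population = None
        for conjunct in expr.conjuncts:
            if (
                isinstance(conjunct, ObjectSome)
                and conjunct.prop == OCCURS_IN_POPULATION
            ):
                population = conjunct.filler
        if population is None:
            continue
        vaccine_id = None
        ae_id = None
        for parent in cls.asserted_parents:
            if parent in parent_to_vaccine:
                vaccine_id = parent_to_vaccine[parent]
            else:
                ae_id = parent
        if vaccine_id is None or ae_id is None:
            continue
        groups = []
        age_part = None
        if isinstance(population, And):
            for conjunct in population.conjuncts:
                if isinstance(conjunct, (Or, And, DataInterval)):
                    age_part = conjunct
        if age_part is None:
            options: tuple = ()
        elif isinstance(age_part, Or):
            options = age_part.options
        else:
            options = (age_part,)
        for option in options:
            interval = None
            occurrence = None
            conjuncts = option.conjuncts if isinstance(option, And) else (option,)
            for atom in conjuncts:
                if isinstance(atom, DataInterval) and atom.prop == HAS_AGE_IN_YEAR:
                    interval = AgeInterval(atom.lo, atom.hi)
                if isinstance(atom, DataValue) and atom.prop == HAS_VAE_OCCURRENCE:
                    occurrence = atom.value
            if interval is not None and occurrence is not None:
                groups.append(
                    VaccineeGroup(
                        interval=interval,
                        category=categorize_age(interval),
                        occurrence=occurrence,
                    )
                )
        if not groups:
            continue
        groups.sort(key=lambda g: g.interval.min_years)
        ae_label = kb.get(ae_id).label
        kb.associations.append(
            VAEAssociation(
                vaccine=vaccine_id,
                ae=ae_id,
                location=(
                    "injection-site" if "injection-site" in ae_label else "systemic"
                ),
                groups=groups,
                reference=cls.definition_source or "",
                vaccine_label=kb.vaccines[vaccine_id].label,
                ae_label=ae_label,
            )
        )
    kb.associations.sort(key=lambda a: (a.vaccine_label, a.ae_label))


def read_kb(path) -> KnowledgeBase:
    return kb_from_triples(read_turtle(path))


def write_kb(kb: KnowledgeBase, path) -> None:
    write_turtle(to_triples(kb), path)
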