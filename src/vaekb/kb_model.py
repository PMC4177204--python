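"""Core domain types: term identifiers, class expressions, the knowledge base.

The knowledge base is purely class-level (no individuals): a registry of
ontology classes with an acyclic asserted subclass graph, a registry of
properties, the curated vaccine-AE associations, and — after classification —
the inferred subsumption closure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .errors import (
    CycleError,
    DanglingReferenceError,
    DuplicateTermError,
    ParseError,
)

_TERM_ID_RE = re.compile(r"^([A-Za-z]+)_(\d{7})$")


@dataclass(frozen=True, order=True)
class TermId:
    """OBO-style identifier: an alphabetic prefix and a 7-digit local part.

    Equality and hashing are by rendered form (``PREFIX_0001234``), which for
    the canonical field representation coincides with field equality.
    """

    prefix: str
    local: str

    def __post_init__(self):
        if not re.fullmatch(r"[A-Za-z]+", self.prefix):
            raise ParseError(f"invalid term id prefix: {self.prefix!r}")
        if not re.fullmatch(r"\d{7}", self.local):
            raise ParseError(f"term id local part must be 7 digits: {self.local!r}")

    @classmethod
    def parse(cls, text: str) -> "TermId":
        m = _TERM_ID_RE.match(text.strip())
        if not m:
            raise ParseError(f"not a valid term id: {text!r}")
        return cls(m.group(1), m.group(2))

    @classmethod
    def make(cls, prefix: str, serial: int) -> "TermId":
        return cls(prefix, f"{serial:07d}")

    @property
    def serial(self) -> int:
        return int(self.local)

    def __str__(self) -> str:
        return f"{self.prefix}_{self.local}"


# ---------------------------------------------------------------------------
# Class expressions (EL fragment plus the population OR-clause)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NamedClass:
    id: TermId


@dataclass(frozen=True)
class ObjectSome:
    """Existential restriction: ``property some filler``."""

    prop: TermId
    filler: "ClassExpression"


@dataclass(frozen=True)
class DataInterval:
    """Closed decimal interval restriction on a datatype property.

    ``hi`` of ``None`` means an unbounded upper end ("65+").
    """

    prop: TermId
    lo: float
    hi: Optional[float]


@dataclass(frozen=True)
class DataValue:
    """Exact decimal value restriction on a datatype property."""

    prop: TermId
    value: float


@dataclass(frozen=True)
class And:
    conjuncts: tuple["ClassExpression", ...]

    def __post_init__(self):
        if not self.conjuncts:
            raise ParseError("empty conjunction")


@dataclass(frozen=True)
class Or:
    options: tuple["ClassExpression", ...]

    def __post_init__(self):
        if not self.options:
            raise ParseError("empty disjunction")


ClassExpression = Union[NamedClass, ObjectSome, DataInterval, DataValue, And, Or]


def expression_key(expr: ClassExpression) -> str:
    """Canonical string form of an expression; equal expressions share keys."""
    if isinstance(expr, NamedClass):
        return str(expr.id)
    if isinstance(expr, ObjectSome):
        return f"some({expr.prop},{expression_key(expr.filler)})"
    if isinstance(expr, DataInterval):
        hi = "inf" if expr.hi is None else repr(expr.hi)
        return f"interval({expr.prop},{expr.lo!r},{hi})"
    if isinstance(expr, DataValue):
        return f"value({expr.prop},{expr.value!r})"
    if isinstance(expr, And):
        return "and(" + ",".join(sorted(expression_key(c) for c in expr.conjuncts)) + ")"
    if isinstance(expr, Or):
        return "or(" + ",".join(sorted(expression_key(o) for o in expr.options)) + ")"
    raise TypeError(f"not a class expression: {expr!r}")


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropertyDef:
    id: TermId
    label: str
    kind: str  # object | datatype | annotation
    range_hint: Optional[str] = None  # class | decimal | text

    def __post_init__(self):
        if self.kind not in {"object", "datatype", "annotation"}:
            raise ParseError(f"unknown property kind: {self.kind!r}")


# The five relations every knowledge base carries.  'has VAE occurrence' and
# 'has age in year' are datatype (decimal) shortcuts; the other three are
# object properties.
OCCURS_IN_POPULATION = TermId("OVAE", "0900001")
OCCURS_IN = TermId("OVAE", "0900002")
IS_PRECEDED_BY = TermId("OVAE", "0900003")
HAS_AGE_IN_YEAR = TermId("OVAE", "0900004")
HAS_VAE_OCCURRENCE = TermId("OVAE", "0900005")

PATTERN_PROPERTIES: tuple[PropertyDef, ...] = (
    PropertyDef(OCCURS_IN_POPULATION, "occurs in population", "object", "class"),
    PropertyDef(OCCURS_IN, "occurs in", "object", "class"),
    PropertyDef(IS_PRECEDED_BY, "is preceded by", "object", "class"),
    PropertyDef(HAS_AGE_IN_YEAR, "has age in year", "datatype", "decimal"),
    PropertyDef(HAS_VAE_OCCURRENCE, "has VAE occurrence", "datatype", "decimal"),
)


# ---------------------------------------------------------------------------
# Classes, vaccines, associations
# ---------------------------------------------------------------------------


@dataclass
class OntologyClass:
    id: TermId
    label: str
    asserted_parents: set[TermId] = field(default_factory=set)
    definition: Optional[str] = None
    definition_source: Optional[str] = None
    defining_expression: Optional[ClassExpression] = None
    definition_is_equivalence: bool = False
    source_ontology: Optional[str] = None

    def __post_init__(self):
        if self.source_ontology is None:
            self.source_ontology = self.id.prefix


@dataclass
class Vaccine:
    id: TermId
    label: str
    manufacturer: Optional[str] = None
    target_pathogen: Optional[str] = None
    route: Optional[str] = None
    organism_viability: Optional[str] = None


@dataclass(frozen=True)
class AgeInterval:
    """Closed age range in years; ``max_years`` of ``None`` means unbounded."""

    min_years: float
    max_years: Optional[float]

    def __post_init__(self):
        from .errors import RangeError

        if self.min_years < 0:
            raise RangeError(f"negative age: {self.min_years}")
        if self.max_years is not None and self.min_years >= self.max_years:
            raise RangeError(
                f"empty age interval: [{self.min_years}, {self.max_years}]"
            )

    def overlaps(self, other: "AgeInterval") -> bool:
        a_hi = self.max_years if self.max_years is not None else float("inf")
        b_hi = other.max_years if other.max_years is not None else float("inf")
        return self.min_years < b_hi and other.min_years < a_hi


@dataclass(frozen=True)
class VaccineeGroup:
    interval: AgeInterval
    category: str  # child | adult | senior | child-adult
    occurrence: float  # fraction in [0, 1]

    def __post_init__(self):
        from .errors import RangeError

        if self.category not in {"child", "adult", "senior", "child-adult"}:
            raise ParseError(f"unknown age category: {self.category!r}")
        if not 0.0 <= self.occurrence <= 1.0:
            raise RangeError(f"occurrence outside [0,1]: {self.occurrence}")


@dataclass
class VAEAssociation:
    """One vaccine x one adverse event, with per-age-group occurrence rates."""

    vaccine: TermId
    ae: TermId
    location: str  # injection-site | systemic
    groups: list[VaccineeGroup]
    reference: str
    vaccine_label: str = ""
    ae_label: str = ""

    def __post_init__(self):
        if self.location not in {"injection-site", "systemic"}:
            raise ParseError(f"unknown VAE location: {self.location!r}")
        if not self.groups:
            raise ParseError("association needs at least one vaccinee group")


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------


class KnowledgeBase:
    """Registries of classes, properties, and associations.

    A fresh knowledge base contains only the five pattern properties.  The
    asserted subclass graph is kept acyclic by construction; classification
    (:func:`vaekb.el_reasoner.classify`) fills ``inferred_parents``.
    """

    def __init__(self):
        self.classes: dict[TermId, OntologyClass] = {}
        self.by_label: dict[str, TermId] = {}
        self.properties: dict[TermId, PropertyDef] = {
            p.id: p for p in PATTERN_PROPERTIES
        }
        self.associations: list[VAEAssociation] = []
        self.vaccines: dict[TermId, Vaccine] = {}
        self.vaccine_parent: dict[TermId, TermId] = {}  # vaccine -> AE-parent class
        self.vaccination_class: dict[TermId, TermId] = {}  # vaccine -> event class
        self.inferred_parents: dict[TermId, set[TermId]] = {}
        self.classified: bool = False

    # -- registration -------------------------------------------------------

    def register_class(self, cls: OntologyClass) -> TermId:
        if cls.id in self.classes:
            raise DuplicateTermError(f"id already registered: {cls.id}")
        if cls.label in self.by_label:
            raise DuplicateTermError(f"label already registered: {cls.label!r}")
        for parent in cls.asserted_parents:
            if parent not in self.classes:
                raise DanglingReferenceError(f"unregistered parent: {parent}")
        # parents already exist and the graph was acyclic, so adding a new
        # leaf node cannot create a cycle; self-parenting is the only risk
        if cls.id in cls.asserted_parents:
            raise CycleError(f"class cannot be its own parent: {cls.id}")
        self.classes[cls.id] = cls
        self.by_label[cls.label] = cls.id
        self.classified = False
        return cls.id

    def add_parent(self, child: TermId, parent: TermId) -> None:
        """Add an asserted subclass edge, refusing cycles."""
        if child not in self.classes:
            raise DanglingReferenceError(f"unregistered class: {child}")
        if parent not in self.classes:
            raise DanglingReferenceError(f"unregistered parent: {parent}")
        if parent == child or child in self._ancestors_asserted(parent):
            raise CycleError(f"edge {child} -> {parent} would create a cycle")
        self.classes[child].asserted_parents.add(parent)
        self.classified = False

    def _ancestors_asserted(self, start: TermId) -> set[TermId]:
        seen: set[TermId] = set()
        stack = [start]
        while stack:
            node = stack.pop()
            for p in self.classes[node].asserted_parents:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def get(self, id: TermId) -> OntologyClass:
        try:
            return self.classes[id]
        except KeyError:
            raise DanglingReferenceError(f"unregistered class: {id}") from None

    def id_for_label(self, label: str) -> Optional[TermId]:
        return self.by_label.get(label)

    def register_property(self, prop: PropertyDef) -> TermId:
        if prop.id in self.properties:
            raise DuplicateTermError(f"property already registered: {prop.id}")
        self.properties[prop.id] = prop
        return prop.id

    def register_vaccine(self, vaccine: Vaccine) -> TermId:
        self.vaccines[vaccine.id] = vaccine
        return vaccine.id

    # -- navigation ---------------------------------------------------------

    def descendants(self, id: TermId, inferred: bool = False) -> set[TermId]:
        """All strict descendants of ``id`` (the class itself excluded)."""
        if id not in self.classes:
            raise DanglingReferenceError(f"unregistered class: {id}")
        if inferred:
            if not self.classified:
                from .errors import ClassificationNotRunError

                raise ClassificationNotRunError("run classify() first")
            return {
                c for c, parents in self.inferred_parents.items()
                if id in parents and c != id
            }
        children: dict[TermId, set[TermId]] = {c: set() for c in self.classes}
        for c, cls in self.classes.items():
            for p in cls.asserted_parents:
                children[p].add(c)
        out: set[TermId] = set()
        stack = list(children[id])
        while stack:
            node = stack.pop()
            if node not in out:
                out.add(node)
                stack.extend(children[node])
        out.discard(id)
        return out

    def ancestors(self, id: TermId, inferred: bool = False) -> set[TermId]:
        if id not in self.classes:
            raise DanglingReferenceError(f"unregistered class: {id}")
        if inferred:
            if not self.classified:
                from .errors import ClassificationNotRunError

                raise ClassificationNotRunError("run classify() first")
            return set(self.inferred_parents.get(id, set())) - {id}
        return self._ancestors_asserted(id)

    # -- statistics ---------------------------------------------------------

    def term_statistics(self):
        """Per-source term counts plus a totals row, as a pandas DataFrame.

        Columns: source, classes, object_properties, datatype_properties,
        total (= sum of the three count columns; annotation properties are
        not tabulated).  The final row has source ``"Total"`` and holds the
        column sums.
        """
        import pandas as pd

        counts: dict[str, list[int]] = {}

        def row(source: str) -> list[int]:
            return counts.setdefault(source, [0, 0, 0])

        for cls in self.classes.values():
            row(cls.source_ontology)[0] += 1
        for prop in self.properties.values():
            if prop.kind == "object":
                row(prop.id.prefix)[1] += 1
            elif prop.kind == "datatype":
                row(prop.id.prefix)[2] += 1
        records = []
        for source in sorted(counts):
            c, o, d = counts[source]
            records.append((source, c, o, d, c + o + d))
        total = [sum(r[i] for r in records) for i in range(1, 5)]
        records.append(("Total", *total))
        return pd.DataFrame(
            records,
            columns=[
                "source",
                "classes",
                "object_properties",
                "datatype_properties",
                "total",
            ],
        )


# Module-level operation aliases (functional surface over the KB methods).


def register_class(kb: KnowledgeBase, cls: OntologyClass) -> TermId:
    return kb.register_class(cls)


def term_statistics(kb: KnowledgeBase):
    return kb.term_statistics()


def descendants(kb: KnowledgeBase, id: TermId, inferred: bool = False) -> set[TermId]:
    return kb.descendants(id, inferred=inferred)
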