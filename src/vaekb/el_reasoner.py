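"""EL subsumption reasoning over the compiled knowledge base.

Axioms are normalized into the four EL normal forms

    A subClassOf B
    A1 and ... and An subClassOf B
    A subClassOf r some B
    r some B subClassOf A

over named classes plus fresh auxiliary atoms, then saturated with the
standard completion rules.  Datatype restrictions and disjunctions are
encapsulated as opaque atoms (structurally identical restrictions share an
atom); no interval arithmetic is performed, which keeps the fragment sound
and matches the one object-existential inference the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Optional, Union

from .errors import ClassificationNotRunError, UnsupportedAxiomError
from .kb_model import (
    And,
    ClassExpression,
    DataInterval,
    DataValue,
    KnowledgeBase,
    NamedClass,
    OCCURS_IN_POPULATION,
    ObjectSome,
    Or,
    TermId,
    expression_key,
)

Atom = Hashable  # TermId for named classes, str for auxiliary/opaque atoms


@dataclass
class NormalizedAxiomSet:
    atomic: list[tuple[Atom, Atom]] = field(default_factory=list)
    conjunctions: list[tuple[tuple[Atom, ...], Atom]] = field(default_factory=list)
    exists_rhs: list[tuple[Atom, TermId, Atom]] = field(default_factory=list)  # A <= r some B
    exists_lhs: list[tuple[TermId, Atom, Atom]] = field(default_factory=list)  # r some B <= A
    aux_expressions: dict[str, ClassExpression] = field(default_factory=dict)
    atoms: set[Atom] = field(default_factory=set)


class _Normalizer:
    def __init__(self):
        self.out = NormalizedAxiomSet()
        self._aux_by_key: dict[str, str] = {}
        self._counter = 0

    def _fresh(self, expr: ClassExpression, opaque: bool) -> str:
        key = ("opaque:" if opaque else "aux:") + expression_key(expr)
        if key in self._aux_by_key:
            return self._aux_by_key[key]
        self._counter += 1
        name = f"__aux{self._counter}"
        self._aux_by_key[key] = name
        self.out.aux_expressions[name] = expr
        self.out.atoms.add(name)
        return name

    def encode(self, expr: ClassExpression) -> Atom:
        """Return an atom equivalent to ``expr`` (definitional encoding)."""
        if isinstance(expr, NamedClass):
            self.out.atoms.add(expr.id)
            return expr.id
        if isinstance(expr, (DataInterval, DataValue, Or)):
            return self._fresh(expr, opaque=True)
        if isinstance(expr, And):
            aux = self._fresh(expr, opaque=False)
            conj = tuple(self.encode(c) for c in expr.conjuncts)
            for atom in conj:
                self.out.atomic.append((aux, atom))
            self.out.conjunctions.append((conj, aux))
            return aux
        if isinstance(expr, ObjectSome):
            aux = self._fresh(expr, opaque=False)
            filler = self.encode(expr.filler)
            self.out.exists_rhs.append((aux, expr.prop, filler))
            self.out.exists_lhs.append((expr.prop, filler, aux))
            return aux
        raise UnsupportedAxiomError(f"unsupported expression: {expr!r}")


def _check_disjunction_placement(expr: ClassExpression, in_population: bool) -> None:
    if isinstance(expr, Or):
        if not in_population:
            raise UnsupportedAxiomError(
                "disjunction outside an 'occurs in population' filler"
            )
        for option in expr.options:
            _check_disjunction_placement(option, in_population)
    elif isinstance(expr, And):
        for c in expr.conjuncts:
            _check_disjunction_placement(c, in_population)
    elif isinstance(expr, ObjectSome):
        _check_disjunction_placement(
            expr.filler, in_population or expr.prop == OCCURS_IN_POPULATION
        )


def normalize(kb: KnowledgeBase) -> NormalizedAxiomSet:
    """Decompose every KB axiom into EL normal forms."""
    normalizer = _Normalizer()
    out = normalizer.out
    for cls_id in sorted(kb.classes, key=str):
        cls = kb.classes[cls_id]
        out.atoms.add(cls_id)
        for parent in sorted(cls.asserted_parents, key=str):
            out.atoms.add(parent)
            out.atomic.append((cls_id, parent))
        if cls.defining_expression is not None:
            _check_disjunction_placement(cls.defining_expression, False)
            atom = normalizer.encode(cls.defining_expression)
            out.atomic.append((cls_id, atom))
            if cls.definition_is_equivalence:
                out.atomic.append((atom, cls_id))
    return out


def saturate(axioms: NormalizedAxiomSet) -> dict[Atom, set[Atom]]:
    """Least fixpoint of the EL completion rules; returns subsumer sets."""
    supers: dict[Atom, list[Atom]] = {}
    for a, b in axioms.atomic:
        supers.setdefault(a, []).append(b)
    conj_index: dict[Atom, list[tuple[tuple[Atom, ...], Atom]]] = {}
    for conj, b in axioms.conjunctions:
        for atom in conj:
            conj_index.setdefault(atom, []).append((conj, b))
    exists_rhs_index: dict[Atom, list[tuple[TermId, Atom]]] = {}
    for a, role, b in axioms.exists_rhs:
        exists_rhs_index.setdefault(a, []).append((role, b))
    exists_lhs_index: dict[tuple[TermId, Atom], list[Atom]] = {}
    for role, b, a in axioms.exists_lhs:
        exists_lhs_index.setdefault((role, b), []).append(a)

    subsumers: dict[Atom, set[Atom]] = {a: {a} for a in axioms.atoms}
    links: dict[TermId, set[tuple[Atom, Atom]]] = {}

    changed = True
    while changed:
        changed = False
        for x, sx in subsumers.items():
            new: set[Atom] = set()
            for b in sx:
                for c in supers.get(b, ()):
                    if c not in sx:
                        new.add(c)
                for conj, c in conj_index.get(b, ()):
                    if c not in sx and all(a in sx for a in conj):
                        new.add(c)
                for role, c in exists_rhs_index.get(b, ()):
                    pair = (x, c)
                    bucket = links.setdefault(role, set())
                    if pair not in bucket:
                        bucket.add(pair)
                        changed = True
            if new:
                sx |= new
                changed = True
        for role, pairs in links.items():
            for x, y in list(pairs):
                for b in list(subsumers.get(y, ())):
                    for c in exists_lhs_index.get((role, b), ()):
                        if c not in subsumers[x]:
                            subsumers[x].add(c)
                            changed = True
    return subsumers


def classify(kb: KnowledgeBase) -> KnowledgeBase:
    """Populate ``kb.inferred_parents`` with the full subsumption closure.

    Auxiliary normalization atoms are dropped; every named class maps to the
    set of its named strict subsumers (a superset of the transitive closure
    of the asserted parents).  Idempotent.
    """
    axioms = normalize(kb)
    subsumers = saturate(axioms)
    kb.inferred_parents = {}
    for cls_id in kb.classes:
        named = {
            a for a in subsumers.get(cls_id, {cls_id})
            if isinstance(a, TermId) and a != cls_id and a in kb.classes
        }
        kb.inferred_parents[cls_id] = named
    kb.classified = True
    return kb


def _asserted_closure(kb: KnowledgeBase) -> dict[TermId, set[TermId]]:
    closure: dict[TermId, set[TermId]] = {}

    def walk(node: TermId) -> set[TermId]:
        if node in closure:
            return closure[node]
        closure[node] = set()  # guard; asserted graph is acyclic
        out: set[TermId] = set()
        for p in kb.classes[node].asserted_parents:
            out.add(p)
            out |= walk(p)
        closure[node] = out
        return out

    for c in kb.classes:
        walk(c)
    return closure


def inferred_only_edges(kb: KnowledgeBase) -> list[tuple[TermId, TermId]]:
    """Direct subsumptions discovered by the reasoner only.

    Returns (child, parent) pairs present in the inferred closure but absent
    from the asserted transitive closure, reduced to direct edges (no third
    class strictly between child and parent), sorted by (child label,
    parent label).
    """
    if not kb.classified:
        raise ClassificationNotRunError("run classify() first")
    asserted = _asserted_closure(kb)
    inferred = kb.inferred_parents
    edges: list[tuple[TermId, TermId]] = []
    for child, parents in inferred.items():
        novel = parents - asserted.get(child, set())
        for parent in novel:
            direct = True
            for mid in parents:
                if mid in (child, parent):
                    continue
                if child in inferred.get(mid, set()):
                    continue  # mid is equivalent to child
                if parent in inferred.get(mid, set()):
                    if mid in inferred.get(parent, set()):
                        continue  # mid is equivalent to parent
                    direct = False
                    break
            if direct:
                edges.append((child, parent))
    edges.sort(key=lambda e: (kb.get(e[0]).label, kb.get(e[1]).label))
    return edges
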