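"""Compile curated associations into ontology classes and pattern axioms.

Each (vaccine, adverse event) association becomes a leaf class with two
asserted parents (the adverse-event class and a per-vaccine grouping class)
and a subclass-of axiom built from the fixed design pattern:

    'is preceded by' some (vaccination with V)
    and 'occurs in population' some
        ('human vaccinee population'
         and ((has age in year in [a1,b1] and has VAE occurrence value o1)
              or ... one disjunct per age group))

Label conventions (relied on by the query layer): leaf labels are
"<vaccine>-associated <ae> AE"; per-vaccine parents are
"<vaccine> vaccine adverse event".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CapacityError, DanglingReferenceError
from .kb_model import (
    And,
    DataInterval,
    DataValue,
    HAS_AGE_IN_YEAR,
    HAS_VAE_OCCURRENCE,
    IS_PRECEDED_BY,
    KnowledgeBase,
    NamedClass,
    OCCURS_IN_POPULATION,
    ObjectSome,
    OntologyClass,
    Or,
    TermId,
    VAEAssociation,
    Vaccine,
)
from .template_io import TemplateRecord, records_to_associations

ROOT_AE_LABEL = "adverse event"
ROOT_VAE_LABEL = "vaccine adverse event"
ROOT_VACCINE_LABEL = "vaccine"
ROOT_VACCINATION_LABEL = "vaccination"
HUMAN_VACCINEE_POPULATION_LABEL = "human vaccinee population"

_MAX_SERIAL = 9_999_999


@dataclass
class IdMinter:
    """Auto-incrementing OVAE id dispenser that skips reserved ids."""

    next_serial: int = 1
    reserved: set[TermId] = field(default_factory=set)

    def mint(self) -> TermId:
        while True:
            if self.next_serial > _MAX_SERIAL:
                raise CapacityError("OVAE serial space exhausted")
            candidate = TermId.make("OVAE", self.next_serial)
            self.next_serial += 1
            if candidate not in self.reserved:
                self.reserved.add(candidate)
                return candidate


def mint_ovae_id(minter: IdMinter) -> TermId:
    return minter.mint()


def _strip_ae_suffix(label: str) -> str:
    for suffix in (" adverse event", " AE"):
        if label.endswith(suffix):
            return label[: -len(suffix)]
    return label


def _ensure_class(
    kb: KnowledgeBase, minter: IdMinter, label: str, parents: set[TermId]
) -> TermId:
    existing = kb.id_for_label(label)
    if existing is not None:
        return existing
    return kb.register_class(
        OntologyClass(id=minter.mint(), label=label, asserted_parents=set(parents))
    )


def vaccine_ae_parent(
    kb: KnowledgeBase, vaccine: Vaccine, minter: IdMinter
) -> OntologyClass:
    """Return (creating if needed) the "<vaccine> vaccine adverse event" class."""
    if vaccine.id not in kb.vaccines:
        raise DanglingReferenceError(f"unregistered vaccine: {vaccine.id}")
    if vaccine.id in kb.vaccine_parent:
        return kb.get(kb.vaccine_parent[vaccine.id])
    root = _ensure_class(kb, minter, ROOT_VAE_LABEL, set())
    label = f"{vaccine.label} vaccine adverse event"
    parent_id = _ensure_class(kb, minter, label, {root})
    kb.vaccine_parent[vaccine.id] = parent_id
    return kb.get(parent_id)


def _vaccination_class(kb: KnowledgeBase, vaccine: Vaccine, minter: IdMinter) -> TermId:
    if vaccine.id in kb.vaccination_class:
        return kb.vaccination_class[vaccine.id]
    root = _ensure_class(kb, minter, ROOT_VACCINATION_LABEL, set())
    cls_id = _ensure_class(kb, minter, f"vaccination with {vaccine.label}", {root})
    kb.vaccination_class[vaccine.id] = cls_id
    return cls_id


def _population_expression(kb: KnowledgeBase, assoc: VAEAssociation, minter: IdMinter):
    hvp = _ensure_class(kb, minter, HUMAN_VACCINEE_POPULATION_LABEL, set())
    disjuncts = []
    for group in assoc.groups:
        disjuncts.append(
            And(
                (
                    DataInterval(
                        HAS_AGE_IN_YEAR,
                        group.interval.min_years,
                        group.interval.max_years,
                    ),
                    DataValue(HAS_VAE_OCCURRENCE, group.occurrence),
                )
            )
        )
    age_part = disjuncts[0] if len(disjuncts) == 1 else Or(tuple(disjuncts))
    return ObjectSome(
        OCCURS_IN_POPULATION, And((NamedClass(hvp), age_part))
    )


def build_vae_class(
    kb: KnowledgeBase, assoc: VAEAssociation, minter: IdMinter
) -> OntologyClass:
    """Create the leaf class for one association (idempotent)."""
    if assoc.vaccine not in kb.vaccines:
        raise DanglingReferenceError(f"unregistered vaccine: {assoc.vaccine}")
    if assoc.ae not in kb.classes:
        raise DanglingReferenceError(f"unregistered adverse-event term: {assoc.ae}")
    vaccine = kb.vaccines[assoc.vaccine]
    ae_label = kb.get(assoc.ae).label
    label = f"{vaccine.label}-associated {_strip_ae_suffix(ae_label)} AE"
    existing = kb.id_for_label(label)
    if existing is not None:
        return kb.get(existing)
    parent = vaccine_ae_parent(kb, vaccine, minter)
    expression = And(
        (
            ObjectSome(
                IS_PRECEDED_BY, NamedClass(_vaccination_class(kb, vaccine, minter))
            ),
            _population_expression(kb, assoc, minter),
        )
    )
    cls = OntologyClass(
        id=minter.mint(),
        label=label,
        asserted_parents={assoc.ae, parent.id},
        defining_expression=expression,
        definition_source=assoc.reference,
    )
    kb.register_class(cls)
    return cls


def new_minter(kb: KnowledgeBase) -> IdMinter:
    """A minter whose reserved set covers every OVAE id already in the KB."""
    reserved = {i for i in kb.classes if i.prefix == "OVAE"}
    reserved |= {i for i in kb.properties if i.prefix == "OVAE"}
    return IdMinter(reserved=reserved)


def compile_kb(records: list[TemplateRecord], seed_terms=None) -> KnowledgeBase:
    """Build a complete knowledge base from template records and seed terms.

    ``seed_terms`` is an iterable of ``(id, label, parent_ids, source)``
    tuples (see :func:`vaekb.synthetic_fixtures.read_seed_terms`).
    Associations are processed sorted by (vaccine label, AE label), and ids
    are minted in that order, so identical inputs compile to identical
    knowledge bases.
    """
    kb = KnowledgeBase()
    _register_seed_terms(kb, seed_terms or [])
    minter = new_minter(kb)
    # stable scaffold, minted only when the seed table does not provide it
    _ensure_class(kb, minter, ROOT_AE_LABEL, set())
    _ensure_class(kb, minter, ROOT_VAE_LABEL, set())
    _ensure_class(kb, minter, ROOT_VACCINE_LABEL, set())
    _ensure_class(kb, minter, HUMAN_VACCINEE_POPULATION_LABEL, set())
    vaccine_root = kb.id_for_label(ROOT_VACCINE_LABEL)

    associations = records_to_associations(records)
    for assoc in associations:
        if assoc.vaccine not in kb.vaccines:
            if assoc.vaccine not in kb.classes:
                kb.register_class(
                    OntologyClass(
                        id=assoc.vaccine,
                        label=assoc.vaccine_label,
                        asserted_parents={vaccine_root},
                    )
                )
            kb.register_vaccine(Vaccine(id=assoc.vaccine, label=assoc.vaccine_label))
        build_vae_class(kb, assoc, minter)
        kb.associations.append(assoc)
    return kb


def _register_seed_terms(kb: KnowledgeBase, seed_terms) -> None:
    rows = list(seed_terms)
    pending: list[OntologyClass] = []
    for id_text, label, parent_ids, source in rows:
        cls = OntologyClass(
            id=TermId.parse(id_text),
            label=label,
            asserted_parents=set(),
            source_ontology=source or None,
        )
        pending.append(cls)
    for cls in pending:
        kb.register_class(cls)
    # second pass: parents may be declared in any row order
    for (id_text, _label, parent_ids, _source), cls in zip(rows, pending):
        for parent_text in parent_ids:
            kb.add_parent(cls.id, TermId.parse(parent_text))
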