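import random

import pytest

from vaekb.axiom_builder import compile_kb
from vaekb.kb_model import And, KnowledgeBase, NamedClass, ObjectSome, OntologyClass, TermId
from vaekb.synthetic_fixtures import GeneratorConfig, generate, load_fixture, seed_terms_for


@pytest.fixture(scope="session")
def afluria_records():
    return load_fixture("afluria")


@pytest.fixture(scope="session")
def seed_terms():
    return load_fixture("seed_terms")


@pytest.fixture()
def afluria_kb(afluria_records, seed_terms):
    return compile_kb(afluria_records, seed_terms)


@pytest.fixture()
def figure4_kb():
    return load_fixture("figure4")


def make_generated_kb(seed: int = 0, **overrides) -> KnowledgeBase:
    if "aes_per_vaccine" not in overrides:
        vocab = overrides.get("ae_vocabulary", GeneratorConfig.ae_vocabulary)
        overrides["aes_per_vaccine"] = (1, min(4, vocab))
    config = GeneratorConfig(seed=seed, **overrides)
    records, _ = generate(config)
    return compile_kb(records, seed_terms_for(records))


def random_el_kb(seed: int, max_classes: int = 30) -> KnowledgeBase:
    """Random shallow EL ontology: asserted DAG + conjunctive definitions.

    Defining expressions are conjunctions of named classes and existential
    restrictions over named fillers; about half are equivalences.  Used by
    the reasoner-vs-oracle property tests.
    """
    rng = random.Random(seed)
    n = rng.randint(3, max_classes)
    kb = KnowledgeBase()
    ids = [TermId.make("TST", i + 1) for i in range(n)]
    roles = [TermId.make("TSR", i + 1) for i in range(2)]
    for i, term in enumerate(ids):
        parents = set()
        if i > 0:
            for _ in range(rng.randint(0, 2)):
                parents.add(ids[rng.randrange(i)])
        kb.register_class(
            OntologyClass(id=term, label=f"test class {i + 1}", asserted_parents=parents)
        )
    for i, term in enumerate(ids):
        if rng.random() < 0.4:
            atoms = []
            for _ in range(rng.randint(1, 3)):
                target = NamedClass(ids[rng.randrange(n)])
                if rng.random() < 0.5:
                    atoms.append(ObjectSome(rng.choice(roles), target))
                else:
                    atoms.append(target)
            cls = kb.get(term)
            cls.defining_expression = And(tuple(atoms))
            cls.definition_is_equivalence = rng.random() < 0.5
    return kb


def oracle_subsumers(kb: KnowledgeBase) -> dict:
    """Brute-force saturation, written independently of the reasoner.

    Operates directly on the KB structure (asserted parents plus the shallow
    conjunctive definitions produced by :func:`random_el_kb`), iterating
    every rule instance until nothing changes.
    """
    subs = {c: {c} for c in kb.classes}
    edges = set()  # (x, role, y): x is subsumed by 'role some y'

    def expr_atoms(cls):
        expr = cls.defining_expression
        if expr is None:
            return []
        return list(expr.conjuncts) if isinstance(expr, And) else [expr]

    changed = True
    while changed:
        changed = False
        for x in kb.classes:
            # asserted parents of anything x is subsumed by
            for b in list(subs[x]):
                for p in kb.get(b).asserted_parents:
                    if p not in subs[x]:
                        subs[x].add(p)
                        changed = True
                # definition unfolding (subclass direction)
                for atom in expr_atoms(kb.get(b)):
                    if isinstance(atom, NamedClass):
                        if atom.id not in subs[x]:
                            subs[x].add(atom.id)
                            changed = True
                    elif isinstance(atom, ObjectSome):
                        e = (x, atom.prop, atom.filler.id)
                        if e not in edges:
                            edges.add(e)
                            changed = True
            # definition recognition (equivalence direction)
            for c in kb.classes:
                cls = kb.get(c)
                if not cls.definition_is_equivalence or c in subs[x]:
                    continue
                satisfied = True
                for atom in expr_atoms(cls):
                    if isinstance(atom, NamedClass):
                        if atom.id not in subs[x]:
                            satisfied = False
                            break
                    elif isinstance(atom, ObjectSome):
                        if not any(
                            role == atom.prop and atom.filler.id in subs[y]
                            for (x2, role, y) in edges
                            if x2 == x
                        ):
                            satisfied = False
                            break
                if satisfied:
                    subs[x].add(c)
                    changed = True
    return {c: subs[c] - {c} for c in kb.classes}
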