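import hashlib

import pytest

from vaekb.axiom_builder import (
    IdMinter,
    build_vae_class,
    compile_kb,
    mint_ovae_id,
    new_minter,
    vaccine_ae_parent,
)
from vaekb.errors import CapacityError, DanglingReferenceError
from vaekb.kb_model import And, KnowledgeBase, ObjectSome, Or, TermId, Vaccine
from vaekb.owl_io import to_triples, turtle_text
from vaekb.synthetic_fixtures import load_fixture
from vaekb.template_io import records_to_associations


class TestMinter:
    def test_fresh_minter_starts_at_one(self):
        assert str(mint_ovae_id(IdMinter())) == "OVAE_0000001"

    def test_auto_increment(self):
        minter = IdMinter()
        mint_ovae_id(minter)
        mint_ovae_id(minter)
        assert str(mint_ovae_id(minter)) == "OVAE_0000003"

    def test_reserved_skip(self):
        minter = IdMinter(reserved={TermId.parse("OVAE_0000002")})
        assert str(mint_ovae_id(minter)) == "OVAE_0000001"
        assert str(mint_ovae_id(minter)) == "OVAE_0000003"

    def test_capacity(self):
        minter = IdMinter(next_serial=10_000_000)
        with pytest.raises(CapacityError):
            mint_ovae_id(minter)


class TestVaccineAeParent:
    def _kb(self, label):
        kb = KnowledgeBase()
        vaccine = Vaccine(id=TermId.make("VO", 1), label=label)
        kb.register_vaccine(vaccine)
        return kb, vaccine

    def test_label_convention(self):
        kb, vaccine = self._kb("Recombivax HB")
        cls = vaccine_ae_parent(kb, vaccine, new_minter(kb))
        assert cls.label == "Recombivax HB vaccine adverse event"
        root = kb.id_for_label("vaccine adverse event")
        assert root in cls.asserted_parents

    def test_afluria(self):
        kb, vaccine = self._kb("Afluria")
        cls = vaccine_ae_parent(kb, vaccine, new_minter(kb))
        assert cls.label == "Afluria vaccine adverse event"

    def test_idempotent(self):
        kb, vaccine = self._kb("Afluria")
        minter = new_minter(kb)
        first = vaccine_ae_parent(kb, vaccine, minter)
        second = vaccine_ae_parent(kb, vaccine, minter)
        assert first.id == second.id


class TestBuildVaeClass:
    def test_three_group_disjunction(self, seed_terms):
        records = load_fixture("afluria_pain_groups")
        kb = compile_kb(records, seed_terms)
        leaf = kb.get(kb.id_for_label("Afluria-associated injection-site pain AE"))
        assert leaf is not None
        # parents: the OAE term and the vaccine-specific grouping class
        labels = {kb.get(p).label for p in leaf.asserted_parents}
        assert labels == {"injection-site pain AE", "Afluria vaccine adverse event"}
        expr = leaf.defining_expression
        assert isinstance(expr, And)
        population = [c for c in expr.conjuncts if isinstance(c, ObjectSome)
                      and kb.properties[c.prop].label == "occurs in population"]
        assert len(population) == 1
        filler = population[0].filler
        disjunctions = [c for c in filler.conjuncts if isinstance(c, Or)]
        assert len(disjunctions) == 1
        assert len(disjunctions[0].options) == 3

    def test_single_group_has_no_disjunction(self, afluria_kb):
        leaf = afluria_kb.get(
            afluria_kb.id_for_label("Afluria-associated headache AE")
        )

        def contains_or(expr):
            if isinstance(expr, Or):
                return True
            if isinstance(expr, And):
                return any(contains_or(c) for c in expr.conjuncts)
            if isinstance(expr, ObjectSome):
                return contains_or(expr.filler)
            return False

        assert not contains_or(leaf.defining_expression)

    def test_idempotent(self, seed_terms):
        records = load_fixture("afluria")
        kb = compile_kb(records, seed_terms)
        assoc = records_to_associations(records)[0]
        n_before = len(kb.classes)
        cls = build_vae_class(kb, assoc, new_minter(kb))
        assert len(kb.classes) == n_before
        assert cls.id == kb.id_for_label(cls.label)

    def test_missing_ae_term(self):
        kb = KnowledgeBase()
        kb.register_vaccine(Vaccine(id=TermId.make("VO", 1), label="X"))
        assoc = records_to_associations(load_fixture("afluria")[:1])[0]
        assoc.vaccine = TermId.make("VO", 1)
        with pytest.raises(DanglingReferenceError):
            build_vae_class(kb, assoc, new_minter(kb))


class TestCompileKb:
    def test_afluria_nine_leaves(self, afluria_kb):
        parent = afluria_kb.id_for_label("Afluria vaccine adverse event")
        leaves = {
            c for c in afluria_kb.descendants(parent)
            if "associated" in afluria_kb.get(c).label
        }
        assert len(leaves) == 9

    def test_empty_records(self, seed_terms):
        kb = compile_kb([], seed_terms)
        assert not kb.associations
        assert not kb.vaccines
        # seed terms plus the two scaffold classes the seed table lacks
        # ('vaccine adverse event', 'human vaccinee population')
        assert len(kb.classes) == len(seed_terms) + 2

    def test_deterministic_serialization(self, afluria_records, seed_terms):
        def digest():
            kb = compile_kb(afluria_records, seed_terms)
            return hashlib.sha256(
                turtle_text(to_triples(kb)).encode()
            ).hexdigest()

        assert digest() == digest()

    def test_leaf_count_equals_distinct_pairs(self, afluria_records, seed_terms):
        kb = compile_kb(afluria_records, seed_terms)
        pairs = {(r.vaccine_vo_id, r.oae_id) for r in afluria_records}
        leaves = [c for c in kb.classes.values() if "associated" in c.label]
        assert len(leaves) == len(pairs)

    def test_label_conventions(self, afluria_kb):
        for cls in afluria_kb.classes.values():
            if cls.defining_expression is None:
                continue
            assert "associated" in cls.label and cls.label.endswith("AE")
            parent_labels = [afluria_kb.get(p).label for p in cls.asserted_parents]
            assert any("adverse event" in l for l in parent_labels)

    def test_minted_ids_strictly_increasing(self, afluria_kb, afluria_records, seed_terms):
        leaves = sorted(
            (c for c in afluria_kb.classes.values() if "associated" in c.label),
            key=lambda c: c.label,
        )
        serials = [c.id.serial for c in leaves]
        assert serials == sorted(serials)
        rebuilt = compile_kb(afluria_records, seed_terms)
        assert {str(c) for c in rebuilt.classes} == {str(c) for c in afluria_kb.classes}
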