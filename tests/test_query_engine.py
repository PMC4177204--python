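import random
import re

import pytest

from conftest import make_generated_kb

from vaekb.axiom_builder import compile_kb
from vaekb.errors import EmptyKBError, QueryParseError
from vaekb.kb_model import KnowledgeBase, OntologyClass, TermId
from vaekb.query_engine import (
    ae_frequency,
    count_vae_per_vaccine,
    max_occurrence,
    occurrence_by_age,
    round_percent,
    sparql_lite,
)
from vaekb.synthetic_fixtures import (
    GeneratorConfig,
    generate,
    load_fixture,
    seed_terms_for,
    table2_records,
)

FIG3_QUERY = """
SELECT ?pclass ?plabel (COUNT(?cclass) AS ?count)
WHERE {
  ?cclass rdfs:subClassOf ?pclass .
  ?pclass rdfs:label ?plabel .
  ?cclass rdfs:label ?clabel .
  FILTER regex(?plabel, "adverse event") .
  FILTER regex(?clabel, "associated") .
}
GROUP BY ?pclass ?plabel
ORDER BY DESC(?count)
"""


class TestCountVaePerVaccine:
    def test_table2_top_row(self):
        records = table2_records()
        kb = compile_kb(records, seed_terms_for(records))
        table = count_vae_per_vaccine(kb, "structural")
        assert table.rows[0][1] == "Recombivax HB vaccine adverse event"
        assert table.rows[0][2] == 20

    def test_modes_agree(self):
        records = table2_records(filler_vaccines=5, seed=1)
        kb = compile_kb(records, seed_terms_for(records))
        structural = count_vae_per_vaccine(kb, "structural")
        by_label = count_vae_per_vaccine(kb, "label-convention")
        assert structural.rows == by_label.rows

    def test_empty_kb(self):
        assert count_vae_per_vaccine(KnowledgeBase(), "structural").rows == []

    @pytest.mark.parametrize("seed", [42])
    def test_generator_ground_truth(self, seed):
        config = GeneratorConfig(n_vaccines=8, ae_vocabulary=10, seed=seed)
        records, truth = generate(config)
        kb = compile_kb(records, seed_terms_for(records))
        table = count_vae_per_vaccine(kb, "structural")
        got = {label.replace(" vaccine adverse event", ""): n for _, label, n in table.rows}
        assert got == truth.vae_per_vaccine


class TestAeFrequency:
    def test_planted_table3_counts(self):
        planted = {"injection-site pain AE": 43, "fever AE": 34}
        config = GeneratorConfig(
            n_vaccines=63, ae_vocabulary=8, aes_per_vaccine=(1, 3),
            planted_ae_vaccine_counts=planted, seed=7,
        )
        records, _ = generate(config)
        kb = compile_kb(records, seed_terms_for(records))
        table = ae_frequency(kb)
        by_label = {label: (n, pct) for _, label, n, pct in table.rows}
        assert by_label["injection-site pain AE"] == (43, 68.3)
        assert by_label["fever AE"] == (34, 54.0)
        assert table.meta["total_vaccines"] == 63

    def test_single_vaccine_full_coverage(self):
        config = GeneratorConfig(n_vaccines=1, ae_vocabulary=1, aes_per_vaccine=(1, 1), seed=0)
        records, _ = generate(config)
        kb = compile_kb(records, seed_terms_for(records))
        table = ae_frequency(kb)
        assert len(table.rows) == 1
        assert table.rows[0][2:] == (1, 100.0)

    def test_zero_vaccines(self):
        with pytest.raises(EmptyKBError):
            ae_frequency(KnowledgeBase())

    def test_percent_rounding_half_up(self):
        assert round_percent(34, 63) == 54.0
        assert round_percent(19, 63) == 30.2
        assert round_percent(1, 16) == 6.3  # 6.25 rounds up, not to even

    def test_conservation(self):
        kb = make_generated_kb(seed=11, n_vaccines=6, ae_vocabulary=9)
        table = ae_frequency(kb)
        incidence = {(a.ae, a.vaccine) for a in kb.associations}
        assert sum(r[2] for r in table.rows) == len(incidence)


class TestOccurrenceByAge:
    def test_single_adult_entry(self, seed_terms):
        records = load_fixture("typhim_vi")[:1]
        kb = compile_kb(records, seed_terms)
        table = occurrence_by_age(kb)
        rows = {r[0]: r for r in table.rows}
        assert rows["adult"][1] == 1
        assert rows["adult"][2] == pytest.approx(0.975)

    def test_child_adult_only(self):
        records = table2_records()  # all rows use the 0+ child-adult range
        kb = compile_kb(records, seed_terms_for(records))
        table = occurrence_by_age(kb)
        rows = {r[0]: r for r in table.rows}
        assert rows["child"][1] == 0
        assert rows["adult"][1] == 0
        assert rows["child-adult"][1] == len(records)

    def test_planted_shift_recovered(self):
        kb = make_generated_kb(
            seed=5, n_vaccines=20, ae_vocabulary=10, aes_per_vaccine=(5, 8),
            child_shift=0.15,
        )
        table = occurrence_by_age(kb)
        assert table.meta["child_exceeds_adult"] is True
        assert table.meta["child_mean"] > table.meta["adult_mean"]

    def test_interval_grouping(self, seed_terms):
        kb = compile_kb(load_fixture("typhim_vi"), seed_terms)
        table = occurrence_by_age(kb, group_by="interval")
        assert table.rows and all(r[0].startswith("[") for r in table.rows)


class TestMaxOccurrence:
    def test_typhim_vi(self, seed_terms):
        kb = compile_kb(load_fixture("typhim_vi"), seed_terms)
        vaccine, ae, interval, occurrence = max_occurrence(kb)
        assert vaccine == "Typhim Vi"
        assert ae == "injection-site tenderness AE"
        assert (interval.min_years, interval.max_years) == (18.0, 40.0)
        assert occurrence == pytest.approx(0.975)

    def test_tie_break_alphabetical(self):
        records = table2_records()  # every occurrence is 10%
        kb = compile_kb(records, seed_terms_for(records))
        vaccine, ae, _, _ = max_occurrence(kb)
        expected = min((a.vaccine_label, a.ae_label) for a in kb.associations)
        assert (vaccine, ae) == expected

    def test_empty(self):
        with pytest.raises(EmptyKBError):
            max_occurrence(KnowledgeBase())

    def test_matches_linear_scan(self):
        kb = make_generated_kb(seed=9, n_vaccines=7, ae_vocabulary=9)
        _, _, _, occurrence = max_occurrence(kb)
        brute = max(
            g.occurrence for a in kb.associations for g in a.groups
        )
        assert occurrence == brute


class TestSparqlLite:
    def test_fig3_query_matches_label_mode(self, afluria_kb):
        table = sparql_lite(afluria_kb, FIG3_QUERY)
        expected = count_vae_per_vaccine(afluria_kb, "label-convention")
        assert [(label, n) for _, label, n in expected.rows] == [
            (r[1], r[2]) for r in table.rows
        ]

    def test_subclassof_star_on_chain(self):
        kb = KnowledgeBase()
        c = kb.register_class(OntologyClass(TermId.make("TST", 3), "C"))
        b = kb.register_class(OntologyClass(TermId.make("TST", 2), "B", asserted_parents={c}))
        kb.register_class(OntologyClass(TermId.make("TST", 1), "A", asserted_parents={b}))
        table = sparql_lite(
            kb, "SELECT ?c WHERE { ?c rdfs:subClassOf* obo:TST_0000003 }"
        )
        assert len(table.rows) == 3

    def test_regex_filter_matches_brute_force(self):
        kb = make_generated_kb(seed=2, n_vaccines=5, ae_vocabulary=8)
        pattern = "associated"
        table = sparql_lite(
            kb,
            'SELECT ?c ?l WHERE { ?c rdfs:label ?l . FILTER regex(?l, "%s") }' % pattern,
        )
        rx = re.compile(pattern)
        brute = {
            (str(c.id), c.label) for c in kb.classes.values() if rx.search(c.label)
        }
        assert set(table.rows) == brute

    def test_limit(self, afluria_kb):
        table = sparql_lite(afluria_kb, "SELECT ?c WHERE { ?c rdfs:label ?l } LIMIT 4")
        assert len(table.rows) == 4

    @pytest.mark.parametrize(
        "query",
        [
            "ASK { ?c rdfs:label ?l }",
            "SELECT ?c WHERE { ?c owl:sameAs ?d }",
            "SELECT ?c WHERE { ?c rdfs:label ?l ",
        ],
    )
    def test_unsupported_syntax(self, query):
        with pytest.raises(QueryParseError):
            sparql_lite(KnowledgeBase(), query)
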