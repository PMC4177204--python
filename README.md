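# vaekb

A vaccine adverse-event (VAE) knowledge-base engine. Curated
package-insert-style records (one CSV row per vaccine × adverse event × age
group) are compiled into an ontology through a fixed design pattern,
classified with a small EL subsumption reasoner, serialized to canonical
Turtle, and analyzed with ranking / frequency / age-stratification queries.

## What is in the box

| module | role |
| --- | --- |
| `vaekb.kb_model` | term ids, class expressions, the knowledge base, term statistics |
| `vaekb.template_io` | read/validate/normalize the ten-column curation template CSV |
| `vaekb.axiom_builder` | compile associations into classes + pattern axioms, OVAE id minting |
| `vaekb.el_reasoner` | EL normalization, saturation, inferred-only subsumption edges |
| `vaekb.query_engine` | per-vaccine AE variety, AE frequency, age strata, max occurrence, SPARQL-lite |
| `vaekb.owl_io` | RDF triple view, canonical Turtle writer, subset Turtle reader |
| `vaekb.synthetic_fixtures` | bundled mini-ontology fixtures + a ground-truthed synthetic generator |

The compiled pattern axiom for one association reads:

```
<vaccine>-associated <ae> AE  SubClassOf
    'is preceded by' some ('vaccination with <vaccine>')
    and 'occurs in population' some (
        'human vaccinee population'
        and ( ('has age in year' in [a1,b1] and 'has VAE occurrence' value o1)
              or ... one disjunct per age group ) )
```

Leaf classes carry two asserted parents (the adverse-event term and the
per-vaccine grouping class), and label conventions ("associated ... AE"
leaves under "... adverse event" parents) support the regex-based queries.

## CLI

```sh
vaekb validate records.csv
vaekb build records.csv --seed-terms terms.csv -o kb.ttl [--classify]
vaekb classify kb.ttl -o kb.classified.ttl --report inferred_edges.tsv
vaekb query kb.ttl --analysis per-vaccine|ae-frequency|by-age|max-occurrence [--top N]
vaekb sparql kb.ttl -q query.rq
vaekb simulate --config sim.yaml --seed 7 -o records.csv --truth truth.json
```

`vaekb sparql` accepts the supported SPARQL subset: `SELECT` with variables
and one `(COUNT(?v) AS ?alias)`, triple patterns over `rdfs:subClassOf`
(optionally `rdfs:subClassOf*` for the transitive closure) and
`rdfs:label`, case-sensitive `FILTER regex`, `GROUP BY`, `ORDER BY
[DESC|ASC]`, `LIMIT`.

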