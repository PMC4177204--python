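# Bundled fixture data

All fixtures are small plain-text CSVs so the package is testable offline.

Provenance:

* `table2.csv`, `table3.csv` — per-vaccine AE-variety counts and
  cross-vaccine AE frequency rows transcribed from the published OVAE
  knowledge-base summary tables (terms carry their public VO/OAE ids).
* `figure4_terms.csv`, `seed_terms.csv` — mini asserted hierarchy of the
  most frequently reported adverse-event classes, reconstructed from the
  published OVAE/OAE hierarchy description. Some intermediate ids
  (e.g. `OAE_0000004`, `OAE_0000777`, `UBERON_0012338`) are stand-ins, not
  the released ids.
* `afluria.csv` — the nine Afluria-associated adverse events. The AE list
  and single-vaccine structure are factual; **age ranges and occurrence
  percentages are synthetic placeholders** (the public source presents them
  only in figure images), as is the VO id.
* `afluria_pain_groups.csv` — the three-age-group curation rows for
  Afluria-associated injection-site pain; ages/occurrences synthetic.
* `typhim_vi.csv` — Typhim Vi records; the 97.5% injection-site tenderness
  rate at ages 18–40 is factual, other rows are synthetic filler.
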