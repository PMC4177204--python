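"""Bundled mini-ontology fixtures and a synthetic dataset generator.

The bundled CSVs transcribe structural facts from the published OVAE
knowledge-base summary (per-vaccine AE variety, cross-vaccine AE frequency,
the asserted mini-hierarchy of the most frequent AEs, and per-source term
counts); occurrence values that are not legible from public text are
synthetic and marked as such in the data README.  The generator produces
arbitrary-scale template datasets with exact ground-truth bookkeeping.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .errors import ConfigError, FixtureNotFoundError
from .kb_model import (
    And,
    KnowledgeBase,
    NamedClass,
    OCCURS_IN,
    ObjectSome,
    TermId,
)
from .template_io import TemplateRecord, categorize_age, parse_age_years

# Per-source class counts of the released knowledge base (summary table);
# the class column is the self-consistent one and sums to 1189.
TABLE1_CLASS_COUNTS: dict[str, int] = {
    "OVAE": 626,
    "BFO": 40,
    "CHEBI": 7,
    "OBI": 8,
    "PATO": 7,
    "IAO": 6,
    "NCBITaxon": 81,
    "OAE": 119,
    "OGMS": 2,
    "UBERON": 105,
    "VO": 188,
}

# Cross-vaccine AE frequency rows: (label, OAE id, number of reporting
# vaccines out of 63).
TABLE3_ROWS: list[tuple[str, str, int]] = [
    ("injection-site pain AE", "OAE_0000369", 43),
    ("headache AE", "OAE_0000377", 39),
    ("fever AE", "OAE_0000361", 34),
    ("local swelling AE", "OAE_0001139", 30),
    ("injection-site redness AE", "OAE_0001546", 25),
    ("irritability AE", "OAE_0001105", 23),
    ("malaise AE", "OAE_0000390", 21),
    ("injection-site erythema AE", "OAE_0000644", 20),
    ("myalgia AE", "OAE_0000375", 19),
    ("fatigue AE", "OAE_0000034", 18),
]

TABLE3_TOTAL_VACCINES = 63

_FIXTURE_FILES = {
    "afluria": "afluria.csv",
    "afluria_pain_groups": "afluria_pain_groups.csv",
    "typhim_vi": "typhim_vi.csv",
    "table2": "table2.csv",
    "table3": "table3.csv",
    "figure4": "figure4_terms.csv",
    "seed_terms": "seed_terms.csv",
}


def _data_path(name: str):
    return resources.files("vaekb.data").joinpath(name)


def read_seed_terms(path) -> list[tuple[str, str, list[str], str]]:
    """Read a seed term table: ``id,label,parent_ids,source`` with
    pipe-separated parent ids."""
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_seed_rows(fh)


def _parse_seed_rows(fh) -> list[tuple[str, str, list[str], str]]:
    from .errors import SchemaError

    reader = csv.DictReader(fh)
    required = {"id", "label", "parent_ids", "source"}
    if reader.fieldnames is None or set(reader.fieldnames) != required:
        raise SchemaError(
            "seed term table needs columns id,label,parent_ids,source"
        )
    rows = []
    for row in reader:
        parents = [p for p in (row["parent_ids"] or "").split("|") if p]
        rows.append((row["id"], row["label"], parents, row["source"]))
    return rows


def load_fixture(name: str):
    """Load a bundled fixture.

    * ``afluria``, ``afluria_pain_groups``, ``typhim_vi`` — template records
    * ``table2`` — list of (vaccine label, VO id, AE-variety count)
    * ``table3`` — list of (AE label, OAE id, vaccine count, percent)
    * ``seed_terms`` — seed term rows for :func:`vaekb.axiom_builder.compile_kb`
    * ``figure4`` — a ready KnowledgeBase of the top-AE mini-hierarchy with
      definitional expressions attached (CSV alone cannot carry them)
    """
    if name not in _FIXTURE_FILES:
        raise FixtureNotFoundError(f"unknown fixture: {name!r}")
    path = _data_path(_FIXTURE_FILES[name])
    if name in {"afluria", "afluria_pain_groups", "typhim_vi"}:
        from .template_io import read_template

        with resources.as_file(path) as p:
            return read_template(p)
    if name == "table2":
        with path.open(newline="", encoding="utf-8") as fh:
            return [
                (r["vaccine_name"], r["vaccine_vo_id"], int(r["n_vae"]))
                for r in csv.DictReader(fh)
            ]
    if name == "table3":
        with path.open(newline="", encoding="utf-8") as fh:
            return [
                (r["ae_name"], r["oae_id"], int(r["n_vaccines"]), float(r["percent"]))
                for r in csv.DictReader(fh)
            ]
    if name == "seed_terms":
        with path.open(newline="", encoding="utf-8") as fh:
            return _parse_seed_rows(fh)
    return figure4_kb()


def seed_terms_fixture():
    return load_fixture("seed_terms")


def figure4_kb() -> KnowledgeBase:
    """The asserted mini-hierarchy of the ten most frequent AE classes.

    Two injection-site classes carry an ``occurs in some injection site``
    existential; 'injection-site adverse event' is defined by equivalence as
    ``adverse event and (occurs in some injection site)`` so classification
    places exactly those two classes under it.
    """
    kb = KnowledgeBase()
    from .axiom_builder import _register_seed_terms

    with resources.as_file(_data_path(_FIXTURE_FILES["figure4"])) as p:
        _register_seed_terms(kb, read_seed_terms(p))
    injection_site = kb.id_for_label("injection site")
    adverse_event = kb.id_for_label("adverse event")
    occurs_at_site = ObjectSome(OCCURS_IN, NamedClass(injection_site))
    for label in ("injection-site pain AE", "injection-site redness AE"):
        kb.get(kb.id_for_label(label)).defining_expression = occurs_at_site
    isae = kb.get(kb.id_for_label("injection-site adverse event"))
    isae.defining_expression = And((NamedClass(adverse_event), occurs_at_site))
    isae.definition_is_equivalence = True
    return kb


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    n_vaccines: int = 10
    ae_vocabulary: int = 12
    aes_per_vaccine: tuple[int, int] = (2, 6)  # inclusive uniform range
    age_scheme: tuple[str, ...] = ("0-17", "18-64")
    adult_mean: float = 0.2
    child_shift: float = 0.1  # added to the child-category mean
    concentration: float = 10.0  # Beta pseudo-count total
    planted_ae_vaccine_counts: Optional[dict[str, int]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_vaccines < 1 or self.ae_vocabulary < 1:
            raise ConfigError("need at least one vaccine and one AE")
        lo, hi = self.aes_per_vaccine
        if lo < 0 or lo > hi:
            raise ConfigError(f"bad aes_per_vaccine range: {self.aes_per_vaccine}")
        if hi > self.ae_vocabulary:
            raise ConfigError("aes_per_vaccine exceeds the AE vocabulary size")
        if not self.age_scheme:
            raise ConfigError("age_scheme must list at least one age range")
        for mean in (self.adult_mean, self.adult_mean + self.child_shift):
            if not 0 < mean < 1:
                raise ConfigError(f"occurrence mean outside (0,1): {mean}")
        if self.planted_ae_vaccine_counts:
            for label, count in self.planted_ae_vaccine_counts.items():
                if count > self.n_vaccines:
                    raise ConfigError(
                        f"planted count for {label!r} exceeds n_vaccines"
                    )


@dataclass
class GroundTruth:
    vae_per_vaccine: dict[str, int] = field(default_factory=dict)
    vaccines_per_ae: dict[str, int] = field(default_factory=dict)
    mean_occurrence_by_category: dict[str, float] = field(default_factory=dict)


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def generate(config: GeneratorConfig) -> tuple[list[TemplateRecord], GroundTruth]:
    """Produce template records plus exact bookkeeping of what was planted.

    Deterministic for a fixed config (seed included).  Planted per-AE
    vaccine counts, when given, assign each listed AE to exactly that many
    vaccines; remaining AE picks are uniform draws from the synthetic
    vocabulary.
    """
    config.validate()
    rng = random.Random(config.seed)
    vaccines = [
        (f"Synthetic vaccine {i + 1:03d}", TermId.make("VO", 9000001 + i))
        for i in range(config.n_vaccines)
    ]
    ae_vocab = [
        (f"synthetic condition {i + 1:03d} AE", TermId.make("OAE", 9000001 + i))
        for i in range(config.ae_vocabulary)
    ]
    # planted AE labels join the vocabulary, reusing public ids when known
    known_ids = {label: TermId.parse(id_text) for label, id_text, _ in TABLE3_ROWS}
    existing = {label for label, _ in ae_vocab}
    for j, label in enumerate(sorted(config.planted_ae_vaccine_counts or ())):
        if label not in existing:
            ae_vocab.append(
                (label, known_ids.get(label, TermId.make("OAE", 9500001 + j)))
            )
    ae_by_label = {label: term for label, term in ae_vocab}

    chosen: dict[int, set[str]] = {i: set() for i in range(config.n_vaccines)}
    if config.planted_ae_vaccine_counts:
        for label, count in sorted(config.planted_ae_vaccine_counts.items()):
            if label not in ae_by_label:
                raise ConfigError(f"planted AE not in vocabulary: {label!r}")
            holders = rng.sample(range(config.n_vaccines), count)
            for i in holders:
                chosen[i].add(label)
    lo, hi = config.aes_per_vaccine
    planted_labels = set(config.planted_ae_vaccine_counts or ())
    free_labels = [label for label, _ in ae_vocab if label not in planted_labels]
    for i in range(config.n_vaccines):
        extra = rng.randint(lo, hi)
        pool = [l for l in free_labels if l not in chosen[i]]
        rng.shuffle(pool)
        chosen[i].update(pool[:extra])

    occurrences_by_category: dict[str, list[float]] = {}
    records: list[TemplateRecord] = []
    for i, (vaccine_label, vo_id) in enumerate(vaccines):
        for ae_label in sorted(chosen[i]):
            oae_id = ae_by_label[ae_label]
            location = (
                "injection-site" if "injection-site" in ae_label else "systemic"
            )
            for age_expr in config.age_scheme:
                interval = parse_age_years(age_expr)
                category = categorize_age(interval)
                mean = config.adult_mean + (
                    config.child_shift if category == "child" else 0.0
                )
                alpha, beta = _beta_params(mean, config.concentration)
                occurrence = min(max(rng.betavariate(alpha, beta), 1e-4), 0.9999)
                occurrences_by_category.setdefault(category, []).append(occurrence)
                records.append(
                    TemplateRecord(
                        vaccine_name=vaccine_label,
                        vaccine_vo_id=vo_id,
                        vae_location=location,
                        vae_name_insert=ae_label.replace(" AE", ""),
                        vae_name_oae=ae_label,
                        oae_id=oae_id,
                        age_category=category,
                        age_years=age_expr,
                        vae_occurrence=f"{occurrence * 100:.4f}%",
                        reference=f"synthetic insert for {vaccine_label}",
                    )
                )
    truth = GroundTruth(
        vae_per_vaccine={
            vaccines[i][0]: len(chosen[i]) for i in range(config.n_vaccines)
        },
        vaccines_per_ae={
            label: sum(1 for i in chosen if label in chosen[i])
            for label, _ in ae_vocab
            if any(label in chosen[i] for i in chosen)
        },
        mean_occurrence_by_category={
            cat: sum(vals) / len(vals)
            for cat, vals in occurrences_by_category.items()
        },
    )
    return records, truth


def seed_terms_for(records: list[TemplateRecord]):
    """Minimal seed term table covering the AE terms a record set needs."""
    root_id = "OAE_0000001"
    rows = [
        (root_id, "adverse event", [], "OAE"),
        ("VO_0000001", "vaccine", [], "VO"),
    ]
    seen = {root_id, "VO_0000001"}
    for record in sorted(records, key=lambda r: str(r.oae_id)):
        id_text = str(record.oae_id)
        if id_text in seen:
            continue
        seen.add(id_text)
        rows.append((id_text, record.vae_name_oae, [root_id], "OAE"))
    return rows


def table2_records(
    filler_vaccines: int = 0, filler_max_aes: int = 12, seed: int = 0
) -> list[TemplateRecord]:
    """Template records realizing the per-vaccine AE-variety fixture.

    Each listed vaccine receives exactly its listed number of distinct AE
    associations from a synthetic vocabulary; optional filler vaccines get
    1..``filler_max_aes`` each (always fewer than the listed minimum matters
    for, i.e. the planted ranking is preserved).
    """
    rng = random.Random(seed)
    table2 = load_fixture("table2")
    max_needed = max(n for _, _, n in table2)
    vocab = [
        (f"synthetic condition {i + 1:03d} AE", TermId.make("OAE", 9000001 + i))
        for i in range(max(max_needed, filler_max_aes))
    ]
    records: list[TemplateRecord] = []

    def add(vaccine_label: str, vo_id: TermId, n_aes: int) -> None:
        for ae_label, oae_id in vocab[:n_aes]:
            records.append(
                TemplateRecord(
                    vaccine_name=vaccine_label,
                    vaccine_vo_id=vo_id,
                    vae_location="systemic",
                    vae_name_insert=ae_label.replace(" AE", ""),
                    vae_name_oae=ae_label,
                    oae_id=oae_id,
                    age_category="child-adult",
                    age_years="0+",
                    vae_occurrence="10%",
                    reference=f"synthetic insert for {vaccine_label}",
                )
            )

    for vaccine_label, vo_id_text, n_aes in table2:
        add(vaccine_label, TermId.parse(vo_id_text), n_aes)
    for i in range(filler_vaccines):
        add(
            f"Filler vaccine {i + 1:03d}",
            TermId.make("VO", 9100001 + i),
            rng.randint(1, filler_max_aes),
        )
    return records
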