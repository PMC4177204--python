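"""Curation-template CSV input: parsing, validation, normalization.

The template is a ten-column CSV (UTF-8, comma-separated, quoted fields),
one row per (vaccine, adverse event, age group) observation as curated from
package-insert "Adverse Reactions" sections.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import (
    ConflictError,
    OverlapError,
    ParseError,
    RangeError,
    RowError,
    SchemaError,
    ValidationWarning,
)
from .kb_model import AgeInterval, TermId, VAEAssociation, VaccineeGroup

TEMPLATE_COLUMNS = (
    "vaccine_name",
    "vaccine_vo_id",
    "vae_location",
    "vae_name_insert",
    "vae_name_oae",
    "oae_id",
    "age_category",
    "age_years",
    "vae_occurrence",
    "reference",
)

_CATEGORIES = {"child", "adult", "senior", "child-adult"}
_LOCATIONS = {"injection-site", "systemic"}


@dataclass(frozen=True)
class TemplateRecord:
    vaccine_name: str
    vaccine_vo_id: TermId
    vae_location: str
    vae_name_insert: str
    vae_name_oae: str
    oae_id: TermId
    age_category: str
    age_years: str
    vae_occurrence: str
    reference: str


# ---------------------------------------------------------------------------
# Field parsers
# ---------------------------------------------------------------------------

_ENDPOINT_RE = re.compile(r"^(\d+(?:\.\d+)?)(mo)?$")


def _parse_endpoint(token: str) -> tuple[float, bool]:
    """Return (value in years, was given in months)."""
    m = _ENDPOINT_RE.match(token.strip())
    if not m:
        raise ParseError(f"bad age token: {token!r}")
    value = float(m.group(1))
    if m.group(2):
        return value / 12.0, True
    return value, False


def parse_age_years(expr: str) -> AgeInterval:
    """Parse an age-range expression into a closed interval in years.

    Grammar: ``<num>`` (a single age, widened to one unit: ``[n, n+1]`` for
    years, ``[n/12, (n+1)/12]`` for months), ``<num>-<num>``, ``<num>+``
    (unbounded above), with an optional ``mo`` suffix per endpoint meaning
    months (divided by 12).  En dashes are accepted as range separators.
    """
    text = expr.strip().replace("–", "-")
    if not text:
        raise ParseError("empty age expression")
    if text.endswith("+"):
        lo, _ = _parse_endpoint(text[:-1])
        return AgeInterval(lo, None)
    if "-" in text:
        left, _, right = text.partition("-")
        lo, _ = _parse_endpoint(left)
        hi, _ = _parse_endpoint(right)
        if lo >= hi:
            raise RangeError(f"empty age range: {expr!r}")
        return AgeInterval(lo, hi)
    value, in_months = _parse_endpoint(text)
    width = 1.0 / 12.0 if in_months else 1.0
    return AgeInterval(value, value + width)


def parse_occurrence(expr: str) -> float:
    """Parse an occurrence: ``<num>%`` or a bare fraction in [0, 1]."""
    text = expr.strip()
    if not text:
        raise ParseError("empty occurrence expression")
    if text.endswith("%"):
        try:
            pct = float(text[:-1])
        except ValueError:
            raise ParseError(f"bad occurrence: {expr!r}") from None
        if pct < 0 or pct > 100:
            raise RangeError(f"percentage outside [0, 100]: {expr!r}")
        return pct / 100.0
    try:
        value = float(text)
    except ValueError:
        raise ParseError(f"bad occurrence: {expr!r}") from None
    if value < 0 or value > 1:
        raise RangeError(f"bare occurrence outside [0, 1]: {expr!r}")
    return value


def categorize_age(interval: AgeInterval) -> str:
    """Assign an age category: child (max <= 18), senior (min >= 65),
    adult (18 <= min < 65), child-adult (straddles 18)."""
    hi = interval.max_years if interval.max_years is not None else float("inf")
    if hi <= 18:
        return "child"
    if interval.min_years >= 65:
        return "senior"
    if interval.min_years >= 18:
        return "adult"
    return "child-adult"


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_template(path) -> list[TemplateRecord]:
    """Read and validate a template CSV; returns records in file order.

    Raises :class:`SchemaError` if the header does not consist of exactly
    the ten template columns, :class:`RowError` (with the 1-based data-row
    number) for unparseable rows.  A declared age category that disagrees
    with the category computed from the age range triggers a
    :class:`ValidationWarning`, not an error.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: no header") from None
        header = [h.strip() for h in header]
        missing = [c for c in TEMPLATE_COLUMNS if c not in header]
        extra = [c for c in header if c not in TEMPLATE_COLUMNS]
        if missing or extra:
            parts = []
            if missing:
                parts.append("missing columns: " + ", ".join(missing))
            if extra:
                parts.append("unexpected columns: " + ", ".join(extra))
            raise SchemaError("; ".join(parts))
        index = [header.index(c) for c in TEMPLATE_COLUMNS]
        records: list[TemplateRecord] = []
        for row_number, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise RowError(row_number, f"expected {len(header)} fields, got {len(row)}")
            values = [row[i].strip() for i in index]
            try:
                record = _parse_record(values)
            except (ParseError, RangeError) as exc:
                raise RowError(row_number, str(exc)) from exc
            records.append(record)
    return records


def _parse_record(values: list[str]) -> TemplateRecord:
    (name, vo_id, location, insert_name, oae_name, oae_id,
     category, age_years, occurrence, reference) = values
    if location not in _LOCATIONS:
        raise ParseError(f"unknown VAE location: {location!r}")
    if category not in _CATEGORIES:
        raise ParseError(f"unknown age category: {category!r}")
    interval = parse_age_years(age_years)
    parse_occurrence(occurrence)
    computed = categorize_age(interval)
    if computed != category and not (computed == "senior" and category == "adult"):
        warnings.warn(
            f"declared age category {category!r} != computed {computed!r} "
            f"for age {age_years!r} ({name} / {oae_name})",
            ValidationWarning,
            stacklevel=3,
        )
    return TemplateRecord(
        vaccine_name=name,
        vaccine_vo_id=TermId.parse(vo_id),
        vae_location=location,
        vae_name_insert=insert_name,
        vae_name_oae=oae_name,
        oae_id=TermId.parse(oae_id),
        age_category=category,
        age_years=age_years,
        vae_occurrence=occurrence,
        reference=reference,
    )


def write_template(records: Iterable[TemplateRecord], path) -> None:
    """Write records back to CSV; inverse of :func:`read_template`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TEMPLATE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.vaccine_name,
                    str(r.vaccine_vo_id),
                    r.vae_location,
                    r.vae_name_insert,
                    r.vae_name_oae,
                    str(r.oae_id),
                    r.age_category,
                    r.age_years,
                    r.vae_occurrence,
                    r.reference,
                ]
            )


# ---------------------------------------------------------------------------
# Normalization into associations
# ---------------------------------------------------------------------------


def records_to_associations(records: list[TemplateRecord]) -> list[VAEAssociation]:
    """Merge rows sharing (vaccine id, AE id) into single associations.

    Each row contributes one (age interval, occurrence) vaccinee group;
    groups are sorted by ascending minimum age.  Associations are returned
    sorted by (vaccine name, AE name), so the result does not depend on the
    input row order.  Overlapping intervals within one pair raise
    :class:`OverlapError`; disagreeing locations raise :class:`ConflictError`.
    """
    merged: dict[tuple[TermId, TermId], VAEAssociation] = {}
    for record in records:
        key = (record.vaccine_vo_id, record.oae_id)
        interval = parse_age_years(record.age_years)
        group = VaccineeGroup(
            interval=interval,
            category=record.age_category,
            occurrence=parse_occurrence(record.vae_occurrence),
        )
        if key not in merged:
            merged[key] = VAEAssociation(
                vaccine=record.vaccine_vo_id,
                ae=record.oae_id,
                location=record.vae_location,
                groups=[group],
                reference=record.reference,
                vaccine_label=record.vaccine_name,
                ae_label=record.vae_name_oae,
            )
            continue
        assoc = merged[key]
        if assoc.location != record.vae_location:
            raise ConflictError(
                f"conflicting locations for ({record.vaccine_name}, "
                f"{record.vae_name_oae}): {assoc.location} vs {record.vae_location}"
            )
        for existing in assoc.groups:
            if existing.interval.overlaps(interval):
                raise OverlapError(
                    f"overlapping age intervals for ({record.vaccine_name}, "
                    f"{record.vae_name_oae}): {existing.interval} vs {interval}"
                )
        assoc.groups.append(group)
    out = sorted(merged.values(), key=lambda a: (a.vaccine_label, a.ae_label))
    for assoc in out:
        assoc.groups.sort(key=lambda g: g.interval.min_years)
    return out
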