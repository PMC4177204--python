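import random
import warnings

import pytest

from vaekb.errors import (
    ConflictError,
    OverlapError,
    ParseError,
    RangeError,
    RowError,
    SchemaError,
    ValidationWarning,
)
from vaekb.kb_model import AgeInterval
from vaekb.synthetic_fixtures import load_fixture
from vaekb.template_io import (
    TEMPLATE_COLUMNS,
    categorize_age,
    parse_age_years,
    parse_occurrence,
    read_template,
    records_to_associations,
    write_template,
)


class TestParseAgeYears:
    def test_plain_range(self):
        assert parse_age_years("18-40") == AgeInterval(18.0, 40.0)

    def test_en_dash(self):
        assert parse_age_years("18–40") == AgeInterval(18.0, 40.0)

    def test_open_ended(self):
        assert parse_age_years("65+") == AgeInterval(65.0, None)

    def test_months(self):
        interval = parse_age_years("6mo-35mo")
        assert interval.min_years == pytest.approx(0.5)
        assert interval.max_years == pytest.approx(35 / 12)

    def test_single_age_widened_one_year(self):
        assert parse_age_years("2") == AgeInterval(2.0, 3.0)

    def test_single_month_age_widened_one_month(self):
        interval = parse_age_years("6mo")
        assert interval.min_years == pytest.approx(0.5)
        assert interval.max_years == pytest.approx(7 / 12)

    def test_inverted_range(self):
        with pytest.raises(RangeError):
            parse_age_years("40-18")

    def test_garbage(self):
        with pytest.raises(ParseError):
            parse_age_years("eighteen")


class TestParseOccurrence:
    def test_percent(self):
        assert parse_occurrence("97.5%") == pytest.approx(0.975)

    def test_zero(self):
        assert parse_occurrence("0") == 0.0

    def test_bare_above_one(self):
        with pytest.raises(RangeError):
            parse_occurrence("1.5")

    def test_percent_above_hundred(self):
        with pytest.raises(RangeError):
            parse_occurrence("150%")

    def test_negative(self):
        with pytest.raises((RangeError, ParseError)):
            parse_occurrence("-5%")

    def test_garbage(self):
        with pytest.raises(ParseError):
            parse_occurrence("lots")


class TestCategorizeAge:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (18, 40, "adult"),
            (0, 18, "child"),
            (2, 49, "child-adult"),
            (65, None, "senior"),
            (70, 80, "senior"),
            (18, None, "adult"),
            (0, None, "child-adult"),
        ],
    )
    def test_rules(self, lo, hi, expected):
        assert categorize_age(AgeInterval(float(lo), hi if hi is None else float(hi))) == expected


class TestReadTemplate:
    def test_afluria_fixture(self):
        records = load_fixture("afluria")
        assert len(records) == 9
        assert all(r.vaccine_name == "Afluria" for r in records)
        assert len({r.oae_id for r in records}) == 9

    def test_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(TEMPLATE_COLUMNS) + "\n")
        assert read_template(path) == []

    def test_missing_column(self, tmp_path):
        cols = [c for c in TEMPLATE_COLUMNS if c != "reference"]
        path = tmp_path / "bad.csv"
        path.write_text(",".join(cols) + "\n")
        with pytest.raises(SchemaError, match="reference"):
            read_template(path)

    def test_bad_row_reports_row_number(self, tmp_path):
        path = tmp_path / "rows.csv"
        good = "Afluria,VO_0004810,systemic,fever,fever AE,OAE_0000361,child,5-17,16%,ref"
        bad = "Afluria,VO_0004810,systemic,fever,fever AE,not-an-id,child,5-17,16%,ref"
        path.write_text(",".join(TEMPLATE_COLUMNS) + "\n" + good + "\n" + bad + "\n")
        with pytest.raises(RowError) as err:
            read_template(path)
        assert err.value.row_number == 2

    def test_category_mismatch_warns(self, tmp_path):
        path = tmp_path / "warn.csv"
        row = "Afluria,VO_0004810,systemic,fever,fever AE,OAE_0000361,adult,5-17,16%,ref"
        path.write_text(",".join(TEMPLATE_COLUMNS) + "\n" + row + "\n")
        with pytest.warns(ValidationWarning):
            records = read_template(path)
        assert len(records) == 1

    def test_round_trip(self, tmp_path):
        records = load_fixture("afluria")
        out = tmp_path / "again.csv"
        write_template(records, out)
        assert read_template(out) == records


class TestParsingProperties:
    from hypothesis import given, strategies as st

    @given(st.floats(min_value=0, max_value=100, allow_nan=False).map(lambda x: round(x, 3)))
    def test_percent_round_trip(self, pct):
        assert parse_occurrence(f"{pct}%") == pytest.approx(pct / 100.0)

    @given(
        st.integers(min_value=0, max_value=120),
        st.integers(min_value=1, max_value=80),
    )
    def test_range_parses_and_categorizes(self, lo, width):
        interval = parse_age_years(f"{lo}-{lo + width}")
        assert interval == AgeInterval(float(lo), float(lo + width))
        assert categorize_age(interval) in {"child", "adult", "senior", "child-adult"}

    @given(st.integers(min_value=0, max_value=9_999_999), st.sampled_from(["OAE", "VO", "OVAE"]))
    def test_term_id_round_trip(self, serial, prefix):
        from vaekb.kb_model import TermId

        term = TermId.make(prefix, serial)
        assert TermId.parse(str(term)) == term


class TestRecordsToAssociations:
    def test_three_age_groups_merge(self):
        records = load_fixture("afluria_pain_groups")
        assocs = records_to_associations(records)
        assert len(assocs) == 1
        assert len(assocs[0].groups) == 3
        mins = [g.interval.min_years for g in assocs[0].groups]
        assert mins == sorted(mins)

    def test_single_row_identity(self):
        records = load_fixture("afluria")[:1]
        assocs = records_to_associations(records)
        assert len(assocs) == 1 and len(assocs[0].groups) == 1

    def test_order_insensitive(self):
        records = list(load_fixture("afluria")) + list(load_fixture("afluria_pain_groups"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shuffled = records[:]
            random.Random(3).shuffle(shuffled)
            with pytest.raises(OverlapError):
                # afluria.csv already has an 18-64 pain row; the grouped
                # fixture adds another -> overlap, regardless of order
                records_to_associations(records)
            with pytest.raises(OverlapError):
                records_to_associations(shuffled)

    def test_order_insensitive_clean(self):
        records = list(load_fixture("afluria"))
        shuffled = records[:]
        random.Random(5).shuffle(shuffled)
        assert records_to_associations(records) == records_to_associations(shuffled)

    def test_overlap_error(self):
        base = load_fixture("afluria_pain_groups")[0]
        from dataclasses import replace

        overlapping = replace(base, age_years="0-10", age_category="child")
        other = replace(base, age_years="5-20", age_category="child-adult")
        with pytest.raises(OverlapError):
            records_to_associations([overlapping, other])

    def test_conflicting_location(self):
        from dataclasses import replace

        base = load_fixture("afluria_pain_groups")[0]
        systemic = replace(base, age_years="30-40", vae_location="systemic",
                           age_category="adult")
        with pytest.raises(ConflictError):
            records_to_associations([base, systemic])
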