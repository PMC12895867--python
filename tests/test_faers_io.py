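"""faers_io: ASCII parsing, partial dates, report assembly, deduplication."""

import datetime

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal import faers_io
from pvsignal.faers_io import (
    PartialDate,
    RawRecordSet,
    assemble_reports,
    classify_route,
    deduplicate,
    parse_ascii_table,
    parse_partial_date,
)

from conftest import make_report


class TestParseAsciiTable:
    def test_single_row_identity(self):
        rs = parse_ascii_table("PRIMARYID$CASEID$EVENT_DT\n1001$555$20190301", "DEMO")
        assert rs.rows == [{"PRIMARYID": "1001", "CASEID": "555", "EVENT_DT": "20190301"}]

    def test_empty_stream_after_header(self):
        rs = parse_ascii_table("PRIMARYID$CASEID\n", "DEMO")
        assert rs.rows == [] and rs.rejects == []

    def test_malformed_line_goes_to_rejects(self):
        text = "PRIMARYID$CASEID$PT\n1$10$NAUSEA\n2$20\n3$30$RASH\n"
        rs = parse_ascii_table(text, "REAC")
        assert len(rs.rows) == 2
        assert len(rs.rejects) == 1
        assert rs.rejects[0].line_number == 3

    def test_missing_key_column_is_hard_error(self):
        with pytest.raises(ValueError, match="PRIMARYID"):
            parse_ascii_table("CASEID$PT\n10$NAUSEA", "REAC", "modern")

    def test_values_trimmed_empties_preserved(self):
        rs = parse_ascii_table("PRIMARYID$AGE$SEX\n7$ 42 $\n", "DEMO")
        assert rs.rows[0] == {"PRIMARYID": "7", "AGE": "42", "SEX": ""}

    def test_legacy_dialect_keyed_by_isr(self):
        rs = parse_ascii_table("ISR$CASE$PT\n900$55$RASH", "REAC", dialect="legacy")
        assert rs.rows[0]["ISR"] == "900"
        with pytest.raises(ValueError, match="ISR"):
            parse_ascii_table("PRIMARYID$PT\n900$RASH", "REAC", dialect="legacy")


class TestPartialDate:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("20190301", PartialDate(2019, 3, 1, "day")),
            ("201903", PartialDate(2019, 3, None, "month")),
            ("2019", PartialDate(2019, None, None, "year")),
            ("", PartialDate()),
            ("20191341", PartialDate()),   # impossible month
            ("20190230", PartialDate()),   # impossible day
            ("1234567", PartialDate()),    # odd length
            ("ABCDEFGH", PartialDate()),   # non-digits
        ],
    )
    def test_parse(self, token, expected):
        assert parse_partial_date(token) == expected

    @given(st.dates(min_value=datetime.date(1900, 1, 1), max_value=datetime.date(2100, 12, 31)))
    def test_roundtrip_on_full_dates(self, d):
        token = d.strftime("%Y%m%d")
        pd_ = parse_partial_date(token)
        assert pd_.precision == "day"
        assert pd_.format() == token
        assert pd_.to_date() == d


class TestAssembleReports:
    def _demo(self, rows):
        return RawRecordSet("DEMO", rows, "2023Q1", "modern")

    def test_age_conversion_years(self):
        reports, _ = assemble_reports([self._demo(
            [{"PRIMARYID": "1", "CASEID": "1", "AGE": "72", "AGE_COD": "YR"}])])
        assert reports[0].age_years == 72.0

    def test_age_conversion_months(self):
        reports, _ = assemble_reports([self._demo(
            [{"PRIMARYID": "1", "CASEID": "1", "AGE": "6", "AGE_COD": "MON"}])])
        assert reports[0].age_years == pytest.approx(0.5)

    @pytest.mark.parametrize("code,expected", [
        ("DEC", 70.0), ("WK", 26 / 52.14), ("DY", 7 / 365.25), ("HR", 7 / 8766),
    ])
    def test_age_unit_factors(self, code, expected):
        age = "7" if code != "WK" else "26"
        reports, _ = assemble_reports([self._demo(
            [{"PRIMARYID": "1", "CASEID": "1", "AGE": age, "AGE_COD": code}])])
        assert reports[0].age_years == pytest.approx(expected)

    def test_reporter_qualification_mapping(self):
        reports, _ = assemble_reports([self._demo(
            [{"PRIMARYID": "1", "CASEID": "1", "OCC_COD": "MD"},
             {"PRIMARYID": "2", "CASEID": "2", "OCC_COD": "CN"},
             {"PRIMARYID": "3", "CASEID": "3", "OCC_COD": "XX"}])])
        quals = {r.primaryid: r.reporter_qualification for r in reports}
        assert quals == {"1": "physician", "2": "consumer", "3": "unknown"}

    def test_orphan_child_rows_rejected(self):
        reac = RawRecordSet("REAC", [{"PRIMARYID": "99", "PT": "NAUSEA"}], "2023Q1", "modern")
        reports, rejects = assemble_reports(
            [self._demo([{"PRIMARYID": "1", "CASEID": "1"}]), reac])
        assert len(reports) == 1 and reports[0].reaction_pts == frozenset()
        assert len(rejects) == 1 and "no DEMO row" in rejects[0].reason

    def test_child_row_conservation(self):
        # every non-rejected DRUG/REAC row lands in exactly one report
        demo = self._demo([{"PRIMARYID": str(i), "CASEID": str(i)} for i in range(1, 4)])
        drug = RawRecordSet("DRUG", [
            {"PRIMARYID": "1", "DRUG_SEQ": "1", "ROLE_COD": "PS", "DRUGNAME": "A", "ROUTE": ""},
            {"PRIMARYID": "2", "DRUG_SEQ": "1", "ROLE_COD": "SS", "DRUGNAME": "B", "ROUTE": ""},
            {"PRIMARYID": "2", "DRUG_SEQ": "2", "ROLE_COD": "C", "DRUGNAME": "C", "ROUTE": ""},
        ], "2023Q1", "modern")
        reac = RawRecordSet("REAC", [
            {"PRIMARYID": "1", "PT": "NAUSEA"}, {"PRIMARYID": "3", "PT": "RASH"},
        ], "2023Q1", "modern")
        reports, rejects = assemble_reports([demo, drug, reac])
        assert not rejects
        assert sum(len(r.drugs) for r in reports) == 3
        assert sum(len(r.reaction_pts) for r in reports) == 2

    def test_therapy_start_earliest_for_primary_suspect(self):
        demo = self._demo([{"PRIMARYID": "1", "CASEID": "1"}])
        drug = RawRecordSet("DRUG", [
            {"PRIMARYID": "1", "DRUG_SEQ": "1", "ROLE_COD": "PS", "DRUGNAME": "A", "ROUTE": ""},
            {"PRIMARYID": "1", "DRUG_SEQ": "2", "ROLE_COD": "SS", "DRUGNAME": "B", "ROUTE": ""},
        ], "2023Q1", "modern")
        ther = RawRecordSet("THER", [
            {"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": "20230401"},
            {"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": "20230101"},
            {"PRIMARYID": "1", "DSG_DRUG_SEQ": "2", "START_DT": "20220101"},
        ], "2023Q1", "modern")
        reports, _ = assemble_reports([demo, drug, ther])
        assert reports[0].therapy_start.format() == "20230101"


class TestRouteClassification:
    @pytest.mark.parametrize("route,expected", [
        ("INTRAVENOUS", "intravenous"),
        ("Intravenous drip", "intravenous"),
        ("INTRAVENOUS (NOT OTHERWISE SPECIFIED)", "intravenous"),
        ("INTRAVITREAL", "intraocular"),
        ("OPHTHALMIC", "intraocular"),
        ("ORAL", "other"),
        ("", "unspecified"),
        ("   ", "unspecified"),
    ])
    def test_classes(self, route, expected):
        assert classify_route(route) == expected


class TestDeduplicate:
    def test_latest_fda_date_survives(self):
        v1 = make_report("10", caseid="555", fda="20190101")
        v2 = make_report("11", caseid="555", fda="20200101")
        survivors, _ = deduplicate([v1, v2])
        assert [r.primaryid for r in survivors] == ["11"]

    def test_fda_tie_broken_by_largest_primaryid(self):
        v1 = make_report("21", caseid="555", fda="20200101")
        v2 = make_report("102", caseid="555", fda="20200101")
        survivors, _ = deduplicate([v1, v2])
        assert survivors[0].primaryid == "102"

    def test_single_report_unchanged(self):
        r = make_report("1")
        survivors, flags = deduplicate([r])
        assert survivors == [r] and not flags

    def test_brute_force_oracle_five_cases_three_versions(self):
        reports, expected = [], {}
        for case in range(5):
            caseid = f"c{case}"
            versions = []
            for v in range(3):
                r = make_report(
                    primaryid=str(100 * case + v),
                    caseid=caseid,
                    fda=f"201{v % 2}0101",  # duplicate dates force pid tie-breaks
                )
                versions.append(r)
                reports.append(r)
            expected[caseid] = max(
                versions, key=lambda r: (r.fda_date.sort_key(), int(r.primaryid))
            ).primaryid
        survivors, _ = deduplicate(reports)
        assert len(survivors) == 5
        assert {r.caseid: r.primaryid for r in survivors} == expected

    def test_idempotent_and_count_matches_distinct_caseids(self):
        reports = [make_report(str(i), caseid=str(i % 7), fda=f"202{i % 3}0101")
                   for i in range(20)]
        once, _ = deduplicate(reports)
        twice, _ = deduplicate(once)
        assert once == twice
        assert len(once) == len({r.caseid for r in reports})

    def test_empty_caseid_kept_and_flagged(self):
        r1 = make_report("1", caseid="")
        r2 = make_report("2", caseid="")
        survivors, flags = deduplicate([r1, r2])
        assert len(survivors) == 2
        assert len(flags) == 2 and "singleton" in flags[0].reason

    def test_input_not_modified_and_output_sorted(self):
        reports = [make_report(str(i), caseid=c) for i, c in enumerate("bca")]
        snapshot = list(reports)
        survivors, _ = deduplicate(reports)
        assert reports == snapshot
        assert [r.caseid for r in survivors] == sorted(r.caseid for r in survivors)


def test_read_archive_round_trip(tmp_path):
    qdir = tmp_path / "2023Q1"
    qdir.mkdir()
    (qdir / "DEMO23Q1.txt").write_text("PRIMARYID$CASEID$FDA_DT\n1$1$20230301\n")
    (qdir / "REAC23Q1.txt").write_text("PRIMARYID$CASEID$PT\n1$1$NAUSEA\n")
    sets, rejects = faers_io.read_archive(tmp_path)
    assert {rs.table_name for rs in sets} == {"DEMO", "REAC"}
    assert sets[0].quarter_label == "2023Q1"
    assert not rejects
    reports, _ = assemble_reports(sets)
    assert reports[0].reaction_pts == frozenset({"NAUSEA"})
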