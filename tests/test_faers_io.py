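from __future__ import annotations

import pytest

from pvsignal.faers_io import (
    FaersFormatError,
    FixtureValidationError,
    TableKind,
    assemble_reports,
    read_faers_table,
    read_signal_fixture,
    write_faers_table,
)

DEMO_HEADER = "primaryid$caseid$fda_dt$sex$age$age_cod$occr_country"


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


class TestReadTable:
    def test_direct_parse_of_constructed_line(self, tmp_path):
        path = write_lines(
            tmp_path / "DEMO.txt",
            ["primaryid$caseid$fda_dt$sex$age$occr_country", "100001$9001$20230101$F$34$US"],
        )
        rows = read_faers_table(path, TableKind.DEMO)
        assert len(rows) == 1
        assert rows[0].get("sex") == "F"
        assert rows[0].get("age") == "34"
        assert rows[0].get("occr_country") == "US"

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = write_lines(tmp_path / "DEMO.txt", [DEMO_HEADER])
        assert read_faers_table(path, TableKind.DEMO) == []

    def test_missing_fields_preserved_as_empty_strings(self, tmp_path):
        path = write_lines(tmp_path / "DEMO.txt", [DEMO_HEADER, "1$2$20230101$$$$"])
        (row,) = read_faers_table(path, TableKind.DEMO)
        assert row.get("sex") == ""
        assert row.get("occr_country") == ""

    def test_wrong_field_count_names_line_number(self, tmp_path):
        path = write_lines(tmp_path / "DEMO.txt", [DEMO_HEADER, "1$2$3$F$34$YR$US", "1$2"])
        with pytest.raises(FaersFormatError, match=r":3:"):
            read_faers_table(path, TableKind.DEMO)

    def test_header_missing_primaryid_is_named(self, tmp_path):
        path = write_lines(tmp_path / "DEMO.txt", ["caseid$fda_dt", "2$3"])
        with pytest.raises(FaersFormatError, match="primaryid"):
            read_faers_table(path, TableKind.DEMO)

    def test_duplicate_header_column_rejected(self, tmp_path):
        path = write_lines(tmp_path / "DEMO.txt", ["primaryid$caseid$caseid", "1$2$3"])
        with pytest.raises(FaersFormatError, match="caseid"):
            read_faers_table(path, TableKind.DEMO)

    def test_column_names_matched_case_insensitively(self, tmp_path):
        path = write_lines(tmp_path / "DEMO.txt", ["PRIMARYID$CASEID$FDA_DT", "1$2$20230101"])
        (row,) = read_faers_table(path, TableKind.DEMO)
        assert row.get("primaryid") == "1"


class TestRoundTrip:
    def test_three_record_demo_round_trip(self, tmp_path):
        rows_in = [
            {"primaryid": str(100 + i), "caseid": str(i), "fda_dt": "20230101",
             "sex": "F" if i % 2 else "", "age": "", "age_cod": "", "occr_country": "US"}
            for i in range(3)
        ]
        path = write_faers_table(tmp_path / "DEMO.txt", TableKind.DEMO, rows_in)
        rows_out = read_faers_table(path, TableKind.DEMO)
        assert len(rows_out) == 3
        assert [dict(r.fields) for r in rows_out] == rows_in

    def test_write_read_write_is_byte_identical(self, tmp_path):
        rows = [{"primaryid": "1", "caseid": "2", "fda_dt": "20230101", "sex": "M",
                 "age": "40", "age_cod": "YR", "occr_country": ""}]
        p1 = write_faers_table(tmp_path / "a.txt", TableKind.DEMO, rows)
        p2 = write_faers_table(tmp_path / "b.txt", TableKind.DEMO, read_faers_table(p1, "DEMO"))
        assert p1.read_bytes() == p2.read_bytes()

    def test_delimiter_in_value_rejected(self, tmp_path):
        with pytest.raises(FaersFormatError, match="drugname"):
            write_faers_table(
                tmp_path / "DRUG.txt",
                TableKind.DRUG,
                [{"primaryid": "1", "caseid": "1", "drug_seq": "1", "role_cod": "PS",
                  "drugname": "BAD$NAME", "dose_amt": "", "dose_unit": ""}],
            )


def demo_row(pid="100001", caseid="9001", fda="20230101", sex="F", age="34",
             age_cod="YR", country="US"):
    return {"primaryid": pid, "caseid": caseid, "fda_dt": fda, "sex": sex,
            "age": age, "age_cod": age_cod, "occr_country": country}


def build_tables(tmp_path, demo_rows, **children):
    tables = {TableKind.DEMO: read_faers_table(
        write_faers_table(tmp_path / "DEMO.txt", TableKind.DEMO, demo_rows), TableKind.DEMO)}
    for name, rows in children.items():
        kind = TableKind(name.upper())
        tables[kind] = read_faers_table(
            write_faers_table(tmp_path / f"{kind.value}.txt", kind, rows), kind)
    return tables


class TestAssemble:
    def test_join_by_key_two_reac_rows(self, tmp_path):
        tables = build_tables(
            tmp_path,
            [demo_row()],
            reac=[{"primaryid": "100001", "caseid": "9001", "pt": "Dizziness"},
                  {"primaryid": "100001", "caseid": "9001", "pt": "Somnolence"}],
        )
        result = assemble_reports(tables)
        assert len(result.reports) == 1
        assert result.reports[0].events == {"Dizziness", "Somnolence"}

    def test_outcome_code_ho_maps_to_hospitalization(self, tmp_path):
        tables = build_tables(
            tmp_path, [demo_row()],
            outc=[{"primaryid": "100001", "caseid": "9001", "outc_cod": "HO"}],
        )
        assert "hospitalization" in assemble_reports(tables).reports[0].outcomes

    def test_unknown_outcome_code_maps_to_unknown(self, tmp_path):
        tables = build_tables(
            tmp_path, [demo_row()],
            outc=[{"primaryid": "100001", "caseid": "9001", "outc_cod": "CA"}],
        )
        assert assemble_reports(tables).reports[0].outcomes == {"unknown"}

    def test_orphan_reac_row_counted_not_fatal(self, tmp_path):
        tables = build_tables(
            tmp_path, [demo_row()],
            reac=[{"primaryid": "555", "caseid": "555", "pt": "Nausea"}],
        )
        result = assemble_reports(tables)
        assert len(result.reports) == 1
        assert result.orphan_rows == 1

    def test_non_numeric_primaryid_goes_to_rejects(self, tmp_path):
        tables = build_tables(tmp_path, [demo_row(pid="ABC")])
        result = assemble_reports(tables)
        assert result.reports == []
        assert len(result.rejects) == 1

    def test_assembly_conserves_counts(self, tmp_path):
        demo_rows = [demo_row(pid=str(100 + i), caseid=str(i)) for i in range(5)]
        reac_rows = [
            {"primaryid": str(100 + i), "caseid": str(i), "pt": f"Event{j}"}
            for i in range(5)
            for j in range(i + 1)
        ]
        result = assemble_reports(build_tables(tmp_path, demo_rows, reac=reac_rows))
        assert len(result.reports) == len(demo_rows)
        assert sum(len(r.events) for r in result.reports) == len(reac_rows)

    def test_age_in_non_year_units_becomes_missing(self, tmp_path):
        tables = build_tables(tmp_path, [demo_row(age="5", age_cod="MON")])
        assert assemble_reports(tables).reports[0].age_years is None

    def test_blank_age_code_interpreted_as_years(self, tmp_path):
        tables = build_tables(tmp_path, [demo_row(age="34", age_cod="")])
        assert assemble_reports(tables).reports[0].age_years == 34.0

    def test_missing_sex_and_country_map_to_unknown(self, tmp_path):
        tables = build_tables(tmp_path, [demo_row(sex="", country="")])
        report = assemble_reports(tables).reports[0]
        assert report.sex == "unknown"
        assert report.country is None

    def test_dose_parsed_only_for_mg_units(self, tmp_path):
        tables = build_tables(
            tmp_path, [demo_row()],
            drug=[{"primaryid": "100001", "caseid": "9001", "drug_seq": "1", "role_cod": "PS",
                   "drugname": "VIMPAT", "dose_amt": "150", "dose_unit": "MG"},
                  {"primaryid": "100001", "caseid": "9001", "drug_seq": "2", "role_cod": "SS",
                   "drugname": "OTHER", "dose_amt": "2", "dose_unit": "ML"}],
        )
        report = assemble_reports(tables).reports[0]
        assert report.drugs[0].daily_dose_mg == 150.0
        assert report.drugs[1].daily_dose_mg is None


class TestSignalFixture:
    def test_row_cardinality_matches_published_table(self):
        rows = read_signal_fixture()
        assert len(rows) == 153
        assert sum(r.drug == "lacosamide" for r in rows) == 98
        assert sum(r.drug == "cenobamate" for r in rows) == 55

    def test_per_soc_lacosamide_counts(self):
        rows = read_signal_fixture()

        def count(soc):
            return sum(1 for r in rows if r.drug == "lacosamide" and r.soc == soc)

        assert count("Cardiac disorders") == 18
        assert count("Congenital, familial and genetic disorders") == 13
        assert count("Investigations") == 5

    def test_multiple_drug_resistance_row_values(self):
        (row,) = [r for r in read_signal_fixture()
                  if r.pt == "Multiple-drug resistance" and r.drug == "lacosamide"]
        assert row.n == 177
        assert row.prr == 95.75
        assert row.chi2 == 15413.47
        assert row.ror == 96.17
        assert row.ror_ci025 == 82.51
        assert row.ic_minus_2sd == 6.25

    def test_diplopia_cenobamate_row(self):
        (row,) = [r for r in read_signal_fixture()
                  if r.pt == "Diplopia" and r.drug == "cenobamate"]
        assert row.n == 83
        assert row.ic_minus_2sd == 3.8

    def test_slash_cells_emit_no_row(self, tmp_path):
        path = tmp_path / "fixture.csv"
        path.write_text(
            "soc,pt,drug,n,prr,chi2,ror,ror_ci025,ic,ic_minus_2sd\n"
            "Cardiac disorders,Atrial flutter,lacosamide,37,7.07,191.94,7.08,5.12,2.82,2.35\n"
            "Cardiac disorders,Atrial flutter,cenobamate,/,/,/,/,/,/,/\n",
            encoding="utf-8",
        )
        rows = read_signal_fixture(path)
        assert len(rows) == 1
        assert rows[0].drug == "lacosamide"

    def test_atrial_flutter_has_no_cenobamate_row(self):
        assert not [r for r in read_signal_fixture()
                    if r.pt == "Atrial flutter" and r.drug == "cenobamate"]

    def test_n_below_six_raises_validation_error(self, tmp_path):
        path = tmp_path / "fixture.csv"
        path.write_text(
            "soc,pt,drug,n,prr,chi2,ror,ror_ci025,ic,ic_minus_2sd\n"
            "Cardiac disorders,Atrial flutter,lacosamide,5,7.07,191.94,7.08,5.12,2.82,2.35\n",
            encoding="utf-8",
        )
        with pytest.raises(FixtureValidationError, match="n=5"):
            read_signal_fixture(path)

    def test_fixture_invariants_hold(self):
        for row in read_signal_fixture():
            assert row.n >= 6
            assert row.ror_ci025 < row.ror
            assert row.ic_minus_2sd < row.ic
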