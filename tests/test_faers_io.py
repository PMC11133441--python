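"""Parsing and writing of the dollar-delimited FAERS ASCII dialect."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faers_dispro.faers_io import (
    DemoRecord,
    DrugRecord,
    ReactionRecord,
    SchemaError,
    TableKind,
    load_pt_soc_map,
    parse_table,
    write_table,
)

from conftest import write_lines


class TestParseDemo:
    def test_row_count_equals_data_lines(self, demo_file):
        result = parse_table(demo_file, TableKind.DEMO)
        assert len(result.records) == 2
        assert result.issues == []

    def test_fields_parsed_and_normalised(self, demo_file):
        rec = parse_table(demo_file, TableKind.DEMO).records[0]
        assert rec.primary_id == "1001"
        assert rec.case_id == "500"
        assert rec.fda_dt == 20210101
        assert rec.event_year == 2021
        assert rec.sex == "M"
        assert rec.age_years == 65.0
        assert rec.weight_kg == 80.0
        assert rec.reporter_occupation == "MD"
        assert rec.reporter_country == "US"

    def test_empty_fields_become_missing(self, demo_file):
        rec = parse_table(demo_file, TableKind.DEMO).records[1]
        assert rec.sex is None
        assert rec.age_years is None
        assert rec.weight_kg is None

    @pytest.mark.parametrize(
        "age, age_cod, expected",
        [
            ("24", "MON", 2.0),
            ("730.5", "DY", 2.0),
            ("65", "YR", 65.0),
            ("65", "", 65.0),  # blank unit treated as years
            ("7", "DEC", None),  # unsupported unit -> missing
        ],
    )
    def test_age_unit_conversion(self, tmp_path, age, age_cod, expected):
        path = write_lines(
            tmp_path / "d.txt",
            [
                "primaryid$caseid$fda_dt$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country",
                f"1$1$20200101$F${age}${age_cod}$$$$",
            ],
        )
        rec = parse_table(path, "DEMO").records[0]
        assert rec.age_years == pytest.approx(expected) if expected is not None else rec.age_years is None

    @pytest.mark.parametrize(
        "wt, wt_cod, expected",
        [("100", "KG", 100.0), ("150", "LBS", 150 * 0.453592), ("100", "GMS", None)],
    )
    def test_weight_normalised_to_kg(self, tmp_path, wt, wt_cod, expected):
        path = write_lines(
            tmp_path / "d.txt",
            [
                "primaryid$caseid$fda_dt$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country",
                f"1$1$20200101$M$$${wt}${wt_cod}$$",
            ],
        )
        rec = parse_table(path, "DEMO").records[0]
        if expected is None:
            assert rec.weight_kg is None
        else:
            assert rec.weight_kg == pytest.approx(expected)

    def test_null_literal_and_whitespace_are_missing(self, tmp_path):
        path = write_lines(
            tmp_path / "d.txt",
            [
                "primaryid$caseid$fda_dt$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country",
                "1$1$20200101$NULL$  $$NULL$$  $NULL",
            ],
        )
        rec = parse_table(path, "DEMO").records[0]
        assert rec.sex is None and rec.weight_kg is None
        assert rec.reporter_occupation is None and rec.reporter_country is None

    def test_column_order_follows_header_not_position(self, tmp_path):
        path = write_lines(
            tmp_path / "d.txt",
            [
                "caseid$primaryid$reporter_country$fda_dt$sex$age$age_cod$wt$wt_cod$occp_cod",
                "500$1001$US$20210101$F$$$$$",
            ],
        )
        rec = parse_table(path, "DEMO").records[0]
        assert rec.primary_id == "1001" and rec.case_id == "500"
        assert rec.reporter_country == "US" and rec.sex == "F"

    def test_extra_columns_ignored(self, tmp_path):
        path = write_lines(
            tmp_path / "d.txt",
            [
                "primaryid$caseid$i_f_code$event_dt$fda_dt$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country",
                "1$1$I$20191201$20200101$M$$$$$$",
            ],
        )
        assert parse_table(path, "DEMO").records[0].sex == "M"


class TestParseErrors:
    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_table(tmp_path / "absent.txt", "DEMO")

    def test_missing_required_column_names_it(self, tmp_path):
        path = write_lines(tmp_path / "d.txt", ["primaryid$caseid$sex", "1$1$M"])
        with pytest.raises(SchemaError, match="fda_dt"):
            parse_table(path, "DEMO")

    def test_wrong_field_count_reported_with_line_number(self, tmp_path):
        path = write_lines(
            tmp_path / "r.txt",
            ["primaryid$pt", "1$Nausea", "2$Nausea$extra", "3$Fatigue"],
        )
        result = parse_table(path, "REAC")
        assert len(result.records) == 2
        assert len(result.issues) == 1
        assert result.issues[0].line_no == 3
        assert "found 3" in result.issues[0].reason

    def test_malformed_date_skips_record_only(self, tmp_path):
        path = write_lines(
            tmp_path / "d.txt",
            [
                "primaryid$caseid$fda_dt$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country",
                "1$1$20200101$M$$$$$$",
                "2$2$20211301$M$$$$$$",  # month 13
                "3$3$2020$M$$$$$$",  # too short
            ],
        )
        result = parse_table(path, "DEMO")
        assert [r.primary_id for r in result.records] == ["1"]
        assert len(result.issues) == 2

    def test_unknown_role_code_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "drug.txt",
            [
                "primaryid$drug_seq$role_cod$drugname$prod_ai",
                "1$1$PS$XPOVIO$SELINEXOR",
                "1$2$XX$OTHER$",
            ],
        )
        result = parse_table(path, "DRUG")
        assert len(result.records) == 1
        assert result.records[0].role_code == "PS"
        assert "XX" in result.issues[0].reason

    def test_unknown_outcome_code_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "o.txt", ["primaryid$outc_cod", "1$HO", "2$ZZ"]
        )
        result = parse_table(path, "OUTC")
        assert [r.outcome_code for r in result.records] == ["HO"]
        assert len(result.issues) == 1

    def test_parsing_is_total_over_data_lines(self, tmp_path):
        lines = ["primaryid$pt"] + [f"{i}$PT" if i % 3 else f"{i}$PT$x" for i in range(1, 31)]
        path = write_lines(tmp_path / "r.txt", lines)
        result = parse_table(path, "REAC")
        assert len(result.records) + len(result.issues) == 30


class TestRoundTrip:
    def test_all_seven_tables_round_trip(self, tmp_path, small_tables):
        small_tables.write(tmp_path)
        for kind, records in [
            (TableKind.DEMO, small_tables.demo),
            (TableKind.DRUG, small_tables.drug),
            (TableKind.REAC, small_tables.reac),
            (TableKind.OUTC, small_tables.outc),
            (TableKind.INDI, small_tables.indi),
            (TableKind.THER, small_tables.ther),
            (TableKind.RPSR, small_tables.rpsr),
        ]:
            reparsed = parse_table(tmp_path / f"{kind.value}.txt", kind)
            assert reparsed.issues == []
            assert reparsed.records == records

    def test_empty_record_list_gives_header_only_file(self, tmp_path):
        path = tmp_path / "REAC.txt"
        write_table([], path, "REAC")
        assert path.read_text().strip() == "primaryid$pt"
        assert parse_table(path, "REAC").records == []

    def test_delimiter_in_field_rejected(self, tmp_path):
        rec = DrugRecord(primary_id="1", drug_seq=1, role_code="PS", drug_name="BAD$NAME")
        with pytest.raises(ValueError, match="delimiter"):
            write_table([rec], tmp_path / "DRUG.txt", "DRUG")

    def test_wrong_record_type_rejected(self, tmp_path):
        with pytest.raises(TypeError):
            write_table([ReactionRecord("1", "Nausea")], tmp_path / "DRUG.txt", "DRUG")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.builds(
                DemoRecord,
                primary_id=st.integers(1, 10**9).map(str),
                case_id=st.integers(1, 10**6).map(str),
                fda_dt=st.dates(min_value=__import__("datetime").date(2000, 1, 1)).map(
                    lambda d: d.year * 10000 + d.month * 100 + d.day
                ),
                sex=st.sampled_from([None, "M", "F"]),
                age_years=st.one_of(
                    st.none(), st.floats(0, 120, allow_nan=False).map(lambda x: round(x, 3))
                ),
                weight_kg=st.one_of(
                    st.none(), st.floats(0.1, 300, allow_nan=False).map(lambda x: round(x, 3))
                ),
                reporter_occupation=st.sampled_from([None, "MD", "PH", "HP", "CN", "OT", "LW"]),
                reporter_country=st.sampled_from([None, "US", "CN", "FR"]),
            ),
            max_size=20,
            unique_by=lambda r: r.primary_id,
        )
    )
    def test_demo_round_trip_property(self, tmp_path_factory, records):
        """parse(write(records)) reproduces every field exactly."""
        path = tmp_path_factory.mktemp("rt") / "DEMO.txt"
        write_table(records, path, "DEMO")
        result = parse_table(path, "DEMO")
        assert result.issues == []
        assert result.records == records


class TestPtSocMap:
    def test_lookup_round_trips(self, tmp_path):
        path = write_lines(tmp_path / "map.tsv", ["Nausea\tGastrointestinal disorders"])
        m = load_pt_soc_map(path)
        assert m.lookup("Nausea") == "Gastrointestinal disorders"

    def test_normalisation_merges_case_and_whitespace(self, tmp_path):
        path = write_lines(tmp_path / "map.tsv", ["NAUSEA \tGastrointestinal disorders"])
        m = load_pt_soc_map(path)
        assert m.lookup("nausea") == "Gastrointestinal disorders"
        assert "  Nausea " in m
        assert len(m) == 1

    def test_conflicting_duplicate_is_fatal_and_names_pt(self, tmp_path):
        path = write_lines(
            tmp_path / "map.tsv",
            ["Nausea\tGastrointestinal disorders", "nausea\tInvestigations"],
        )
        with pytest.raises(ValueError, match="[Nn]ausea"):
            load_pt_soc_map(path)

    def test_agreeing_duplicate_allowed(self, tmp_path):
        path = write_lines(tmp_path / "map.tsv", ["Nausea\tGI", "NAUSEA\tGI"])
        assert len(load_pt_soc_map(path)) == 1

    def test_header_line_skipped(self, tmp_path):
        path = write_lines(tmp_path / "map.tsv", ["pt\tsoc", "Nausea\tGI"])
        assert load_pt_soc_map(path).lookup("Nausea") == "GI"

    def test_unknown_pt_lookup_is_none(self, tmp_path):
        path = write_lines(tmp_path / "map.tsv", ["Nausea\tGI"])
        assert load_pt_soc_map(path).lookup("Vertigo") is None
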