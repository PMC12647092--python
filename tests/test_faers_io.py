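"""Quarterly-file parsing, deduplication, harmonization and cohorts."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from faersig import faers_io
from faersig.faers_io import (
    CaseReport,
    DrugEntry,
    MedDRAMap,
    RawCaseRecord,
    assemble_reports,
    assign_age_group,
    build_cohort,
    deduplicate,
    harmonize_age,
    normalize_drug_name,
    parse_dataset,
    parse_quarter,
    parse_table,
    write_records,
)


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _demo_record(pid, caseid, fda="20230101"):
    date, _ = faers_io.parse_faers_date(fda)
    return RawCaseRecord(pid, caseid, date, "DEMO",
                         {"primaryid": pid, "caseid": caseid, "fda_dt": fda})


class TestParsing:
    def test_row_preserving_parse(self, tmp_path):
        p = tmp_path / "DEMO23Q1.txt"
        _write(p, [
            "primaryid$caseid$fda_dt$sex",
            "101$1$20230101$M",
            "102$2$20230215$F",
            "103$3$20230301$",
        ])
        records, skipped = parse_table(p, "DEMO")
        assert len(records) == 3 and skipped == 0
        assert all(r.source_table == "DEMO" for r in records)
        assert records[0].fda_receipt_date == dt.date(2023, 1, 1)

    def test_wrong_field_count_skipped_and_counted(self, tmp_path):
        p = tmp_path / "DRUG23Q1.txt"
        _write(p, [
            "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai",
            "101$1$1$PS$RILUZOLE$RILUZOLE",
            "102$2$1$PS$BAD$DRUG$EXTRA$FIELD",  # embedded extra delimiters
        ])
        records, skipped = parse_table(p, "DRUG")
        assert len(records) == 1 and skipped == 1

    def test_unknown_column_carried_opaquely(self, tmp_path, caplog):
        p = tmp_path / "DEMO23Q1.txt"
        _write(p, ["primaryid$caseid$fda_dt$mystery", "101$1$20230101$42"])
        records, _ = parse_table(p, "DEMO")
        assert records[0].payload["mystery"] == "42"

    def test_missing_mandatory_table_fatal(self, tmp_path):
        demo = tmp_path / "DEMO23Q1.txt"
        _write(demo, ["primaryid$caseid$fda_dt", "101$1$20230101"])
        with pytest.raises(faers_io.FaersDataError, match="REAC"):
            parse_quarter([demo, _drug_file(tmp_path)])

    def test_synthetic_quarter_row_count(self, small_dataset):
        config, truth, run, directory = small_dataset
        parsed = parse_dataset(directory)
        # DEMO rows before dedup = unique cases + planted duplicates
        assert parsed.row_counts["DEMO"] == (
            truth.unique_case_count + truth.duplicate_count)
        assert sum(parsed.skipped_counts.values()) == 0

    def test_round_trip_is_fixed_point(self, tmp_path):
        src = tmp_path / "src"
        src.mkdir()
        _write(src / "DEMO23Q1.txt", [
            "primaryid$caseid$fda_dt$sex$extra",
            "101$1$20230101$M$x",
            "102$2$20230215$F$",
        ])
        _write(src / "DRUG23Q1.txt", [
            "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai",
            "101$1$1$PS$RILUZOLE$RILUZOLE",
        ])
        _write(src / "REAC23Q1.txt", ["primaryid$caseid$pt", "101$1$NAUSEA"])
        first = parse_dataset(src)
        out = tmp_path / "rt"
        write_records(first, out, 2023, 1)
        second = parse_dataset(out)
        for table in ("DEMO", "DRUG", "REAC"):
            assert [r.payload for r in second.records[table]] == \
                   [r.payload for r in first.records[table]]


def _drug_file(tmp_path):
    p = tmp_path / "DRUG23Q1.txt"
    _write(p, ["primaryid$caseid$drug_seq$role_cod$drugname$prod_ai",
               "101$1$1$PS$RILUZOLE$RILUZOLE"])
    return p


class TestDeduplicate:
    def test_latest_receipt_date_wins(self):
        recs = [_demo_record("101", "1", "20230101"),
                _demo_record("102", "1", "20230301")]
        assert deduplicate(recs).retained == {"102"}

    def test_tie_broken_by_largest_primary_id(self):
        recs = [_demo_record("205", "1", "20230101"),
                _demo_record("31", "1", "20230101")]
        assert deduplicate(recs).retained == {"205"}

    def test_single_record_is_identity(self):
        recs = [_demo_record("101", "1")]
        assert deduplicate(recs).retained == {"101"}

    def test_missing_case_id_kept_as_singleton(self):
        recs = [_demo_record("101", ""), _demo_record("102", "")]
        result = deduplicate(recs)
        assert result.retained == {"101", "102"} and result.no_case_id == 2

    def test_planted_duplicates_removed(self, small_dataset):
        config, truth, run, directory = small_dataset
        assert truth.duplicate_count == int(0.2 * config.n_reports)
        assert run.dedup_retained == truth.unique_case_count

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 8),
                              st.integers(0, 400))))
    @settings(deadline=None, derandomize=True)
    def test_idempotent_and_bounded(self, raw):
        recs = [
            _demo_record(str(1000 + i), str(case),
                         (dt.date(2020, 1, 1) + dt.timedelta(days=off)
                          ).strftime("%Y%m%d"))
            for i, (_, case, off) in enumerate(raw)
        ]
        first = deduplicate(recs)
        assert len(first.retained) <= len({r.case_id for r in recs})
        kept = [r for r in recs if r.primary_id in first.retained]
        assert deduplicate(kept).retained == first.retained


class TestHarmonization:
    @pytest.mark.parametrize("value,unit,expected", [
        (24, "MON", 2.0),
        (6, "DEC", 60.0),
        (52, "WK", 1.0),
        (365, "DY", 1.0),
        (8760, "HR", 1.0),
        (40, "YR", 40.0),
        (-5, "YR", None),
        (40, "", None),
        ("", "YR", None),
        ("abc", "YR", None),
    ])
    def test_age_unit_conversion(self, value, unit, expected):
        assert harmonize_age(value, unit) == expected

    @pytest.mark.parametrize("age,group", [
        (17.9, "under18"), (0.0, "under18"), (18.0, "from18to65"),
        (64.99, "from18to65"), (65.0, "over65"), (90, "over65"),
        (None, "unknown"),
    ])
    def test_age_groups_half_open(self, age, group):
        assert assign_age_group(age) == group

    def test_age_group_is_function_of_age(self):
        # the derived field always agrees with the rule
        for age in (None, 3, 17.999, 18, 30, 64.9, 65, 120):
            assert assign_age_group(age) == assign_age_group(age)


class TestMedDRAMap:
    def test_case_insensitive_after_whitespace_normalization(self):
        m = MedDRAMap({"Hepatic  enzyme increased": "Investigations"})
        assert m.soc_of("HEPATIC ENZYME INCREASED") == "Investigations"
        assert m.soc_of(" hepatic enzyme   increased ") == "Investigations"

    def test_unmapped_marker(self):
        assert MedDRAMap().soc_of("ANYTHING") == faers_io.UNMAPPED

    def test_from_file_comma_and_tab(self, tmp_path):
        p = tmp_path / "map.csv"
        p.write_text("pt,soc\nNAUSEA,Gastrointestinal disorders\n")
        assert MedDRAMap.from_file(p).soc_of("nausea") == \
            "Gastrointestinal disorders"
        q = tmp_path / "map.tsv"
        q.write_text("pt\tsoc\nNAUSEA\tGastrointestinal disorders\n")
        assert MedDRAMap.from_file(q).soc_of("NAUSEA") == \
            "Gastrointestinal disorders"


def _report(pid, drugs):
    return CaseReport(
        primary_id=pid, case_id=pid, sex="unknown", age_years=None,
        age_group="unknown", country="unknown", reporter="unknown",
        outcomes=frozenset(), drugs=drugs, reactions=["NAUSEA"],
        reaction_socs={"NAUSEA": "GI"}, event_date=None, receipt_year=2023)


class TestCohort:
    def test_normalized_name_matches(self):
        reports = {"1": _report("1", [DrugEntry("RILUZOLE.", "PS")])}
        assert len(build_cohort(reports, ["riluzole"])) == 1

    def test_non_target_excluded(self):
        reports = {"1": _report("1", [DrugEntry("BACLOFEN", "PS")])}
        assert build_cohort(reports, ["riluzole"]) == []

    def test_concomitant_role_excluded_by_default(self):
        reports = {"1": _report("1", [DrugEntry("RILUZOLE", "C")])}
        assert build_cohort(reports, ["riluzole"]) == []
        assert len(build_cohort(reports, ["riluzole"], role_codes=None)) == 1

    def test_active_ingredient_alias_matches(self):
        entry = DrugEntry("RILUTEK", "PS", alias="RILUZOLE")
        reports = {"1": _report("1", [entry])}
        assert len(build_cohort(reports, ["riluzole"])) == 1

    def test_substring_match_is_opt_in(self):
        reports = {"1": _report("1", [DrugEntry("RILUZOLE 50MG TAB", "PS")])}
        assert build_cohort(reports, ["riluzole"]) == []
        assert len(build_cohort(reports, ["riluzole"], substring=True)) == 1

    def test_every_cohort_member_matches_its_target(self, small_dataset):
        config, truth, run, directory = small_dataset
        for drug, cohort in run.cohorts.items():
            want = {normalize_drug_name(drug)}
            for rep in cohort:
                assert any(
                    faers_io.drug_matches(e, want) for e in rep.drugs)

    def test_cohort_order_independent_of_row_order(self, small_dataset):
        config, truth, run, directory = small_dataset
        parsed = parse_dataset(directory)
        retained = deduplicate(parsed.records["DEMO"]).retained
        forward = assemble_reports(parsed, retained)
        for table in parsed.records.values():
            table.reverse()
        backward = assemble_reports(parsed, retained)
        ids_f = [r.primary_id for r in build_cohort(forward, ["Riluzole"])]
        ids_b = [r.primary_id for r in build_cohort(backward, ["Riluzole"])]
        assert ids_f == ids_b and len(ids_f) > 0


class TestIndicationFilter:
    def test_indication_pt_stripped_when_enabled(self):
        rep = _report("1", [DrugEntry("RILUZOLE", "PS")])
        rep.reactions = ["AMYOTROPHIC LATERAL SCLEROSIS", "NAUSEA"]
        rep.reaction_socs = {"AMYOTROPHIC LATERAL SCLEROSIS": "Nervous",
                             "NAUSEA": "GI"}
        rep.indications = ["Amyotrophic lateral sclerosis"]
        stripped = faers_io.strip_indication_reactions(rep)
        assert stripped.reactions == ["NAUSEA"]
        # original untouched; filter defaults to off in the pipeline
        assert rep.reactions[0] == "AMYOTROPHIC LATERAL SCLEROSIS"

    def test_no_indication_is_identity(self):
        rep = _report("1", [DrugEntry("RILUZOLE", "PS")])
        assert faers_io.strip_indication_reactions(rep) is rep


class TestCohortJsonl:
    def test_round_trip(self, tmp_path):
        rep = _report("7", [DrugEntry("RILUZOLE", "PS",
                                      dt.date(2023, 1, 5), "RILUZOLE AI")])
        path = tmp_path / "cohort.jsonl"
        faers_io.write_cohort([rep], path)
        back = faers_io.read_cohort(path)
        assert back == [rep]
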