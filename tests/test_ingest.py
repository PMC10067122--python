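"""Parsing, deduplication, report assembly, case selection and TTO."""

import pytest

from icivigil import (
    DrugExposure,
    SafetyReport,
    build_reports,
    classify_regimen,
    compute_tto,
    deduplicate,
    parse_quarter,
    select_cases,
)
from icivigil.ingest import convert_age, frame_to_reports, reports_to_frame


def _report(**kw):
    base = dict(
        case_id="1",
        primary_id="11",
        sex="male",
        age_years=60.0,
        country="US",
        continent="America",
        report_date="20200601",
        event_date="20200301",
        indication="Lung cancer",
        drugs=[DrugExposure("OPDIVO", "nivolumab", "PS", "20200201")],
        reactions=["Atrial fibrillation"],
        outcome_codes=("HO",),
    )
    base.update(kw)
    return SafetyReport(**base)


class TestParseQuarter:
    def test_row_counts_preserved(self, tiny_quarter):
        rs = parse_quarter(tiny_quarter, "2020Q1")
        assert len(rs.demo) == 4
        assert len(rs.reac) == 5

    def test_orphan_rows_dropped_and_counted(self, tiny_quarter):
        rs = parse_quarter(tiny_quarter, "2020Q1")
        # the GHOST drug row references primaryid 9999, absent from DEMO
        assert rs.counters["orphan_rows"] == 1
        assert "9999" not in set(rs.drug["primaryid"])

    def test_header_case_insensitive(self, tmp_path, tiny_quarter):
        upper = tmp_path / "DEMO_upper.txt"
        text = tiny_quarter["demo"].read_text()
        header, rest = text.split("\n", 1)
        upper.write_text(header.upper() + "\n" + rest)
        rs1 = parse_quarter(tiny_quarter, "2020Q1")
        rs2 = parse_quarter({**tiny_quarter, "demo": upper}, "2020Q1")
        assert list(rs1.demo.columns) == list(rs2.demo.columns)
        assert rs1.demo.equals(rs2.demo)

    def test_legacy_isr_header_normalized(self, tmp_path):
        demo = tmp_path / "demo.txt"
        demo.write_text("ISR$CASE$FDA_DT\n1$10$20110301\n")
        reac = tmp_path / "reac.txt"
        reac.write_text("ISR$PT\n1$Tachycardia\n")
        drug = tmp_path / "drug.txt"
        drug.write_text("ISR$DRUG_SEQ$ROLE_COD$DRUGNAME\n1$1$PS$OPDIVO\n")
        rs = parse_quarter({"demo": demo, "reac": reac, "drug": drug}, "2011Q1")
        assert list(rs.demo["primaryid"]) == ["1"]
        assert list(rs.demo["caseid"]) == ["10"]

    def test_missing_mandatory_column_is_hard_error(self, tmp_path, tiny_quarter):
        bad = tmp_path / "drug_bad.txt"
        bad.write_text("primaryid$caseid$drugname\n1001$100$OPDIVO\n")
        with pytest.raises(ValueError, match="role_cod"):
            parse_quarter({**tiny_quarter, "drug": bad}, "2020Q1")

    def test_bad_quarter_label(self, tiny_quarter):
        with pytest.raises(ValueError, match="quarter"):
            parse_quarter(tiny_quarter, "2020Q5")


class TestDeduplicate:
    def test_latest_fda_date_version_kept(self, tiny_quarter):
        rs = deduplicate(parse_quarter(tiny_quarter, "2020Q1"))
        kept = set(rs.demo["primaryid"])
        assert "1002" in kept and "1001" not in kept
        # satellite tables filtered to the retained version
        assert set(rs.reac["primaryid"]) <= kept

    def test_no_revisions_is_identity(self, tiny_quarter):
        rs = parse_quarter(tiny_quarter, "2020Q1")
        once = deduplicate(rs)
        twice = deduplicate(once)
        assert once.demo["primaryid"].tolist() == twice.demo["primaryid"].tolist()

    def test_tie_broken_by_higher_primaryid(self, tmp_path):
        demo = tmp_path / "demo.txt"
        demo.write_text(
            "primaryid$caseid$fda_dt\n51$5$20200101\n52$5$20200101\n"
        )
        reac = tmp_path / "reac.txt"
        reac.write_text("primaryid$caseid$pt\n51$5$Nausea\n52$5$Nausea\n")
        drug = tmp_path / "drug.txt"
        drug.write_text("primaryid$caseid$drug_seq$role_cod$drugname\n52$5$1$PS$X\n")
        rs = deduplicate(parse_quarter({"demo": demo, "reac": reac, "drug": drug}, "2020Q1"))
        assert rs.demo["primaryid"].tolist() == ["52"]

    def test_never_increases_case_count(self, tiny_quarter):
        rs = parse_quarter(tiny_quarter, "2020Q1")
        out = deduplicate(rs)
        assert out.n_cases() <= rs.n_cases()
        assert out.counters["versions_dropped"] == 1


class TestBuildReports:
    def test_decade_age_unit(self, tiny_quarter, dictionary):
        rs = deduplicate(parse_quarter(tiny_quarter, "2020Q1"))
        reports = {r.case_id: r for r in build_reports(rs, dictionary)}
        assert reports["100"].age_years == 70.0

    @pytest.mark.parametrize(
        "value,unit,expected",
        [("7", "DEC", 70.0), ("6", "MON", 0.5), ("730.5", "DY", 2.0), ("5", "XX", None)],
    )
    def test_age_unit_conversion(self, value, unit, expected):
        counters = {}
        assert convert_age(value, unit, counters) == expected
        if expected is None:
            assert counters["age_unit_unknown"] == 1

    def test_death_flag_from_outcomes(self, tiny_quarter, dictionary):
        rs = deduplicate(parse_quarter(tiny_quarter, "2020Q1"))
        reports = {r.case_id: r for r in build_reports(rs, dictionary)}
        assert reports["100"].died  # outcome codes {DE, HO}
        assert not reports["200"].died

    def test_brand_name_canonicalized(self, tiny_quarter, dictionary):
        rs = deduplicate(parse_quarter(tiny_quarter, "2020Q1"))
        reports = {r.case_id: r for r in build_reports(rs, dictionary)}
        assert reports["100"].drugs[0].substance == "nivolumab"
        # containment match despite the dose suffix
        assert reports["200"].drugs[0].substance == "pembrolizumab"
        assert reports["200"].drugs[1].substance == "other"

    def test_continent_mapping(self, tiny_quarter, dictionary):
        rs = deduplicate(parse_quarter(tiny_quarter, "2020Q1"))
        reports = {r.case_id: r for r in build_reports(rs, dictionary)}
        assert reports["200"].continent == "Asia"
        assert reports["300"].continent == "Europe"


class TestSelectCases:
    def test_ps_plus_catalog_pt_retained(self, dictionary, catalog):
        r = _report()
        assert select_cases([r], dictionary, catalog) == [r]

    def test_ss_only_excluded(self, dictionary, catalog):
        r = _report(drugs=[DrugExposure("YERVOY", "ipilimumab", "SS")])
        assert select_cases([r], dictionary, catalog) == []

    def test_no_qualifying_pt_excluded(self, dictionary, catalog):
        r = _report(reactions=["Nausea"])
        assert select_cases([r], dictionary, catalog) == []

    def test_pt_match_case_insensitive(self, dictionary, catalog):
        r = _report(reactions=["ATRIAL FIBRILLATION"])
        assert len(select_cases([r], dictionary, catalog)) == 1

    def test_idempotent_and_order_independent(self, dictionary, catalog):
        rs = [_report(case_id=str(i)) for i in range(5)]
        rs[2] = _report(case_id="2", reactions=["Nausea"])
        once = select_cases(rs, dictionary, catalog)
        assert select_cases(once, dictionary, catalog) == once
        rev = select_cases(list(reversed(rs)), dictionary, catalog)
        assert sorted(r.case_id for r in rev) == sorted(r.case_id for r in once)


class TestClassifyRegimen:
    def test_monotherapy_classes(self):
        for sub, cls in [
            ("nivolumab", "anti-PD-1"),
            ("durvalumab", "anti-PD-L1"),
            ("ipilimumab", "anti-CTLA-4"),
        ]:
            r = _report(drugs=[DrugExposure(sub.upper(), sub, "PS")])
            lab = classify_regimen(r)
            assert lab.kind == "monotherapy"
            assert lab.drug_class == cls
            assert lab.label == sub.capitalize()

    def test_named_combination(self):
        r = _report(
            drugs=[
                DrugExposure("YERVOY", "ipilimumab", "PS"),
                DrugExposure("OPDIVO", "nivolumab", "SS"),
            ]
        )
        lab = classify_regimen(r)
        assert lab.kind == "combination"
        assert lab.label == "Ipilimumab + nivolumab"

    def test_three_agents_is_other_combination(self):
        r = _report(
            drugs=[
                DrugExposure("A", "nivolumab", "PS"),
                DrugExposure("B", "pembrolizumab", "PS"),
                DrugExposure("C", "ipilimumab", "PS"),
            ]
        )
        assert classify_regimen(r).label == "Other combination"

    def test_no_study_drug_raises(self):
        r = _report(drugs=[DrugExposure("ASPIRIN", "other", "PS")])
        with pytest.raises(ValueError, match="select_cases"):
            classify_regimen(r)


class TestComputeTTO:
    def test_whole_day_difference(self):
        r = _report(
            event_date="20190202",
            drugs=[DrugExposure("OPDIVO", "nivolumab", "PS", "20190101")],
        )
        assert compute_tto(r) == 32

    def test_partial_start_date_is_missing(self):
        r = _report(
            event_date="20190701",
            drugs=[DrugExposure("OPDIVO", "nivolumab", "PS", "201906")],
        )
        assert compute_tto(r) is None

    def test_negative_interval_excluded_and_counted(self):
        r = _report(
            event_date="20190401",
            drugs=[DrugExposure("OPDIVO", "nivolumab", "PS", "20190501")],
        )
        counters = {}
        assert compute_tto(r, counters) is None
        assert counters["tto_negative"] == 1

    def test_earliest_start_used(self):
        r = _report(
            event_date="20190301",
            drugs=[
                DrugExposure("OPDIVO", "nivolumab", "PS", "20190201"),
                DrugExposure("YERVOY", "ipilimumab", "SS", "20190101"),
            ],
        )
        assert compute_tto(r) == 59


class TestInterchangeRoundTrip:
    def test_bit_identical_round_trip(self, small_db):
        reports, _ = small_db
        df = reports_to_frame(reports)
        assert frame_to_reports(df) == reports

    def test_died_iff_de_code(self, small_db):
        reports, _ = small_db
        for r in reports:
            assert r.died == ("DE" in r.outcome_codes)
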