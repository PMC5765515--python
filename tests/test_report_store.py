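"""Report/hierarchy/register IO and grouping expansion."""

import datetime as dt

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from uifscan.report_store import (
    FormatError,
    IntegrityError,
    RowValidationError,
    TermHierarchy,
    concern_case_definition,
    expand_grouping,
    load_concerns,
    load_hierarchy,
    load_reports,
    packaged_concerns_path,
    write_hierarchy,
    write_reports,
)

from conftest import make_concern, make_report


def _write_reports_csv(path, rows):
    header = "case_id,receive_date,substance,product_name,event_pt,literature,module\n"
    path.write_text(header + "".join(rows))


class TestLoadReports:
    def test_study_rows_dropped_and_tallied(self, tmp_path, small_hierarchy):
        f = tmp_path / "reports.csv"
        _write_reports_csv(
            f,
            [
                "C1,2010-07-01,s,,pt_a,false,post_marketing\n",
                "C2,2010-07-02,s,,pt_b,false,post_marketing\n",
                "C3,2010-07-03,s,,pt_c,true,post_marketing\n",
                "C4,2010-07-04,s,,pt_a,false,study\n",
            ],
        )
        records, log = load_reports(f, small_hierarchy)
        assert len(records) == 3
        assert log.n_study_excluded == 1
        assert all(r.module == "post_marketing" for r in records)

    def test_empty_file_with_header(self, tmp_path, small_hierarchy):
        f = tmp_path / "reports.csv"
        _write_reports_csv(f, [])
        records, log = load_reports(f, small_hierarchy)
        assert records == [] and log.n_rows == 0

    def test_unknown_pt_rejected_with_row_number(self, tmp_path, small_hierarchy):
        f = tmp_path / "reports.csv"
        _write_reports_csv(
            f,
            [
                "C1,2010-07-01,s,,pt_a,false,post_marketing\n",
                "C2,2010-07-02,s,,pt_nope,false,post_marketing\n",
            ],
        )
        with pytest.raises(RowValidationError) as exc:
            load_reports(f, small_hierarchy)
        assert exc.value.rows == [2]

    def test_missing_column_is_format_error(self, tmp_path, small_hierarchy):
        f = tmp_path / "reports.csv"
        f.write_text("case_id,receive_date,substance\nC1,2010-07-01,s\n")
        with pytest.raises(FormatError):
            load_reports(f, small_hierarchy)

    def test_bad_date_lists_offending_rows(self, tmp_path, small_hierarchy):
        f = tmp_path / "reports.csv"
        _write_reports_csv(
            f,
            [
                "C1,07/01/2010,s,,pt_a,false,post_marketing\n",
                "C2,2010-07-02,s,,pt_a,false,post_marketing\n",
                "C3,not-a-date,s,,pt_a,false,post_marketing\n",
            ],
        )
        with pytest.raises(RowValidationError) as exc:
            load_reports(f, small_hierarchy)
        assert exc.value.rows == [1, 3]

    def test_round_trip_is_record_identical(self, tmp_path, small_hierarchy):
        records = [
            make_report("C1", "2010-07-01", pt="pt_a"),
            make_report("C2", "2010-08-15", pt="pt_b", product="brand x", literature=True),
        ]
        f = tmp_path / "out.csv"
        write_reports(records, f)
        reloaded, _ = load_reports(f, small_hierarchy)
        assert reloaded == records


class TestHierarchy:
    def test_fixture_cardinalities(self, small_hierarchy):
        assert len(small_hierarchy.pts) == 10
        assert len(small_hierarchy.hlt_to_hlgt) == 3
        assert len(small_hierarchy.smq_members) == 1
        assert len(small_hierarchy.smq_members["smq_x"]) == 4

    def test_dangling_hlt_is_integrity_error(self):
        with pytest.raises(IntegrityError, match="hlt_missing"):
            TermHierarchy(
                pt_to_hlt={"pt_a": "hlt_missing"},
                hlt_to_hlgt={},
                hlgt_to_soc={},
            )

    def test_smq_with_unknown_pt_is_integrity_error(self):
        with pytest.raises(IntegrityError, match="smq"):
            TermHierarchy(
                pt_to_hlt={"pt_a": "hlt_1"},
                hlt_to_hlgt={"hlt_1": "hlgt_1"},
                hlgt_to_soc={"hlgt_1": "soc_1"},
                smq_members={"smq_1": {"pt_ghost": "broad"}},
            )

    def test_term_at_two_levels_rejected(self):
        # "x" as both PT and HLT would allow a cycle in the level maps.
        with pytest.raises(IntegrityError):
            TermHierarchy(
                pt_to_hlt={"x": "x"},
                hlt_to_hlgt={"x": "hlgt_1"},
                hlgt_to_soc={"hlgt_1": "soc_1"},
            )

    def test_bundle_round_trip(self, tmp_path, small_hierarchy):
        write_hierarchy(small_hierarchy, tmp_path / "hier")
        h = load_hierarchy(tmp_path / "hier")
        assert h.pt_to_hlt == small_hierarchy.pt_to_hlt
        assert h.smq_members == small_hierarchy.smq_members
        assert h.ime_terms == small_hierarchy.ime_terms
        assert h.quality_issue_terms == small_hierarchy.quality_issue_terms


class TestExpandGrouping:
    def test_union_across_terms(self, small_hierarchy):
        got = expand_grouping(
            small_hierarchy, [("HLT", "hlt_1"), ("SMQ", "smq_x")]
        )
        assert got == {"pt_a", "pt_b", "pt_c", "pt_d", "pt_g"}

    def test_empty_list_gives_empty_set(self, small_hierarchy):
        assert expand_grouping(small_hierarchy, []) == set()

    def test_restriction_can_empty_a_grouping(self, small_hierarchy):
        # hlt_3 members pt_g/pt_h/pt_i/pt_q; only pt_g and pt_q are IME.
        got = expand_grouping(small_hierarchy, [("HLT", "hlt_3")], restrict_ime_dme=True)
        assert got == {"pt_g", "pt_q"}
        # An SMQ of exclusively non-serious members expands to nothing.
        h = TermHierarchy(
            pt_to_hlt={"pt_a": "hlt_1"},
            hlt_to_hlgt={"hlt_1": "hlgt_1"},
            hlgt_to_soc={"hlgt_1": "soc_1"},
            smq_members={"smq_1": {"pt_a": "broad"}},
        )
        assert expand_grouping(h, [("SMQ", "smq_1")], restrict_ime_dme=True) == set()

    def test_unknown_grouping_raises_lookup_error(self, small_hierarchy):
        with pytest.raises(KeyError):
            expand_grouping(small_hierarchy, [("HLT", "hlt_nope")])

    @settings(max_examples=50, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.data())
    def test_monotone_in_term_list(self, small_hierarchy, data):
        pool = [("HLT", "hlt_1"), ("HLT", "hlt_2"), ("HLT", "hlt_3"), ("SMQ", "smq_x")]
        subset = data.draw(st.lists(st.sampled_from(pool), max_size=4, unique=True))
        superset = subset + [t for t in pool if t not in subset]
        assert expand_grouping(small_hierarchy, subset) <= expand_grouping(
            small_hierarchy, superset
        )

    def test_qd_case_definition_excludes_quality_terms(self, small_hierarchy):
        concern = make_concern(concern_type="QD", grouping=(("HLT", "hlt_3"),))
        pts = concern_case_definition(small_hierarchy, concern, restrict_ime_dme=True)
        assert pts == {"pt_g"}  # pt_q dropped: quality-issue term
        concern_me = make_concern(concern_type="ME", grouping=(("HLT", "hlt_3"),))
        assert concern_case_definition(small_hierarchy, concern_me) == {"pt_g", "pt_q"}


class TestConcernRegister:
    def test_packaged_register_has_13_concerns(self):
        concerns = load_concerns(packaged_concerns_path())
        assert len(concerns) == 13
        by_type = {}
        for c in concerns:
            by_type[c.concern_type] = by_type.get(c.concern_type, 0) + 1
        assert by_type == {"QD": 5, "ME": 5, "AM": 3}
        octagam = next(c for c in concerns if "octagam" in (c.product_names or set()))
        assert octagam.index_date == dt.date(2010, 8, 23)
        # Abuse/misuse concerns are substance-wide (no product scope).
        assert all(c.product_names is None for c in concerns if c.concern_type == "AM")

    def test_register_round_trip_and_validation(self, tmp_path, small_hierarchy):
        from uifscan.report_store import write_concerns

        concerns = [
            make_concern("c1", grouping=(("SMQ", "smq_x"), ("HLT", "hlt_1"))),
            make_concern("c2", substance="other drug", concern_type="AM",
                         grouping=(("HLT", "hlt_2"),)),
        ]
        f = tmp_path / "concerns.csv"
        write_concerns(concerns, f)
        assert load_concerns(f, small_hierarchy) == concerns

    def test_unknown_grouping_term_is_integrity_error(self, tmp_path, small_hierarchy):
        f = tmp_path / "concerns.csv"
        f.write_text(
            "concern_id,substance,product_names,index_date,concern_type,"
            "grouping_level,grouping_id\n"
            "c1,s,,2010-08-23,QD,SMQ,smq_ghost\n"
        )
        with pytest.raises(IntegrityError):
            load_concerns(f, small_hierarchy)
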