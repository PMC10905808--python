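import pytest

from redcapkit import (
    FieldDef,
    Query,
    QueryReport,
    QueryRule,
    ValidationError,
    check_queries,
    rd_event,
    rd_query,
    read_project,
    summarize,
    transform_project,
)
from redcapkit.queries import natural_key
from conftest import make_bundle


def simple_query(identifier="100-58", field="copd", value="", event="Baseline visit",
                 text="The value is NA and it should not be missing"):
    return Query(identifier=identifier, dag="Hospital 11", event=event,
                 instrument="Comorbidities", field=field,
                 description="Chronic obstructive pulmonary disease",
                 query_text=text, snapshot_value=value)


class TestRdQuery:
    def test_missingness_query_carries_full_schema(self, default_bundle):
        report = rd_query(default_bundle, QueryRule.missing(["copd"]))
        q = report.queries[0]
        assert q.event == "Baseline visit"
        assert q.instrument == "Comorbidities"
        assert q.field == "copd"
        assert q.description == "Chronic obstructive pulmonary disease"
        assert q.query_text == "The value is NA and it should not be missing"
        assert q.code == f"{q.identifier}-1"
        assert q.dag.startswith("Hospital")

    def test_counts_match_manifest(self, default_bundle, default_fixture):
        _, spec, _ = default_fixture
        report = rd_query(default_bundle, QueryRule.missing(["copd", "age"]))
        per_var = {row["variable"]: row["total"] for row in summarize(report)}
        assert per_var == {"copd": 6, "age": 5}

    def test_no_discrepancies_empty_report(self, tmp_path):
        from redcapkit import FixtureSpec, generate

        generate(FixtureSpec(n_records=8, seed=3), tmp_path / "clean")
        bundle = read_project(tmp_path / "clean" / "records.csv",
                              tmp_path / "clean" / "dictionary.csv",
                              tmp_path / "clean" / "events.csv")
        assert len(rd_query(bundle, QueryRule.missing(["copd", "age"]))) == 0

    def test_range_rule_flags_planted_value(self, default_bundle, default_fixture):
        _, spec, _ = default_fixture
        rule = QueryRule(["weight"], ["[weight] >= 30 and [weight] <= 250"])
        report = rd_query(default_bundle, rule)
        out_of_range = [q for q in report.queries if q.snapshot_value == "300"]
        assert len(out_of_range) == spec.out_of_range["weight"] == 2
        assert "should be" in out_of_range[0].query_text

    def test_event_restriction_uses_event_map(self, default_bundle):
        # copd lives only at baseline; blanks on follow-up rows must not fire
        report = rd_query(default_bundle, QueryRule.missing(["copd"]))
        assert all(q.event == "Baseline visit" for q in report.queries)

    def test_unknown_variable_rejected(self, default_bundle):
        with pytest.raises(ValidationError, match="ghost"):
            rd_query(default_bundle, QueryRule.missing(["ghost"]))

    def test_unmapped_variable_rejected(self, toy_dictionary, toy_event_map):
        dictionary = toy_dictionary + [FieldDef("orphan", "ghost_form", "text", "Orphan")]
        bundle = make_bundle(
            [{"record_id": "1", "redcap_event_name": "baseline_visit_arm_1",
              "orphan": ""}],
            dictionary, toy_event_map)
        with pytest.raises(ValidationError, match="orphan"):
            rd_query(bundle, QueryRule.missing(["orphan"]))

    def test_works_on_transform_result(self, default_bundle):
        result = transform_project(default_bundle)
        report = rd_query(result, QueryRule.missing(["copd", "age"]))
        per_var = {row["variable"]: row["total"] for row in summarize(report)}
        assert per_var == {"copd": 6, "age": 5}

    def test_codes_consecutive_per_identifier(self, default_bundle):
        report = rd_query(default_bundle, QueryRule.missing(["copd", "age"]))
        seen: dict[str, int] = {}
        for q in report.queries:
            seen[q.identifier] = seen.get(q.identifier, 0) + 1
            assert q.code == f"{q.identifier}-{seen[q.identifier]}"

    def test_negate_inverts_rule(self, default_bundle):
        flagged = rd_query(default_bundle, QueryRule(["copd"], ["[copd] = ''"], negate=True))
        straight = rd_query(default_bundle, QueryRule.missing(["copd"]))
        assert {q.identifier for q in flagged.queries} == {
            q.identifier for q in straight.queries
        }


class TestRdEvent:
    def test_planted_missing_events_found(self, default_bundle, default_fixture):
        _, spec, _ = default_fixture
        report = rd_event(default_bundle, ["follow_up_arm_1"])
        assert len(report.queries) == spec.n_missing_events == 3
        q = report.queries[0]
        assert q.query_text == "The event is missing"
        assert q.field == "" and q.instrument == "" and q.description == ""
        assert q.event == "Follow up"

    def test_complete_grid_empty_report(self, tmp_path):
        from redcapkit import FixtureSpec, generate

        generate(FixtureSpec(n_records=6, seed=5), tmp_path / "full")
        bundle = read_project(tmp_path / "full" / "records.csv",
                              tmp_path / "full" / "dictionary.csv",
                              tmp_path / "full" / "events.csv")
        assert len(rd_event(bundle, ["follow_up_arm_1", "baseline_visit_arm_1"])) == 0

    def test_two_missing_events_two_codes(self, toy_dictionary):
        from redcapkit import EventFormEntry, EventFormMap

        event_map = EventFormMap([
            EventFormEntry(1, "baseline_arm_1", "demographics"),
            EventFormEntry(1, "fu1_arm_1", "comorbidities"),
            EventFormEntry(1, "fu2_arm_1", "comorbidities"),
        ])
        bundle = make_bundle(
            [{"record_id": "7", "redcap_event_name": "baseline_arm_1", "age": "30"}],
            toy_dictionary, event_map)
        report = rd_event(bundle, ["fu1_arm_1", "fu2_arm_1"])
        assert [q.code for q in report.queries] == ["7-1", "7-2"]

    def test_unknown_event_rejected(self, default_bundle):
        with pytest.raises(ValidationError, match="ghost"):
            rd_event(default_bundle, ["ghost_arm_1"])

    def test_requires_event_map(self, toy_dictionary):
        bundle = make_bundle([{"record_id": "1", "age": "3"}], toy_dictionary)
        with pytest.raises(ValidationError):
            rd_event(bundle, ["baseline_arm_1"])


class TestSummarize:
    def test_totals_conserve_and_sort_descending(self, default_bundle):
        report = rd_query(default_bundle, QueryRule.missing(["copd", "age"]))
        rows = summarize(report)
        assert sum(r["total"] for r in rows) == len(report.queries)
        assert [r["total"] for r in rows] == sorted(
            (r["total"] for r in rows), reverse=True)
        assert rows[0]["query"] == "The value should not be missing"

    def test_empty_report_empty_summary(self):
        assert summarize(QueryReport([])) == []

    def test_same_variable_two_events_two_rows(self):
        report = QueryReport([
            simple_query(event="Baseline visit"),
            simple_query(identifier="100-59", event="Follow up"),
        ])
        assert len(summarize(report)) == 2


class TestCheckQueries:
    def test_same_report_all_pending(self, default_bundle):
        report = rd_query(default_bundle, QueryRule.missing(["copd", "age"]))
        diff = check_queries(report, report)
        assert diff.summary == {"New": 0, "Pending": len(report.queries),
                                "Solved": 0, "Miscorrected": 0}

    def test_old_empty_all_new(self, default_bundle):
        report = rd_query(default_bundle, QueryRule.missing(["copd"]))
        diff = check_queries(QueryReport([]), report)
        assert diff.summary["New"] == len(report.queries)

    def test_new_empty_all_solved(self, default_bundle):
        report = rd_query(default_bundle, QueryRule.missing(["copd"]))
        diff = check_queries(report, QueryReport([]))
        assert diff.summary["Solved"] == len(report.queries)

    def test_value_change_is_miscorrected(self):
        old = QueryReport([simple_query(value="",
                                        text="The value is NA and it should be [age] <= 100")])
        new = QueryReport([simple_query(value="999",
                                        text="The value is 999 and it should be [age] <= 100")])
        diff = check_queries(old, new)
        assert diff.summary["Miscorrected"] == 1

    def test_pending_and_new_mix(self):
        old = QueryReport([simple_query()])
        new = QueryReport([simple_query(), simple_query(identifier="100-79")])
        diff = check_queries(old, new)
        modifications = {q.identifier: m for q, m in diff.merged}
        assert modifications == {"100-58": "Pending", "100-79": "New"}

    def test_duplicate_match_key_rejected(self):
        report = QueryReport([simple_query(), simple_query()])
        with pytest.raises(ValidationError, match="duplicate"):
            check_queries(report, QueryReport([]))

    def test_partition_law(self, default_bundle):
        copd = rd_query(default_bundle, QueryRule.missing(["copd"]))
        both = rd_query(default_bundle, QueryRule.missing(["copd", "age"]))
        diff = check_queries(copd, both)
        union = {q.match_key for q in copd.queries} | {q.match_key for q in both.queries}
        assert sum(diff.summary.values()) == len(union)


def test_natural_key_sorts_numeric_segments():
    ids = ["100-113", "100-58", "100-9", "99-1"]
    assert sorted(ids, key=natural_key) == ["99-1", "100-9", "100-58", "100-113"]
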