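import pytest

from redcapkit import (
    ConfigError,
    EventFormEntry,
    EventFormMap,
    FieldDef,
    TransformConfig,
    ValidationError,
    apply_factors,
    delete_pattern_vars,
    read_project,
    split,
    transform_checkboxes,
    transform_project,
)
from conftest import make_bundle


@pytest.fixture
def checkbox_dictionary():
    return [
        FieldDef("record_id", "comorbidities", "text", "Record ID"),
        FieldDef("has_comorb", "comorbidities", "yesno", "Any comorbidity"),
        FieldDef("comorb", "comorbidities", "checkbox", "Comorbidities",
                 choices={"1": "Hypertension", "2": "Diabetes"},
                 branching_logic="[has_comorb] = '1'"),
        FieldDef("symptoms", "comorbidities", "checkbox", "Symptoms",
                 choices={"1": "Fever", "2": "Cough"}),
    ]


def checkbox_rows():
    return [
        {"record_id": "1", "has_comorb": "1", "comorb___1": "0", "comorb___2": "1",
         "symptoms___1": "1", "symptoms___2": "0"},
        {"record_id": "2", "has_comorb": "0", "comorb___1": "0", "comorb___2": "0",
         "symptoms___1": "0", "symptoms___2": "0"},
        {"record_id": "3", "has_comorb": "", "comorb___1": "0", "comorb___2": "0",
         "symptoms___1": "0", "symptoms___2": "1"},
    ]


class TestCheckboxes:
    def test_rename_and_relabel(self, checkbox_dictionary):
        bundle = make_bundle(checkbox_rows(), checkbox_dictionary)
        records, dictionary, _ = transform_checkboxes(bundle.records, checkbox_dictionary)
        assert "diabetes" in records.df.columns
        assert "comorb___2" not in records.df.columns
        assert records.df.iloc[0]["diabetes"] == "Yes"
        assert records.df.iloc[1]["diabetes"] == "No"

    def test_branching_missing_blanks_options(self, checkbox_dictionary):
        bundle = make_bundle(checkbox_rows(), checkbox_dictionary)
        records, _, _ = transform_checkboxes(bundle.records, checkbox_dictionary)
        # record 3: has_comorb blank -> branching missing -> checkbox blanked
        assert records.df.iloc[2]["hypertension"] == ""
        assert records.df.iloc[2]["diabetes"] == ""
        # but branching false (record 2) keeps its No values
        assert records.df.iloc[1]["diabetes"] == "No"

    def test_branching_false_policy(self, checkbox_dictionary):
        bundle = make_bundle(checkbox_rows(), checkbox_dictionary)
        config = TransformConfig(checkbox_na_policy="branching_missing_or_false")
        records, _, _ = transform_checkboxes(bundle.records, checkbox_dictionary, config)
        assert records.df.iloc[1]["diabetes"] == ""  # branching false now blanks too

    def test_no_branching_checkbox_warned(self, checkbox_dictionary):
        bundle = make_bundle(checkbox_rows(), checkbox_dictionary)
        _, _, warnings = transform_checkboxes(bundle.records, checkbox_dictionary)
        assert any("symptoms" in w for w in warnings)

    def test_updated_dictionary_has_option_fields(self, checkbox_dictionary):
        bundle = make_bundle(checkbox_rows(), checkbox_dictionary)
        _, dictionary, _ = transform_checkboxes(bundle.records, checkbox_dictionary)
        names = [f.name for f in dictionary]
        assert "hypertension" in names and "diabetes" in names
        assert "comorb" not in names

    def test_custom_labels(self, checkbox_dictionary):
        bundle = make_bundle(checkbox_rows(), checkbox_dictionary)
        config = TransformConfig(checkbox_labels=("Non", "Oui"))
        records, _, _ = transform_checkboxes(bundle.records, checkbox_dictionary, config)
        assert records.df.iloc[0]["diabetes"] == "Oui"


class TestFactors:
    def test_codes_replaced_by_labels(self, toy_dictionary):
        bundle = make_bundle([{"record_id": "1", "sex": "1", "copd": "0"}], toy_dictionary)
        records, warnings = apply_factors(bundle.records, toy_dictionary)
        assert records.df.iloc[0]["sex"] == "Female"
        assert records.df.iloc[0]["copd"] == "No"
        assert warnings == []

    def test_event_and_dag_keep_both_versions(self, toy_dictionary):
        bundle = make_bundle(
            [{"record_id": "1", "redcap_event_name": "baseline_visit_arm_1",
              "redcap_data_access_group": "hospital_11", "sex": "2"}],
            toy_dictionary,
        )
        records, _ = apply_factors(bundle.records, toy_dictionary)
        row = records.df.iloc[0]
        assert row["redcap_event_name"] == "baseline_visit_arm_1"
        assert row["redcap_event_name_label"] == "Baseline visit"
        assert row["redcap_data_access_group"] == "hospital_11"
        assert row["redcap_data_access_group_label"] == "Hospital 11"

    def test_unknown_code_kept_with_warning(self, toy_dictionary):
        bundle = make_bundle([{"record_id": "1", "sex": "9"}], toy_dictionary)
        records, warnings = apply_factors(bundle.records, toy_dictionary)
        assert records.df.iloc[0]["sex"] == "9"
        assert any("'9'" in w for w in warnings)

    def test_already_labeled_rejected(self, toy_dictionary):
        bundle = make_bundle([{"record_id": "1", "sex": "Female"}], toy_dictionary)
        with pytest.raises(ValidationError, match="already"):
            apply_factors(bundle.records, toy_dictionary)


class TestDeletePatterns:
    def test_suffix_deletion(self, toy_dictionary):
        bundle = make_bundle(
            [{"record_id": "1", "age": "40", "comorbidities_complete": "2",
              "survey_timestamp": "t"}],
            toy_dictionary,
        )
        records = delete_pattern_vars(bundle.records, ["_complete", "_timestamp"])
        assert list(records.df.columns) == ["record_id", "age"]

    def test_suffix_anchored_not_substring(self, toy_dictionary):
        bundle = make_bundle([{"record_id": "1", "age": "1"}], toy_dictionary)
        records = delete_pattern_vars(bundle.records, ["cord"])  # inside "record_id"
        assert "record_id" in records.df.columns

    def test_no_match_is_identity(self, toy_dictionary):
        bundle = make_bundle([{"record_id": "1", "age": "40"}], toy_dictionary)
        records = delete_pattern_vars(bundle.records, ["_complete"])
        assert records.df.equals(bundle.records.df)

    def test_idempotent(self, toy_dictionary):
        bundle = make_bundle(
            [{"record_id": "1", "age": "4", "demographics_complete": "2"}], toy_dictionary
        )
        once = delete_pattern_vars(bundle.records, ["_complete"])
        twice = delete_pattern_vars(once, ["_complete"])
        assert once.df.equals(twice.df)

    def test_empty_patterns_rejected_at_config(self):
        with pytest.raises(ConfigError):
            TransformConfig(delete_patterns=())


class TestSplit:
    def three_event_bundle(self):
        dictionary = [
            FieldDef("record_id", "idform", "text", "ID"),
            FieldDef("a", "form_a", "text", "A"),
            FieldDef("b", "form_b", "text", "B"),
            FieldDef("c", "form_c", "text", "C"),
        ]
        event_map = EventFormMap([
            EventFormEntry(1, "e1_arm_1", "idform"),
            EventFormEntry(1, "e1_arm_1", "form_a"),
            EventFormEntry(1, "e2_arm_1", "form_b"),
            EventFormEntry(1, "e3_arm_1", "form_c"),
        ])
        rows = []
        for rid in ("1", "2"):
            rows.append({"record_id": rid, "redcap_event_name": "e1_arm_1", "a": "x"})
            rows.append({"record_id": rid, "redcap_event_name": "e2_arm_1", "b": "y"})
            rows.append({"record_id": rid, "redcap_event_name": "e3_arm_1", "c": "z"})
        return make_bundle(rows, dictionary, event_map)

    def test_by_event_group_count(self):
        bundle = self.three_event_bundle()
        table = split(bundle.records, "event", bundle.dictionary, bundle.event_map)
        assert [g.key for g in table.groups] == ["e1_arm_1", "e2_arm_1", "e3_arm_1"]

    def test_by_event_vars_disjoint_except_reserved(self):
        bundle = self.three_event_bundle()
        table = split(bundle.records, "event", bundle.dictionary, bundle.event_map)
        reserved = {"record_id", "redcap_event_name"}
        payload = [set(g.vars) - reserved for g in table.groups]
        assert payload[0] & payload[1] == set()
        assert payload[1] & payload[2] == set()

    def test_by_event_requires_event_map(self):
        bundle = self.three_event_bundle()
        with pytest.raises(ConfigError):
            split(bundle.records, "event", bundle.dictionary, None)

    def test_by_form_group_count_and_rows(self):
        bundle = self.three_event_bundle()
        table = split(bundle.records, "form", bundle.dictionary)
        by_key = {g.key: g for g in table.groups}
        assert set(by_key) == {"form_a", "form_b", "form_c"}
        # rows restricted to those with any non-missing value for the form
        assert len(by_key["form_a"].data.df) == 2

    def test_unknown_event_rejected(self):
        bundle = self.three_event_bundle()
        bad_map = EventFormMap([EventFormEntry(1, "e1_arm_1", "form_a")])
        with pytest.raises(ValidationError):
            split(bundle.records, "event", bundle.dictionary, bad_map)


class TestPipeline:
    def test_default_run_five_steps(self, default_bundle):
        result = transform_project(default_bundle)
        assert [s.number for s in result.trace] == [1, 2, 3, 4, 5]

    def test_recalc_flags_planted_age_mismatch(self, default_bundle, default_fixture):
        _, spec, _ = default_fixture
        result = transform_project(default_bundle)
        age = next(r for r in result.recalc_report if r.field == "age")
        assert age.summary["mismatch"] == spec.n_calc_mismatch == 1
        assert age.status == "not identical"

    def test_row_conservation_before_deletion(self, default_bundle):
        result = transform_project(default_bundle)
        assert len(result.records.df) == len(default_bundle.records.df)

    def test_no_surviving_column_matches_pattern(self, default_bundle):
        result = transform_project(default_bundle)
        for col in result.records.df.columns:
            assert not col.endswith(("_complete", "_timestamp"))

    def test_delete_only_complete_keeps_timestamps(self, default_bundle):
        config = TransformConfig(delete_patterns=("_complete",))
        result = transform_project(default_bundle, config)
        assert any(c.endswith("_timestamp") for c in result.records.df.columns)

    def test_by_event_split_appends_sixth_step(self, default_bundle):
        result = transform_project(default_bundle, TransformConfig(final_format="by_event"))
        assert len(result.trace) == 6
        assert len(result.data.groups) == 2

    def test_by_event_without_map_is_config_error(self, default_fixture):
        out, _, _ = default_fixture
        bundle = read_project(out / "records.csv", out / "dictionary.csv")
        with pytest.raises(ConfigError):
            transform_project(bundle, TransformConfig(final_format="by_event"))

    def test_split_completeness(self, default_bundle):
        result = transform_project(default_bundle, TransformConfig(final_format="by_event"))
        grouped = set().union(*(set(g.vars) for g in result.data.groups))
        for col in transform_project(default_bundle).records.df.columns:
            assert col in grouped

    def test_checkbox_no_branching_reported_in_trace(self, default_bundle):
        result = transform_project(default_bundle)
        step2 = result.trace[1]
        assert any("symptoms_1" in w for w in step2.warnings)

    def test_recalc_self_consistency_without_planting(self, tmp_path):
        from redcapkit import FixtureSpec, generate

        generate(FixtureSpec(n_records=10, seed=7), tmp_path / "clean")
        bundle = read_project(tmp_path / "clean" / "records.csv",
                              tmp_path / "clean" / "dictionary.csv",
                              tmp_path / "clean" / "events.csv")
        result = transform_project(bundle)
        for r in result.recalc_report:
            assert r.summary["mismatch"] == 0
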