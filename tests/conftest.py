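from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracle_logic

from redcapkit import (
    EventFormEntry,
    EventFormMap,
    FieldDef,
    FixtureSpec,
    ProjectBundle,
    RecordTable,
    ValidationSpec,
    generate,
    read_project,
)


def make_bundle(rows: list[dict], dictionary: list[FieldDef],
                event_map: EventFormMap | None = None,
                id_column: str = "record_id") -> ProjectBundle:
    """Assemble an in-memory bundle from row dicts (missing cells become '')."""
    columns = list(dict.fromkeys(k for row in rows for k in row))
    if id_column in columns:
        columns.remove(id_column)
        columns.insert(0, id_column)
    df = pd.DataFrame(rows, columns=columns).fillna("").astype(str)
    return ProjectBundle(RecordTable(df, id_column), dictionary, event_map)


@pytest.fixture
def toy_dictionary() -> list[FieldDef]:
    return [
        FieldDef("record_id", "demographics", "text", "Record ID"),
        FieldDef("age", "demographics", "text", "Age",
                 validation=ValidationSpec(kind="integer", min="18", max="100")),
        FieldDef("sex", "demographics", "radio", "Sex",
                 choices={"1": "Female", "2": "Male"}),
        FieldDef("copd", "comorbidities", "yesno",
                 "Chronic obstructive pulmonary disease"),
    ]


@pytest.fixture
def toy_event_map() -> EventFormMap:
    return EventFormMap([
        EventFormEntry(1, "baseline_visit_arm_1", "demographics"),
        EventFormEntry(1, "baseline_visit_arm_1", "comorbidities"),
        EventFormEntry(1, "follow_up_arm_1", "comorbidities"),
    ])


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The standard planted-discrepancy project used across test modules."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(
        n_records=20,
        seed=1,
        missing_required={"copd": 6, "age": 5},
        out_of_range={"weight": 2},
        n_calc_mismatch=1,
        n_missing_events=3,
        n_checkbox_no_branching=1,
    )
    manifest = generate(spec, out)
    return out, spec, manifest


@pytest.fixture(scope="session")
def default_bundle(default_fixture):
    out, _, _ = default_fixture
    return read_project(out / "records.csv", out / "dictionary.csv", out / "events.csv")
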