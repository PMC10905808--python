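"""Readers and writers for the three REDCap export files.

``read_project`` turns a records CSV, a metadata (data dictionary) CSV and an
optional event-form mapping CSV into a validated :class:`ProjectBundle`. Raw
coded values are preserved as strings; an empty cell is the single internal
missing marker (the literal string ``"NA"`` is kept as a value — REDCap
exports blanks for missing data).

Both metadata header dialects are accepted: the web export
("Variable / Field Name", ...) and the API-style snake_case one
(``field_name``, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "ValidationSpec",
    "FieldDef",
    "EventFormEntry",
    "EventFormMap",
    "RecordTable",
    "ProjectBundle",
    "read_dictionary",
    "read_event_map",
    "read_project",
    "write_project",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]

CHECKBOX_SEP = "___"
RESERVED_COLUMNS = {
    "redcap_event_name",
    "redcap_data_access_group",
    "redcap_repeat_instrument",
    "redcap_repeat_instance",
}
REPORT_COLUMNS = ["Identifier", "DAG", "Event", "Instrument", "Field", "Description", "Query", "Code"]

FIELD_TYPES = {
    "text", "notes", "radio", "dropdown", "checkbox", "yesno", "truefalse",
    "calc", "file", "slider", "descriptive",
}
_CHOICE_TYPES = {"radio", "dropdown", "checkbox"}

_VALIDATION_KINDS = {
    "integer": "integer",
    "int": "integer",
    "number": "number",
    "number_1dp": "number",
    "number_2dp": "number",
    "date_dmy": "date_dmy",
    "date_ymd": "date_ymd",
    "date_mdy": "date_mdy",
    "datetime_dmy": "datetime",
    "datetime_ymd": "datetime",
    "datetime_mdy": "datetime",
    "datetime_seconds_ymd": "datetime",
    "datetime_seconds_dmy": "datetime",
    "datetime_seconds_mdy": "datetime",
    "time": "time",
    "email": "email",
    "": "none",
}

# normalized header -> internal name; covers web-export and API dialects
_DIC_ALIASES = {
    "variable_field_name": "field_name",
    "field_name": "field_name",
    "form_name": "form_name",
    "field_type": "field_type",
    "field_label": "field_label",
    "choices_calculations_or_slider_labels": "choices",
    "select_choices_or_calculations": "choices",
    "branching_logic": "branching_logic",
    "branching_logic_show_field_only_if": "branching_logic",
    "text_validation_type_or_show_slider_number": "validation_type",
    "text_validation_type": "validation_type",
    "text_validation_min": "validation_min",
    "text_validation_max": "validation_max",
}
_REQUIRED_DIC = ["field_name", "form_name", "field_type", "field_label"]

_DIC_EXPORT_HEADER = [
    "Variable / Field Name", "Form Name", "Section Header", "Field Type",
    "Field Label", "Choices, Calculations, OR Slider Labels", "Field Note",
    "Text Validation Type OR Show Slider Number", "Text Validation Min",
    "Text Validation Max", "Identifier?",
    "Branching Logic (Show field only if...)", "Required Field?",
    "Custom Alignment", "Question Number (surveys only)", "Matrix Group Name",
    "Matrix Ranking?", "Field Annotation",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ValidationSpec:
    kind: str = "none"  # integer|number|date_dmy|date_ymd|date_mdy|datetime|time|email|none
    min: Optional[str] = None
    max: Optional[str] = None


@dataclass
class FieldDef:
    name: str
    form: str
    field_type: str
    label: str = ""
    choices: dict[str, str] = dc_field(default_factory=dict)  # code -> label, ordered
    calculation: str = ""
    branching_logic: str = ""
    validation: ValidationSpec = dc_field(default_factory=ValidationSpec)

    def __post_init__(self) -> None:
        if self.field_type not in FIELD_TYPES:
            raise SchemaError(f"field {self.name!r}: unknown field type {self.field_type!r}")
        if self.field_type in _CHOICE_TYPES and not self.choices:
            raise SchemaError(f"field {self.name!r}: {self.field_type} field requires choices")
        if self.field_type not in _CHOICE_TYPES and self.choices:
            raise SchemaError(f"field {self.name!r}: choices only allowed on radio/dropdown/checkbox")
        if self.field_type == "calc" and not self.calculation.strip():
            raise SchemaError(f"field {self.name!r}: calc field with empty calculation")
        if self.field_type != "calc" and self.calculation:
            raise SchemaError(f"field {self.name!r}: calculation only allowed on calc fields")
        if CHECKBOX_SEP in self.name:
            raise SchemaError(
                f"field {self.name!r}: field names may not contain {CHECKBOX_SEP!r}"
            )


@dataclass(frozen=True)
class EventFormEntry:
    arm: int
    event: str
    form: str


@dataclass
class EventFormMap:
    entries: list[EventFormEntry]

    def __post_init__(self) -> None:
        triples = [(e.arm, e.event, e.form) for e in self.entries]
        if len(set(triples)) != len(triples):
            raise ValidationError("event-form mapping contains duplicate (arm, event, form) rows")

    @property
    def events(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.event not in seen:
                seen.append(e.event)
        return seen

    def forms_for(self, event: str) -> list[str]:
        return [e.form for e in self.entries if e.event == event]

    def events_for_form(self, form: str) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.form == form and e.event not in seen:
                seen.append(e.event)
        return seen

    def arm_of(self, event: str) -> Optional[int]:
        for e in self.entries:
            if e.event == event:
                return e.arm
        return None


@dataclass
class RecordTable:
    """One row per (record, event[, repeat instance]); values are raw strings,
    empty string meaning missing."""

    df: pd.DataFrame
    id_column: str

    @property
    def events(self) -> list[str]:
        if "redcap_event_name" not in self.df.columns:
            return []
        seen: list[str] = []
        for e in self.df["redcap_event_name"]:
            if e and e not in seen:
                seen.append(e)
        return seen

    def copy(self) -> "RecordTable":
        return RecordTable(self.df.copy(), self.id_column)


@dataclass
class ProjectBundle:
    records: RecordTable
    dictionary: list[FieldDef]
    event_map: Optional[EventFormMap] = None

    @property
    def labels(self) -> dict[str, dict[str, str]]:
        return {f.name: dict(f.choices) for f in self.dictionary if f.choices}

    def field(self, name: str) -> Optional[FieldDef]:
        for f in self.dictionary:
            if f.name == name:
                return f
        return None

    @property
    def forms(self) -> list[str]:
        seen: list[str] = []
        for f in self.dictionary:
            if f.form not in seen:
                seen.append(f.form)
        return seen


# ---------------------------------------------------------------------------
# reading


def _normalize_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def parse_choices(cell: str) -> dict[str, str]:
    """Parse ``"1, Yes | 0, No"`` into an ordered code->label map; labels may
    contain commas (the split is on the first comma of each option)."""
    choices: dict[str, str] = {}
    for part in cell.split("|"):
        part = part.strip()
        if not part:
            continue
        code, _, label = part.partition(",")
        choices[code.strip()] = label.strip()
    return choices


def read_dictionary(dic_path: str | Path) -> list[FieldDef]:
    """Read a REDCap metadata CSV (either header dialect) into FieldDefs."""
    df = _read_csv(Path(dic_path))
    columns: dict[str, str] = {}
    for col in df.columns:
        alias = _DIC_ALIASES.get(_normalize_header(col))
        if alias and alias not in columns:
            columns[alias] = col
    missing = [c for c in _REQUIRED_DIC if c not in columns]
    if missing:
        raise SchemaError(
            "dictionary header mismatch: expected columns for "
            f"{missing} but found {list(df.columns)}"
        )

    def cell(row, key: str) -> str:
        col = columns.get(key)
        return str(row[col]).strip() if col is not None else ""

    fields: list[FieldDef] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = cell(row, "field_name")
        if name in seen:
            raise SchemaError(f"duplicate field name {name!r} in dictionary")
        seen.add(name)
        field_type = cell(row, "field_type")
        raw_choices = cell(row, "choices")
        validation_raw = cell(row, "validation_type").lower()
        kind = _VALIDATION_KINDS.get(validation_raw, "none")
        fields.append(
            FieldDef(
                name=name,
                form=cell(row, "form_name"),
                field_type=field_type,
                label=cell(row, "field_label"),
                choices=parse_choices(raw_choices) if field_type in _CHOICE_TYPES else {},
                calculation=raw_choices if field_type == "calc" else "",
                branching_logic=cell(row, "branching_logic"),
                validation=ValidationSpec(
                    kind=kind,
                    min=cell(row, "validation_min") or None,
                    max=cell(row, "validation_max") or None,
                ),
            )
        )
    return fields


def read_event_map(event_path: str | Path, forms: Sequence[str] | None = None) -> EventFormMap:
    """Read the "Designate Instruments for My Events" CSV."""
    df = _read_csv(Path(event_path))
    normalized = {_normalize_header(c): c for c in df.columns}
    missing = [c for c in ("arm_num", "unique_event_name", "form") if c not in normalized]
    if missing:
        raise SchemaError(
            f"event-form mapping header mismatch: expected {missing}, found {list(df.columns)}"
        )
    entries = [
        EventFormEntry(
            arm=int(row[normalized["arm_num"]]),
            event=str(row[normalized["unique_event_name"]]).strip(),
            form=str(row[normalized["form"]]).strip(),
        )
        for _, row in df.iterrows()
    ]
    event_map = EventFormMap(entries)
    if forms is not None:
        known = set(forms)
        unknown = sorted({e.form for e in event_map.entries} - known)
        if unknown:
            raise ValidationError(
                f"event-form mapping references unknown forms: {unknown}"
            )
    return event_map


def _validate_record_columns(df: pd.DataFrame, dictionary: list[FieldDef]) -> None:
    by_name = {f.name: f for f in dictionary}
    forms = {f.form for f in dictionary}
    id_column = df.columns[0]
    for col in df.columns:
        if col == id_column or col in RESERVED_COLUMNS:
            continue
        if col.endswith("_timestamp"):
            continue
        if col.endswith("_complete") and col[: -len("_complete")] in forms:
            continue
        if CHECKBOX_SEP in col:
            base, _, code = col.partition(CHECKBOX_SEP)
            parent = by_name.get(base)
            if parent is None or parent.field_type != "checkbox":
                raise ValidationError(
                    f"records column {col!r} has no checkbox field {base!r} in the dictionary"
                )
            if code not in parent.choices:
                raise ValidationError(
                    f"records column {col!r}: code {code!r} not among choices of {base!r}"
                )
            continue
        f = by_name.get(col)
        if f is None:
            raise ValidationError(f"records column {col!r} is not defined in the dictionary")
        if f.field_type == "checkbox":
            raise ValidationError(
                f"checkbox field {col!r} must be exported as {col}{CHECKBOX_SEP}<code> columns"
            )


def _validate_row_keys(df: pd.DataFrame, id_column: str) -> None:
    key_cols = [id_column]
    for col in ("redcap_event_name", "redcap_repeat_instrument", "redcap_repeat_instance"):
        if col in df.columns:
            key_cols.append(col)
    dupes = df[df.duplicated(subset=key_cols, keep="first")]
    if not dupes.empty:
        row = int(dupes.index[0]) + 1  # 1-based data rows, header excluded
        raise ValidationError(
            f"duplicate (record, event) key at data row {row}: "
            + ", ".join(str(dupes.iloc[0][c]) for c in key_cols)
        )


def read_project(
    data_path: str | Path,
    dic_path: str | Path,
    event_path: str | Path | None = None,
) -> ProjectBundle:
    """Read the records + dictionary (+ optional event map) CSVs into a
    validated :class:`ProjectBundle`."""
    dictionary = read_dictionary(dic_path)
    df = _read_csv(Path(data_path))
    if df.columns.empty:
        raise SchemaError(f"records file {data_path} has no columns")
    _validate_record_columns(df, dictionary)
    id_column = df.columns[0]
    _validate_row_keys(df, id_column)
    records = RecordTable(df, id_column)

    event_map = None
    if event_path is not None:
        event_map = read_event_map(event_path, forms=[f.form for f in dictionary])
        known_events = set(event_map.events)
        unknown = [e for e in records.events if e not in known_events]
        if unknown:
            raise ValidationError(
                f"records contain events missing from the event-form mapping: {unknown}"
            )
    return ProjectBundle(records=records, dictionary=dictionary, event_map=event_map)


# ---------------------------------------------------------------------------
# writing


def _render_choices(f: FieldDef) -> str:
    if f.field_type == "calc":
        return f.calculation
    return " | ".join(f"{code}, {label}" for code, label in f.choices.items())


def write_dictionary(dictionary: Sequence[FieldDef], path: str | Path) -> None:
    """Write FieldDefs back in the web-export metadata dialect."""
    rows = []
    for f in dictionary:
        row = {c: "" for c in _DIC_EXPORT_HEADER}
        row["Variable / Field Name"] = f.name
        row["Form Name"] = f.form
        row["Field Type"] = f.field_type
        row["Field Label"] = f.label
        row["Choices, Calculations, OR Slider Labels"] = _render_choices(f)
        row["Text Validation Type OR Show Slider Number"] = (
            "" if f.validation.kind == "none" else f.validation.kind
        )
        row["Text Validation Min"] = f.validation.min or ""
        row["Text Validation Max"] = f.validation.max or ""
        row["Branching Logic (Show field only if...)"] = f.branching_logic
        rows.append(row)
    pd.DataFrame(rows, columns=_DIC_EXPORT_HEADER).to_csv(
        path, index=False, lineterminator="\n"
    )


def write_project(bundle: ProjectBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write records.csv / dictionary.csv / events.csv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"records": out / "records.csv", "dictionary": out / "dictionary.csv"}
    bundle.records.df.to_csv(paths["records"], index=False, lineterminator="\n")
    write_dictionary(bundle.dictionary, paths["dictionary"])
    if bundle.event_map is not None:
        paths["events"] = out / "events.csv"
        pd.DataFrame(
            [
                {"arm_num": e.arm, "unique_event_name": e.event, "form": e.form}
                for e in bundle.event_map.entries
            ],
            columns=["arm_num", "unique_event_name", "form"],
        ).to_csv(paths["events"], index=False, lineterminator="\n")
    return paths


def write_report(report, path: str | Path, format: str = "csv",
                 include_snapshot: bool = False) -> None:
    """Persist a QueryReport or QueryDiff with the canonical column layout."""
    from .queries import QueryDiff, QueryReport  # avoid an import cycle

    path = Path(path)
    if isinstance(report, QueryDiff):
        rows = [
            {**_query_row(q, include_snapshot), "Modification": mod}
            for q, mod in report.merged
        ]
        columns = REPORT_COLUMNS + (["Value"] if include_snapshot else []) + ["Modification"]
    elif isinstance(report, QueryReport):
        rows = [_query_row(q, include_snapshot) for q in report.queries]
        columns = REPORT_COLUMNS + (["Value"] if include_snapshot else [])
    else:
        raise TypeError(f"cannot write report of type {type(report).__name__}")
    frame = pd.DataFrame(rows, columns=columns)
    if format == "csv":
        frame.to_csv(path, index=False, lineterminator="\n")
    elif format == "xlsx":
        frame.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def _query_row(q, include_snapshot: bool) -> dict:
    row = {
        "Identifier": q.identifier,
        "DAG": q.dag,
        "Event": q.event,
        "Instrument": q.instrument,
        "Field": q.field,
        "Description": q.description,
        "Query": q.query_text,
        "Code": q.code,
    }
    if include_snapshot:
        row["Value"] = q.snapshot_value
    return row


def read_report(path: str | Path):
    """Read back a report CSV written by :func:`write_report`."""
    from .queries import Query, QueryDiff, QueryReport

    df = _read_csv(Path(path))
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"report {path} is missing columns {missing}")
    queries = []
    modifications = []
    for _, row in df.iterrows():
        queries.append(
            Query(
                identifier=row["Identifier"],
                dag=row["DAG"],
                event=row["Event"],
                instrument=row["Instrument"],
                field=row["Field"],
                description=row["Description"],
                query_text=row["Query"],
                code=row["Code"],
                snapshot_value=row.get("Value", ""),
            )
        )
        if "Modification" in df.columns:
            modifications.append(row["Modification"])
    if modifications:
        return QueryDiff(merged=list(zip(queries, modifications)))
    return QueryReport(queries=queries)
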