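"""The five-step default transformation plus the optional split.

Steps, in fixed order:

1. recalculate every calc field and compare with the stored values;
2. checkbox transformation (option-named columns, No/Yes labels, missing
   handling driven by the parent's branching logic);
3. factor substitution (codes -> labels; event and DAG keep both versions);
4. branching-logic translation into the updated dictionary;
5. pattern-based column deletion (``_complete`` / ``_timestamp`` by default);

then, optionally, the table is split by event or by form. Every step leaves a
record in the trace, including untranslatable-expression warnings and
checkbox fields that lack a branching logic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

from .errors import ConfigError, ValidationError
from .logic import (
    MISSING,
    EvalContext,
    RecalcResult,
    checkbox_rename_map,
    evaluate,
    recalculate,
    to_truth,
    translate,
)
from .naming import prettify
from .project_io import CHECKBOX_SEP, EventFormMap, FieldDef, ProjectBundle, RecordTable

__all__ = [
    "TransformConfig",
    "TraceStep",
    "SplitGroup",
    "SplitTable",
    "TransformResult",
    "transform_project",
    "transform_checkboxes",
    "apply_factors",
    "delete_pattern_vars",
    "split",
]

RESERVED_PREFIX = ("redcap_event_name", "redcap_data_access_group",
                   "redcap_repeat_instrument", "redcap_repeat_instance")


@dataclass
class TransformConfig:
    checkbox_labels: tuple[str, str] = ("No", "Yes")
    delete_patterns: tuple[str, ...] = ("_complete", "_timestamp")
    final_format: str = "raw"  # raw | by_event | by_form
    checkbox_na_policy: str = "branching_missing_only"  # or branching_missing_or_false
    delete_mode: str = "suffix"  # or substring

    def __post_init__(self) -> None:
        if not self.delete_patterns or any(not p for p in self.delete_patterns):
            raise ConfigError("delete_patterns must be a non-empty list of non-empty patterns")
        if self.final_format not in ("raw", "by_event", "by_form"):
            raise ConfigError(f"unknown final_format {self.final_format!r}")
        if self.checkbox_na_policy not in ("branching_missing_only", "branching_missing_or_false"):
            raise ConfigError(f"unknown checkbox_na_policy {self.checkbox_na_policy!r}")
        if self.delete_mode not in ("suffix", "substring"):
            raise ConfigError(f"unknown delete_mode {self.delete_mode!r}")


@dataclass
class TraceStep:
    number: int
    title: str
    details: list[str] = dc_field(default_factory=list)
    warnings: list[str] = dc_field(default_factory=list)

    def __str__(self) -> str:
        lines = [f"{self.number}. {self.title}"]
        lines += [f"   {d}" for d in self.details]
        lines += [f"   WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


@dataclass
class SplitGroup:
    key: str
    vars: list[str]
    data: RecordTable


@dataclass
class SplitTable:
    by: str  # event | form
    groups: list[SplitGroup]


@dataclass
class TransformResult:
    data: Union[RecordTable, SplitTable]
    dictionary: list[FieldDef]
    trace: list[TraceStep]
    recalc_report: list[RecalcResult]
    event_map: Optional[EventFormMap] = None

    @property
    def records(self) -> RecordTable:
        if isinstance(self.data, SplitTable):
            raise ValidationError("transformed data was split; no single record table")
        return self.data

    def trace_text(self) -> str:
        return "\n".join(str(s) for s in self.trace)


def _copy_dictionary(dictionary: Sequence[FieldDef]) -> list[FieldDef]:
    return [dataclasses.replace(f, choices=dict(f.choices)) for f in dictionary]


# ---------------------------------------------------------------------------
# step 2: checkboxes


def transform_checkboxes(
    records: RecordTable,
    dictionary: Sequence[FieldDef],
    config: TransformConfig | None = None,
) -> tuple[RecordTable, list[FieldDef], list[str]]:
    """Rename ``field___code`` columns to their option labels, relabel the
    0/1 values, and blank out rows whose parent branching logic is missing."""
    config = config or TransformConfig()
    no_label, yes_label = config.checkbox_labels
    df = records.df.copy()
    warnings: list[str] = []
    renames = checkbox_rename_map(list(dictionary))

    new_dictionary: list[FieldDef] = []
    for f in dictionary:
        if f.field_type != "checkbox":
            new_dictionary.append(f)
            continue

        branching_missing_rows = None
        if f.branching_logic.strip():
            report = translate(f.branching_logic, list(dictionary))
            if not report.translatable:
                warnings.append(
                    f"checkbox {f.name!r}: branching logic not evaluated ({report.warning_text})"
                )
            else:
                from .logic import parse_source

                ast = parse_source(f.branching_logic)
                flags = []
                for _, row in df.iterrows():
                    ctx = EvalContext(
                        row=dict(row),
                        event=row.get("redcap_event_name", ""),
                    )
                    truth = to_truth(evaluate(ast, ctx))
                    if config.checkbox_na_policy == "branching_missing_only":
                        flags.append(truth is MISSING)
                    else:
                        flags.append(truth is not True)
                branching_missing_rows = flags
        else:
            warnings.append(
                f"checkbox {f.name!r} has no branching logic; "
                "check whether its blanks should be missing"
            )

        for code, label in f.choices.items():
            old_col = f"{f.name}{CHECKBOX_SEP}{code}"
            new_col = renames[(f.name, code)]
            if old_col in df.columns:
                if new_col != old_col and new_col in df.columns:
                    raise ValidationError(
                        f"cannot rename checkbox column {old_col!r}: {new_col!r} already exists"
                    )
                df.rename(columns={old_col: new_col}, inplace=True)
                df[new_col] = df[new_col].map(
                    lambda v: {"0": no_label, "1": yes_label}.get(v, v)
                )
                if branching_missing_rows is not None:
                    df.loc[branching_missing_rows, new_col] = ""
            new_dictionary.append(
                FieldDef(
                    name=new_col,
                    form=f.form,
                    field_type="checkbox",
                    label=f"{f.label}: {label}" if f.label else label,
                    choices={no_label: no_label, yes_label: yes_label},
                    branching_logic=f.branching_logic,
                )
            )
    return RecordTable(df, records.id_column), new_dictionary, warnings


# ---------------------------------------------------------------------------
# step 3: factors


_IMPLICIT_CHOICES = {
    "yesno": {"1": "Yes", "0": "No"},
    "truefalse": {"1": "True", "0": "False"},
}


def apply_factors(
    records: RecordTable, dictionary: Sequence[FieldDef]
) -> tuple[RecordTable, list[str]]:
    """Replace raw codes with their labels for radio/dropdown/yesno/truefalse
    columns; the event and DAG columns keep the raw version and gain a
    labeled ``*_label`` companion. Unknown codes are kept verbatim with a
    warning. Already-labeled data is rejected."""
    df = records.df.copy()
    warnings: list[str] = []

    for f in dictionary:
        if f.name not in df.columns:
            continue
        if f.field_type in ("radio", "dropdown"):
            choices = f.choices
        elif f.field_type in _IMPLICIT_CHOICES:
            choices = _IMPLICIT_CHOICES[f.field_type]
        else:
            continue
        values = {v for v in df[f.name] if v != ""}
        if values and not (values & set(choices)) and values <= set(choices.values()):
            raise ValidationError(
                f"field {f.name!r} already carries labels, not raw codes; "
                "factor substitution was not re-applied"
            )
        unknown = sorted(values - set(choices))
        for code in unknown:
            warnings.append(
                f"field {f.name!r}: value {code!r} is not among the defined choices; kept verbatim"
            )
        df[f.name] = df[f.name].map(lambda v: choices.get(v, v))

    for raw_col in ("redcap_event_name", "redcap_data_access_group"):
        if raw_col in df.columns:
            label_col = f"{raw_col}_label"
            position = df.columns.get_loc(raw_col) + 1
            if label_col not in df.columns:
                df.insert(position, label_col, df[raw_col].map(prettify))
    return RecordTable(df, records.id_column), warnings


# ---------------------------------------------------------------------------
# step 5: deletion


def delete_pattern_vars(
    records: RecordTable,
    patterns: Sequence[str],
    mode: str = "suffix",
) -> RecordTable:
    """Drop columns matching any pattern (suffix-anchored by default)."""
    if not patterns:
        raise ConfigError("delete_patterns must not be empty")

    def hit(col: str) -> bool:
        if mode == "substring":
            return any(p in col for p in patterns)
        return any(col.endswith(p) for p in patterns)

    keep = [c for c in records.df.columns if not hit(c)]
    return RecordTable(records.df[keep].copy(), records.id_column)


# ---------------------------------------------------------------------------
# split


def _reserved_columns(df_columns: Sequence[str], id_column: str,
                      known: set[str]) -> list[str]:
    reserved = []
    for col in df_columns:
        if col == id_column or col.startswith(RESERVED_PREFIX) or col not in known:
            reserved.append(col)
    return reserved


def split(
    records: RecordTable,
    by: str,
    dictionary: Sequence[FieldDef],
    event_map: EventFormMap | None = None,
) -> SplitTable:
    """Split a record table into per-event or per-form groups."""
    df = records.df
    column_form: dict[str, str] = {}
    forms: list[str] = []
    for f in dictionary:
        column_form[f.name] = f.form
        if f.form not in forms:
            forms.append(f.form)
    for form in forms:
        column_form.setdefault(f"{form}_complete", form)
        column_form.setdefault(f"{form}_timestamp", form)
    reserved = _reserved_columns(df.columns, records.id_column, set(column_form))

    if by == "event":
        if event_map is None:
            raise ConfigError("split by event requires an event-form mapping")
        data_events = [] if "redcap_event_name" not in df.columns else list(
            dict.fromkeys(e for e in df["redcap_event_name"] if e)
        )
        unknown = [e for e in data_events if e not in set(event_map.events)]
        if unknown:
            raise ValidationError(f"events absent from the event-form mapping: {unknown}")
        groups = []
        for event in event_map.events:
            if event not in data_events:
                continue
            event_forms = set(event_map.forms_for(event))
            vars_ = [
                c for c in df.columns
                if c in reserved or column_form.get(c) in event_forms
            ]
            subset = df[df["redcap_event_name"] == event][vars_].copy()
            groups.append(SplitGroup(event, vars_, RecordTable(subset, records.id_column)))
        return SplitTable("event", groups)

    if by == "form":
        groups = []
        for form in forms:
            own = [
                c for c in df.columns
                if column_form.get(c) == form and c != records.id_column
            ]
            if not own:
                continue
            vars_ = [c for c in df.columns if c in reserved or c in own]
            payload = [c for c in own if not c.endswith(("_complete", "_timestamp"))]
            mask = df[payload].apply(lambda r: any(v != "" for v in r), axis=1) if payload else (
                df[own].apply(lambda r: any(v != "" for v in r), axis=1)
            )
            subset = df[mask][vars_].copy()
            groups.append(SplitGroup(form, vars_, RecordTable(subset, records.id_column)))
        return SplitTable("form", groups)

    raise ConfigError(f"unknown split mode {by!r}")


# ---------------------------------------------------------------------------
# the pipeline


def transform_project(
    bundle: ProjectBundle, config: TransformConfig | None = None
) -> TransformResult:
    """Run the default transformation (and the optional final split)."""
    config = config or TransformConfig()
    if config.final_format == "by_event" and bundle.event_map is None:
        raise ConfigError("final_format='by_event' requires an event-form mapping")

    records = bundle.records.copy()
    dictionary = _copy_dictionary(bundle.dictionary)
    trace: list[TraceStep] = []

    # 1. recalculation
    step = TraceStep(1, "Recalculation of calculated fields")
    recalc_results: list[RecalcResult] = []
    for f in dictionary:
        if f.field_type != "calc":
            continue
        result = recalculate(f, records, bundle.event_map, dictionary)
        recalc_results.append(result)
        if result.skipped:
            step.warnings.append(
                f"calculated field {f.name!r} skipped: {result.translation.warning_text}"
            )
        else:
            s = result.summary
            step.details.append(
                f"{f.name}: {s['status']} "
                f"({s['match']} match, {s['mismatch']} mismatch, {s['skipped']} skipped)"
            )
    if not recalc_results:
        step.details.append("no calculated fields")
    trace.append(step)

    # 2. checkboxes
    step = TraceStep(2, "Checkbox transformation")
    renames = checkbox_rename_map(dictionary)
    records, dictionary, warnings = transform_checkboxes(records, dictionary, config)
    for (fname, code), new_col in renames.items():
        step.details.append(f"{fname}{CHECKBOX_SEP}{code} -> {new_col}")
    if not renames:
        step.details.append("no checkbox fields")
    step.warnings.extend(warnings)
    trace.append(step)

    # 3. factors
    step = TraceStep(3, "Factor substitution")
    records, warnings = apply_factors(records, dictionary)
    step.details.append("raw codes replaced by labels; event/DAG keep both versions")
    step.warnings.extend(warnings)
    trace.append(step)

    # 4. branching-logic translation
    step = TraceStep(4, "Branching-logic translation")
    translated = 0
    for f in dictionary:
        if not f.branching_logic.strip():
            continue
        report = translate(f.branching_logic, dictionary)
        if report.translatable:
            f.branching_logic = report.rendered
            translated += 1
        else:
            step.warnings.append(f"field {f.name!r}: {report.warning_text}")
    step.details.append(f"{translated} branching logic expression(s) translated")
    trace.append(step)

    # 5. deletion
    step = TraceStep(5, "Deletion of variables matching a pattern")
    before = list(records.df.columns)
    records = delete_pattern_vars(records, config.delete_patterns, config.delete_mode)
    removed = [c for c in before if c not in records.df.columns]
    step.details.append(
        f"{len(removed)} column(s) removed matching {list(config.delete_patterns)}"
    )
    trace.append(step)

    data: Union[RecordTable, SplitTable] = records
    if config.final_format != "raw":
        by = "event" if config.final_format == "by_event" else "form"
        data = split(records, by, dictionary, bundle.event_map)
        step = TraceStep(6, f"Final split by {by}")
        step.details.append(f"{len(data.groups)} group(s): " + ", ".join(g.key for g in data.groups))
        trace.append(step)

    return TransformResult(
        data=data,
        dictionary=dictionary,
        trace=trace,
        recalc_report=recalc_results,
        event_map=bundle.event_map,
    )
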