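"""Discrepancy queries, missing-event detection, summaries and report diffing.

A :class:`QueryRule` states the VALID condition; rows where it evaluates to
false or missing raise a query (set ``negate`` to invert). Reports follow the
eight-column layout (Identifier, DAG, Event, Instrument, Field, Description,
Query, Code) and diffs add a Modification column with one of New / Pending /
Solved / Miscorrected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

from .errors import ValidationError
from .logic import Binary, FieldRef, Literal, evaluate, parse_source, render, to_truth
from .logic.evaluator import EvalContext
from .naming import prettify
from .project_io import EventFormMap, FieldDef, ProjectBundle, RecordTable
from .transform import TransformResult

__all__ = [
    "Query",
    "QueryRule",
    "QueryReport",
    "QueryDiff",
    "rd_query",
    "rd_event",
    "summarize",
    "check_queries",
    "natural_key",
]

MISSING_QUERY_TEXT = "The value is NA and it should not be missing"
MISSING_SUMMARY_TEXT = "The value should not be missing"
MISSING_EVENT_TEXT = "The event is missing"

_VALUE_TEXT_RE = re.compile(r"^The value is .* and it should be (?P<cond>.+)$")


@dataclass
class Query:
    identifier: str
    dag: str
    event: str
    instrument: str
    field: str
    description: str
    query_text: str
    code: str = ""
    snapshot_value: str = ""  # offending value at generation time; not printed
    summary_text: str = ""  # value-free restatement of the rule

    def rule_text(self) -> str:
        """The value-free form of the query text, used for summaries and as
        the stable component of the diff match key."""
        if self.summary_text:
            return self.summary_text
        if self.query_text == MISSING_QUERY_TEXT:
            return MISSING_SUMMARY_TEXT
        m = _VALUE_TEXT_RE.match(self.query_text)
        if m:
            return f"The value should be {m.group('cond')}"
        return self.query_text

    @property
    def match_key(self) -> tuple[str, str, str, str]:
        return (self.identifier, self.event, self.field, self.rule_text())


@dataclass
class QueryRule:
    variables: list[str]
    expressions: list[str]
    query_text_template: str = ""
    negate: bool = False

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValidationError("a query rule needs at least one variable")
        if len(self.expressions) not in (1, len(self.variables)):
            raise ValidationError(
                "expressions must have length 1 (broadcast) or match the variables"
            )

    @classmethod
    def missing(cls, variables: Sequence[str]) -> "QueryRule":
        """Convenience: flag blank values of every listed variable."""
        return cls(list(variables), ["[{var}] <> ''"])

    def expression_for(self, index: int, variable: str) -> str:
        template = self.expressions[0] if len(self.expressions) == 1 else self.expressions[index]
        return template.replace("{var}", variable)


@dataclass
class QueryReport:
    queries: list[Query] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.queries)

    @property
    def summary(self) -> list[dict]:
        return summarize(self)


@dataclass
class QueryDiff:
    merged: list[tuple[Query, str]] = dc_field(default_factory=list)

    @property
    def summary(self) -> dict[str, int]:
        counts = {"New": 0, "Pending": 0, "Solved": 0, "Miscorrected": 0}
        for _, modification in self.merged:
            counts[modification] += 1
        return counts

    def by_modification(self, modification: str) -> list[Query]:
        return [q for q, m in self.merged if m == modification]


def natural_key(text: str) -> tuple:
    """Sort key treating digit runs numerically: '100-9' < '100-58'."""
    parts = re.split(r"(\d+)", text)
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p != "")


# ---------------------------------------------------------------------------


def _unpack(source: Union[ProjectBundle, TransformResult]):
    if isinstance(source, ProjectBundle):
        return source.records, source.dictionary, source.event_map
    if isinstance(source, TransformResult):
        return source.records, source.dictionary, source.event_map
    raise TypeError("rd_query expects a ProjectBundle or TransformResult")


def _dag_of(row, df_columns) -> str:
    if "redcap_data_access_group_label" in df_columns:
        return row["redcap_data_access_group_label"]
    if "redcap_data_access_group" in df_columns:
        return prettify(row["redcap_data_access_group"])
    return ""


def _event_label(row, df_columns) -> str:
    if "redcap_event_name_label" in df_columns:
        return row["redcap_event_name_label"]
    if "redcap_event_name" in df_columns:
        return prettify(row["redcap_event_name"])
    return ""


def _is_missingness(ast, variable: str) -> bool:
    return (
        isinstance(ast, Binary)
        and ast.op == "<>"
        and isinstance(ast.left, FieldRef)
        and ast.left.name == variable
        and isinstance(ast.right, Literal)
        and ast.right.type == "blank"
    )


def _finalize(queries: list[Query], event_order: list[str], field_order: list[str]) -> QueryReport:
    """Order the report and assign per-identifier consecutive codes."""
    event_index = {e: i for i, e in enumerate(event_order)}
    field_index = {f: i for i, f in enumerate(field_order)}
    queries.sort(
        key=lambda q: (
            natural_key(q.identifier),
            event_index.get(q.event, len(event_index)),
            field_index.get(q.field, len(field_index)),
        )
    )
    counter: dict[str, int] = {}
    for q in queries:
        counter[q.identifier] = counter.get(q.identifier, 0) + 1
        q.code = f"{q.identifier}-{counter[q.identifier]}"
    return QueryReport(queries)


def rd_query(
    source: Union[ProjectBundle, TransformResult], rule: QueryRule
) -> QueryReport:
    """Emit one query per (record, event) row where ``rule`` flags a
    discrepancy. With an event-form map, each variable is checked only at the
    events its form is mapped to."""
    records, dictionary, event_map = _unpack(source)
    df = records.df
    by_name: dict[str, FieldDef] = {f.name: f for f in dictionary}
    has_events = "redcap_event_name" in df.columns

    queries: list[Query] = []
    for index, variable in enumerate(rule.variables):
        f = by_name.get(variable)
        if f is None:
            raise ValidationError(f"unknown variable {variable!r}")
        if variable not in df.columns:
            raise ValidationError(f"variable {variable!r} has no column in the data")
        expression = rule.expression_for(index, variable)
        ast = parse_source(expression)
        rendered = render(ast)
        missingness = _is_missingness(ast, variable)

        rows = df
        if event_map is not None:
            variable_events = event_map.events_for_form(f.form)
            if not variable_events:
                raise ValidationError(
                    f"variable {variable!r} (form {f.form!r}) is mapped to no event"
                )
            if has_events:
                rows = df[df["redcap_event_name"].isin(variable_events)]

        for _, row in rows.iterrows():
            ctx = EvalContext(row=dict(row), event=row.get("redcap_event_name", ""))
            truth = to_truth(evaluate(ast, ctx))
            violated = (truth is True) if rule.negate else (truth is not True)
            if not violated:
                continue
            value = row.get(variable, "")
            shown = "NA" if value == "" else value
            if rule.query_text_template:
                text = rule.query_text_template.format(value=shown, expression=rendered)
                summary_text = rule.query_text_template.format(value="", expression=rendered)
            elif missingness:
                text = MISSING_QUERY_TEXT
                summary_text = MISSING_SUMMARY_TEXT
            else:
                text = f"The value is {shown} and it should be {rendered}"
                summary_text = f"The value should be {rendered}"
            queries.append(
                Query(
                    identifier=row[records.id_column],
                    dag=_dag_of(row, df.columns),
                    event=_event_label(row, df.columns),
                    instrument=prettify(f.form),
                    field=variable,
                    description=f.label,
                    query_text=text,
                    snapshot_value=value,
                    summary_text=summary_text,
                )
            )

    event_order = [prettify(e) for e in (event_map.events if event_map else records.events)]
    return _finalize(queries, event_order, [f.name for f in dictionary])


def rd_event(bundle: ProjectBundle, events: Sequence[str]) -> QueryReport:
    """One query per (record, expected event) pair absent from the data.

    A record is expected at every requested event belonging to one of its
    arms (arms inferred from the events it does have rows for).
    """
    if bundle.event_map is None:
        raise ValidationError("rd_event requires an event-form mapping")
    known = set(bundle.event_map.events)
    unknown = [e for e in events if e not in known]
    if unknown:
        raise ValidationError(f"unknown event name(s): {unknown}")

    df = bundle.records.df
    if "redcap_event_name" not in df.columns:
        raise ValidationError("records have no redcap_event_name column")
    id_column = bundle.records.id_column

    observed: dict[str, set[str]] = {}
    dag: dict[str, str] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        rid = row[id_column]
        if rid not in observed:
            observed[rid] = set()
            order.append(rid)
        observed[rid].add(row["redcap_event_name"])
        if rid not in dag:
            dag[rid] = _dag_of(row, df.columns)

    queries: list[Query] = []
    for rid in order:
        arms = {bundle.event_map.arm_of(e) for e in observed[rid]}
        for event in events:
            if bundle.event_map.arm_of(event) not in arms:
                continue
            if event in observed[rid]:
                continue
            queries.append(
                Query(
                    identifier=rid,
                    dag=dag[rid],
                    event=prettify(event),
                    instrument="",
                    field="",
                    description="",
                    query_text=MISSING_EVENT_TEXT,
                    snapshot_value="",
                    summary_text=MISSING_EVENT_TEXT,
                )
            )
    event_order = [prettify(e) for e in bundle.event_map.events]
    return _finalize(queries, event_order, [])


def summarize(report: QueryReport) -> list[dict]:
    """Rows of {variable, description, event, query, total}, grouped by
    (variable, event, query type) and sorted by descending total."""
    groups: dict[tuple[str, str, str], dict] = {}
    for q in report.queries:
        key = (q.field, q.event, q.rule_text())
        if key not in groups:
            groups[key] = {
                "variable": q.field,
                "description": q.description,
                "event": q.event,
                "query": q.rule_text(),
                "total": 0,
            }
        groups[key]["total"] += 1
    return sorted(groups.values(), key=lambda g: -g["total"])


def check_queries(old: QueryReport, new: QueryReport) -> QueryDiff:
    """Diff two query reports into New / Pending / Solved / Miscorrected.

    Queries match on (identifier, event, field, value-free rule text); a
    matched query whose offending value changed is Miscorrected.
    """
    def keyed(report: QueryReport, name: str) -> dict:
        out: dict = {}
        for q in report.queries:
            if q.match_key in out:
                raise ValidationError(
                    f"duplicate match key in {name} report: {q.match_key}"
                )
            out[q.match_key] = q
        return out

    old_by_key = keyed(old, "old")
    new_by_key = keyed(new, "new")

    merged: list[tuple[Query, str]] = []
    for q in new.queries:
        previous = old_by_key.get(q.match_key)
        if previous is None:
            merged.append((q, "New"))
        elif previous.snapshot_value == q.snapshot_value:
            merged.append((q, "Pending"))
        else:
            merged.append((q, "Miscorrected"))
    for q in old.queries:
        if q.match_key not in new_by_key:
            merged.append((q, "Solved"))
    return QueryDiff(merged=merged)
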