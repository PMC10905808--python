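"""Recalculation of auto-calculated fields and comparison with stored values.

The stored value wins the formatting contest: the freshly computed number is
rounded to the stored value's printed decimal places before the comparison,
and a tolerance of 1e-6 absorbs float noise. Blank stored vs blank
recalculated counts as a match.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence

from .ast import FieldRef, walk
from .evaluator import BLANK, MISSING, EvalContext, _round_half_away, evaluate, parse_date
from .parser import parse_source
from .translate import TranslationReport, translate

__all__ = ["RecalcResult", "recalculate", "TOLERANCE"]

TOLERANCE = 1e-6

_VALIDATION_FORMATS = {
    "date_ymd": "%Y-%m-%d",
    "date_dmy": "%d-%m-%Y",
    "date_mdy": "%m-%d-%Y",
}


@dataclass
class RecalcResult:
    field: str
    values: dict[tuple[str, str], object] = dc_field(default_factory=dict)
    comparison: dict[tuple[str, str], bool] = dc_field(default_factory=dict)
    summary: dict = dc_field(default_factory=dict)
    translation: Optional[TranslationReport] = None
    skipped: bool = False
    notes: list[str] = dc_field(default_factory=list)

    @property
    def status(self) -> str:
        return self.summary.get("status", "skipped")


def _build_date_parser(dictionary: Sequence):
    formats: dict[str, str] = {}
    for f in dictionary:
        validation = getattr(f, "validation", None)
        if validation is not None and validation.kind in _VALIDATION_FORMATS:
            formats[f.name] = _VALIDATION_FORMATS[validation.kind]

    def parser(text: str, column: str) -> Optional[_dt.datetime]:
        fmt = formats.get(column)
        if fmt is not None:
            parsed = parse_date(text, fmt)
            if parsed is not None:
                return parsed
        return parse_date(text)

    return parser


def values_match(stored: str, recalculated: object) -> bool:
    """Compare a stored raw string with a freshly computed value."""
    if recalculated is True:
        recalculated = 1.0
    elif recalculated is False:
        recalculated = 0.0
    blank_recalc = recalculated is BLANK or recalculated is MISSING
    if stored == "":
        return blank_recalc
    if blank_recalc:
        return False
    try:
        stored_number = float(stored)
    except ValueError:
        return str(recalculated) == stored
    if not isinstance(recalculated, float):
        try:
            recalculated = float(str(recalculated))
        except ValueError:
            return False
    decimals = len(stored.split(".", 1)[1]) if "." in stored else 0
    return abs(_round_half_away(recalculated, decimals) - stored_number) <= TOLERANCE


def recalculate(
    field,
    records,
    event_map=None,
    dictionary: Sequence | None = None,
    today: _dt.date | None = None,
) -> RecalcResult:
    """Recompute one calc field for every applicable row of ``records``.

    ``records`` is a :class:`~redcapkit.project_io.RecordTable`;
    ``event_map``, when given, restricts rows to the events whose forms carry
    the field. Untranslatable calculations are skipped, never raised.
    """
    dictionary = list(dictionary) if dictionary is not None else [field]
    report = translate(field.calculation, dictionary)
    if not report.translatable:
        return RecalcResult(
            field=field.name,
            translation=report,
            skipped=True,
            summary={"status": "skipped", "match": 0, "mismatch": 0, "skipped": 0},
        )
    # evaluate the ORIGINAL expression: raw data still has field___code columns
    ast = parse_source(field.calculation)

    allowed_events: set[str] | None = None
    if event_map is not None:
        allowed_events = {e.event for e in event_map.entries if e.form == field.form}

    df = records.df
    id_col = records.id_column
    has_events = "redcap_event_name" in df.columns

    needs_cross = any(
        isinstance(n, FieldRef) and n.event_qualifier not in (None, "event-name")
        for n in walk(ast)
    )
    cross: dict[str, dict[tuple[str, str], str]] = {}
    if needs_cross and has_events:
        for _, row in df.iterrows():
            rid = row[id_col]
            bucket = cross.setdefault(rid, {})
            event = row["redcap_event_name"]
            for col, val in row.items():
                bucket[(event, col)] = val

    date_parser = _build_date_parser(dictionary)
    result = RecalcResult(field=field.name, translation=report)
    match = mismatch = skipped = 0
    for _, row in df.iterrows():
        rid = row[id_col]
        event = row["redcap_event_name"] if has_events else ""
        if allowed_events is not None and has_events and event not in allowed_events:
            skipped += 1
            continue
        ctx = EvalContext(
            row=dict(row),
            cross_event=cross.get(rid, {}),
            event=event,
            date_parser=date_parser,
        )
        if today is not None:
            ctx.today = today
        value = evaluate(ast, ctx)
        stored = row.get(field.name, "")
        ok = values_match(stored, value)
        result.values[(rid, event)] = value
        result.comparison[(rid, event)] = ok
        if ok:
            match += 1
        else:
            mismatch += 1
        result.notes.extend(f"{rid}/{event}: {n}" for n in ctx.notes)
    result.summary = {
        "field": field.name,
        "status": "identical" if mismatch == 0 else "not identical",
        "match": match,
        "mismatch": mismatch,
        "skipped": skipped,
    }
    return result
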