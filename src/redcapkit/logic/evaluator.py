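"""Expression evaluation with REDCap blank semantics and Kleene logic.

Value domain
------------
* numbers (``float``) and strings,
* ``BLANK`` — the empty/blank value ('' in an export),
* ``True`` / ``False`` / ``MISSING`` — the tri-state truth values produced by
  comparisons and boolean connectives.

Blank rules:

* arithmetic with a blank (or non-numeric) operand yields blank;
* comparisons with a blank operand yield ``MISSING`` — except equality
  against the blank literal: ``[x] = ''`` is true iff ``[x]`` is blank, and
  ``[x] <> ''`` is true iff it is not;
* ``and`` / ``or`` follow Kleene three-valued logic;
* division by zero (and similar domain errors) yields blank plus a recorded
  note, never an exception.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

from .ast import Binary, Call, FieldRef, Literal, Node, SmartVar, Unary

__all__ = ["BLANK", "MISSING", "EvalContext", "evaluate", "to_truth", "parse_date"]


class _Blank:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "BLANK"

    def __bool__(self) -> bool:
        return False


class _Missing:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


BLANK = _Blank()
MISSING = _Missing()

_DATE_FORMATS = (
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%d %H:%M",
    "%Y-%m-%d",
    "%Y/%m/%d",
    "%d-%m-%Y",
    "%d/%m/%Y",
    "%H:%M:%S",
    "%H:%M",
)

_SECONDS = {"s": 1.0, "m": 60.0, "h": 3600.0, "d": 86400.0}
# REDCap's documented approximations
_SECONDS["M"] = 30.44 * 86400.0
_SECONDS["y"] = 365.2425 * 86400.0


def parse_date(text: str, fmt: str | None = None) -> Optional[_dt.datetime]:
    """Parse a REDCap date/datetime/time string; ``None`` if unparseable."""
    text = text.strip()
    if not text:
        return None
    formats = (fmt,) if fmt else _DATE_FORMATS
    for f in formats:
        try:
            parsed = _dt.datetime.strptime(text, f)
        except ValueError:
            continue
        if f in ("%H:%M:%S", "%H:%M"):
            parsed = parsed.replace(year=1970, month=1, day=1)
        return parsed
    return None


@dataclass
class EvalContext:
    """Everything one (record, event) row exposes to an expression."""

    row: Mapping[str, str] = field(default_factory=dict)
    cross_event: Mapping[tuple[str, str], str] = field(default_factory=dict)
    event: str = ""
    today: _dt.date = field(default_factory=_dt.date.today)
    date_parser: Optional[Callable[[str, str], Optional[_dt.datetime]]] = None
    notes: list[str] = field(default_factory=list)

    def lookup(self, column: str, event: str | None = None) -> object:
        """Raw value of ``column``; absent fields yield blank, never an error."""
        if event is not None and event != self.event:
            raw = self.cross_event.get((event, column), "")
        else:
            raw = self.row.get(column, "")
        return BLANK if raw == "" else raw

    def note(self, message: str) -> None:
        self.notes.append(message)


def _as_number(value: object) -> object:
    """Coerce to float; BLANK if blank or not numeric."""
    if value is BLANK or value is MISSING:
        return BLANK
    if isinstance(value, bool):
        return 1.0 if value else 0.0
    if isinstance(value, float):
        return value
    try:
        return float(str(value))
    except ValueError:
        return BLANK


def to_truth(value: object) -> object:
    """Collapse any value to the tri-state domain {True, False, MISSING}."""
    if value is True or value is False or value is MISSING:
        return value
    if value is BLANK:
        return MISSING
    num = _as_number(value)
    if num is not BLANK:
        return num != 0
    return str(value) != ""


def _kleene_and(a: object, b: object) -> object:
    if a is False or b is False:
        return False
    if a is True and b is True:
        return True
    return MISSING


def _kleene_or(a: object, b: object) -> object:
    if a is True or b is True:
        return True
    if a is False and b is False:
        return False
    return MISSING


def _is_blank_literal(node: Node) -> bool:
    return isinstance(node, Literal) and node.type == "blank"


def _round_half_away(x: float, digits: int) -> float:
    factor = 10.0 ** digits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _compare(op: str, left: object, right: object) -> object:
    ln, rn = _as_number(left), _as_number(right)
    if ln is not BLANK and rn is not BLANK:
        a, b = ln, rn
    else:
        a, b = str(left), str(right)
    if op == "=":
        return a == b
    if op == "<>":
        return a != b
    if op == "<":
        return a < b
    if op == "<=":
        return a <= b
    if op == ">":
        return a > b
    return a >= b


def evaluate(node: Node, ctx: EvalContext | None = None) -> object:
    """Evaluate ``node`` to a number, string, BLANK, or tri-state truth value."""
    if ctx is None:
        ctx = EvalContext()

    if isinstance(node, Literal):
        if node.type == "blank":
            return BLANK
        return node.value

    if isinstance(node, FieldRef):
        column = f"{node.name}___{node.checkbox_code}" if node.checkbox_code else node.name
        event = None
        if node.event_qualifier and node.event_qualifier != "event-name":
            event = node.event_qualifier
        value = ctx.lookup(column, event)
        return value

    if isinstance(node, SmartVar):
        if node.name == "event-name":
            return ctx.event if ctx.event else BLANK
        ctx.note(f"unsupported smart variable [{node.name}] evaluated as blank")
        return BLANK

    if isinstance(node, Unary):
        if node.op == "not":
            truth = to_truth(evaluate(node.child, ctx))
            return MISSING if truth is MISSING else (not truth)
        value = _as_number(evaluate(node.child, ctx))
        return BLANK if value is BLANK else -value

    if isinstance(node, Binary):
        if node.op in ("and", "or"):
            a = to_truth(evaluate(node.left, ctx))
            b = to_truth(evaluate(node.right, ctx))
            return _kleene_and(a, b) if node.op == "and" else _kleene_or(a, b)
        if node.op in ("=", "<>"):
            # equality against the blank literal is a blankness test
            if _is_blank_literal(node.left) or _is_blank_literal(node.right):
                other = node.right if _is_blank_literal(node.left) else node.left
                is_blank = _truthy_operand(other, ctx) is BLANK
                return is_blank if node.op == "=" else not is_blank
            left = _truthy_operand(node.left, ctx)
            right = _truthy_operand(node.right, ctx)
            if left is BLANK or right is BLANK or left is MISSING or right is MISSING:
                return MISSING
            return _compare(node.op, left, right)
        if node.op in ("<", "<=", ">", ">="):
            left = _truthy_operand(node.left, ctx)
            right = _truthy_operand(node.right, ctx)
            if left is BLANK or right is BLANK or left is MISSING or right is MISSING:
                return MISSING
            return _compare(node.op, left, right)
        # arithmetic
        left = _as_number(evaluate(node.left, ctx))
        right = _as_number(evaluate(node.right, ctx))
        if left is BLANK or right is BLANK:
            return BLANK
        if node.op == "+":
            return left + right
        if node.op == "-":
            return left - right
        if node.op == "*":
            return left * right
        if node.op == "/":
            if right == 0:
                ctx.note("division by zero")
                return BLANK
            return left / right
        if node.op == "^":
            try:
                result = left ** right
            except (OverflowError, ValueError, ZeroDivisionError):
                ctx.note(f"invalid power {left} ^ {right}")
                return BLANK
            if isinstance(result, complex):
                ctx.note(f"invalid power {left} ^ {right}")
                return BLANK
            return result
        raise ValueError(f"unknown operator {node.op!r}")

    if isinstance(node, Call):
        return _call(node, ctx)

    raise TypeError(f"not an AST node: {node!r}")


def _truthy_operand(node: Node, ctx: EvalContext) -> object:
    """Evaluate a comparison operand; bare checkbox refs mean "checked"."""
    value = evaluate(node, ctx)
    return value


def _call(node: Call, ctx: EvalContext) -> object:
    name = node.func

    if name == "if":
        truth = to_truth(evaluate(node.args[0], ctx))
        if truth is MISSING:
            return BLANK
        return evaluate(node.args[1] if truth else node.args[2], ctx)

    if name == "datediff":
        return _datediff(node, ctx)

    if name in ("round", "roundup", "rounddown"):
        value = _as_number(evaluate(node.args[0], ctx))
        if value is BLANK:
            return BLANK
        digits = 0.0
        if len(node.args) > 1:
            digits = _as_number(evaluate(node.args[1], ctx))
            if digits is BLANK:
                return BLANK
        factor = 10.0 ** int(digits)
        if name == "round":
            return _round_half_away(value, int(digits))
        if name == "roundup":
            return math.ceil(value * factor) / factor
        return math.floor(value * factor) / factor

    if name == "abs":
        value = _as_number(evaluate(node.args[0], ctx))
        return BLANK if value is BLANK else abs(value)

    if name == "sqrt":
        value = _as_number(evaluate(node.args[0], ctx))
        if value is BLANK:
            return BLANK
        if value < 0:
            ctx.note(f"sqrt of negative number {value}")
            return BLANK
        return math.sqrt(value)

    if name in ("min", "max", "sum", "mean"):
        numbers = []
        for arg in node.args:
            value = _as_number(evaluate(arg, ctx))
            if value is not BLANK:
                numbers.append(value)
        if not numbers:
            return BLANK
        if name == "min":
            return min(numbers)
        if name == "max":
            return max(numbers)
        if name == "sum":
            return sum(numbers)
        return sum(numbers) / len(numbers)

    raise ValueError(f"unknown function {name!r}")


def _datediff(node: Call, ctx: EvalContext) -> object:
    def _resolve(arg: Node) -> object:
        value = evaluate(arg, ctx)
        if value is BLANK or value is MISSING:
            return BLANK
        if isinstance(value, str) and value.strip().lower() == "today":
            return _dt.datetime.combine(ctx.today, _dt.time())
        parser = ctx.date_parser or (lambda text, col: parse_date(text))
        column = arg.name if isinstance(arg, FieldRef) else ""
        parsed = parser(str(value), column)
        if parsed is None:
            ctx.note(f"unparseable date {value!r} in datediff")
            return BLANK
        return parsed

    d1 = _resolve(node.args[0])
    d2 = _resolve(node.args[1])
    if d1 is BLANK or d2 is BLANK:
        return BLANK
    unit_value = evaluate(node.args[2], ctx)
    unit = str(unit_value)
    if unit not in _SECONDS:
        ctx.note(f"unknown datediff unit {unit!r}")
        return BLANK
    signed = False
    for extra in node.args[3:]:
        value = evaluate(extra, ctx)
        text = str(value).strip().lower()
        if text in ("true", "1"):
            signed = True
        elif text in ("false", "0"):
            signed = False
        # anything else is a date-format hint, which parse_date handles already
    seconds = (d2 - d1).total_seconds()
    result = seconds / _SECONDS[unit]
    return result if signed else abs(result)
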