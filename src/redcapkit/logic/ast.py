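"""AST node types for the expression engine, plus a canonical renderer.

``parse(tokenize(render(ast))) == ast`` holds for every well-formed tree; the
renderer inserts parentheses only where precedence or associativity requires
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

__all__ = [
    "FieldRef",
    "Literal",
    "Unary",
    "Binary",
    "Call",
    "SmartVar",
    "Node",
    "render",
    "walk",
    "BLANK_LITERAL",
]

COMPARISON_OPS = {"=", "<>", "<", "<=", ">", ">="}

# precedence levels, lowest binds loosest
_LEVEL = {
    "or": 1,
    "and": 2,
    "not": 3,
    "=": 4, "<>": 4, "<": 4, "<=": 4, ">": 4, ">=": 4,
    "+": 5, "-": 5,
    "*": 6, "/": 6,
    "neg": 7,
    "^": 8,
}
_ATOM_LEVEL = 9


@dataclass(frozen=True)
class FieldRef:
    name: str
    checkbox_code: Optional[str] = None
    event_qualifier: Optional[str] = None


@dataclass(frozen=True)
class Literal:
    value: Union[float, str, None]  # None encodes the blank literal ''
    type: str = "number"  # number | string | blank


BLANK_LITERAL = Literal(None, "blank")


@dataclass(frozen=True)
class Unary:
    op: str  # not | neg
    child: "Node"


@dataclass(frozen=True)
class Binary:
    op: str
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Call:
    func: str
    args: Tuple["Node", ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class SmartVar:
    name: str


Node = Union[FieldRef, Literal, Unary, Binary, Call, SmartVar]


def _level(node: Node) -> int:
    if isinstance(node, Binary):
        return _LEVEL[node.op]
    if isinstance(node, Unary):
        return _LEVEL["not"] if node.op == "not" else _LEVEL["neg"]
    return _ATOM_LEVEL


def _format_number(value: float) -> str:
    if float(value) == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(float(value))


def _wrap(text: str, needed: bool) -> str:
    return f"({text})" if needed else text


def render(node: Node) -> str:
    """Render ``node`` to canonical source text (round-trips through parse)."""
    if isinstance(node, FieldRef):
        body = f"[{node.name}({node.checkbox_code})]" if node.checkbox_code else f"[{node.name}]"
        if node.event_qualifier:
            return f"[{node.event_qualifier}]{body}"
        return body
    if isinstance(node, SmartVar):
        return f"[{node.name}]"
    if isinstance(node, Literal):
        if node.type == "blank":
            return "''"
        if node.type == "number":
            return _format_number(node.value)
        text = str(node.value)
        quote = '"' if "'" in text else "'"
        return f"{quote}{text}{quote}"
    if isinstance(node, Unary):
        lvl = _level(node)
        child = _wrap(render(node.child), _level(node.child) < lvl)
        return f"not {child}" if node.op == "not" else f"-{child}"
    if isinstance(node, Binary):
        lvl = _level(node)
        if node.op == "^":
            # right-associative; left operand must be an atom
            left = _wrap(render(node.left), _level(node.left) < _ATOM_LEVEL)
            right = _wrap(render(node.right), _level(node.right) < _LEVEL["neg"])
        elif node.op in COMPARISON_OPS:
            # non-associative: parenthesize any comparison-or-looser child
            left = _wrap(render(node.left), _level(node.left) <= lvl)
            right = _wrap(render(node.right), _level(node.right) <= lvl)
        else:
            # left-associative chains
            left = _wrap(render(node.left), _level(node.left) < lvl)
            right = _wrap(render(node.right), _level(node.right) <= lvl)
        return f"{left} {node.op} {right}"
    if isinstance(node, Call):
        return f"{node.func}({', '.join(render(a) for a in node.args)})"
    raise TypeError(f"not an AST node: {node!r}")


def walk(node: Node):
    """Yield ``node`` and every descendant, depth-first."""
    yield node
    if isinstance(node, Unary):
        yield from walk(node.child)
    elif isinstance(node, Binary):
        yield from walk(node.left)
        yield from walk(node.right)
    elif isinstance(node, Call):
        for arg in node.args:
            yield from walk(arg)
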